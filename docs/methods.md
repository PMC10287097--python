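# Methods

`headmotion` quantifies head motion during MRI from a markerless depth
camera that films part of the participant's face through the head coil. The
pipeline has three stages: (1) robust rigid registration of every camera
frame's point cloud to a cleaned reference cloud, producing a motion trace
of head poses; (2) post-processing of the trace (triangular-window
resampling to equidistant timestamps, clock synchronization, mapping into
anatomical coordinates); (3) summary metrics — the head pose difference,
per-sequence motion scores, the motion trace difference between two
methods' traces, and the mutual information between the trace and a chest
respiration signal. Real recordings of this kind are access-restricted, so
the package ships a seeded synthetic-scene generator and validates the full
pipeline against known ground truth.

## Registration model

Each frame `P_k` (N×3 points, mm) is mapped to the reference `P_ref` by a
proper rigid transform `p ↦ R p + t`, estimated by minimizing a robust
point-to-point objective

    Σ_p ψ( ‖R p + t − NN(p)‖ )  +  λ(R, t),

where `NN(p)` is the nearest reference point and ψ a robust criterion. The
default ψ is Huber's function with bound `Z = (1 + r_b)·median(residuals)`
and `r_b = 0.2`; Tukey, Cauchy and Welsch alternatives are provided with
their scales set via the 95%-efficiency constants (1.345, 4.685, 2.385,
2.985) so all criteria share the same asymptotic variance at a given Z, and
`identity` gives plain least-squares ICP for ablation contrasts.

The minimizer is IRLS around a closed-form weighted Kabsch solve: per
iteration, (i) nearest-neighbour correspondence via a KD-tree built once on
the static reference (lowest index wins exact ties), (ii) robust bound from
the current residual median, (iii) weights `w = ψ′(res)/res` (normalized to
w(0)=1), (iv) weighted rigid alignment. A zero median (perfect data) falls
back to unit weights. Iterations stop at 30 or when the pose moves less
than 1e-4 mm (head-pose difference over the session ball) — far below
sensor noise, so clean frames converge in a handful of iterations. The
quadratic IRLS surrogate majorizes every shipped criterion, so the robust
objective at fixed correspondences is non-increasing across inner solves;
the solver records the before/after objective per iteration and the test
suite asserts this.

**Anchor regularizer.** The camera sees only the anterior face, so the
posterior head is extrapolated through an 82.5 mm lever arm and small
rotation errors become millimetre errors at the occiput. Because the head
rests on a pillow with tight padding, the pillow contact point moves least;
λ pins it softly: one pseudo-correspondence `p_reg → p_reg` with weight
`α·Σw` (α = 0.03). The regularizer as stated carries no explicit norm; the
squared Euclidean norm is used so it enters the weighted least-squares
solve exactly like a data point. Whether the anchor's multiplier should sum
criterion values or IRLS weights is ambiguous; both are implemented
(`anchor_weight_mode`), defaulting to the weight sum so the anchor remains
a fixed fraction of total data influence regardless of residual scale.
The anchor helps precisely when its mechanical assumption holds (motion
pivoting near the occiput, as for a pillowed head): on front-patch scenes
with an occiput pivot it roughly halves the posterior displacement error.
When the true motion rotates about the head centre — as in the default
synthetic random walk — the occiput genuinely moves and the anchor biases
the fit, so session tracking on such scenes runs without it. Engage the
anchor when the physical setup justifies it.

**Sequential tracking.** Frame k is warm-started from frame k−1's pose
(frame 0 from the identity); within one 125 ms camera interval the head
moves little, so the optimizer only fine-tunes. Before optimization each
frame is under-sampled by keeping every 3rd point in depth-image raster
order and stripped of points farther than 5 mm from the reference under the
warm-start pose — a conservative cutoff (≈30 standard deviations of
typical 125 ms motion) that removes non-overlapping regions and gross
sensor outliers so the residual median stays stable across frames. The
robust bound is recomputed every IRLS iteration; the stable residual scale
achieved by the cutoff is what keeps it effectively constant across a
session. A frame with fewer than 3 usable points is a tracking loss: its
pose is marked missing, tracking resumes from the last good pose, and only
a majority of failures aborts the sequence.

## Trace post-processing

Camera timestamps are non-equidistant, so metrics operate on resampled
traces. For each output time the `window_size` nearest valid samples are
combined with triangular weights `max(0, 1 − slope·|Δt|)` (slope in 1/s;
slope 0 is a plain window average), renormalized to sum one. Translations
use the weighted arithmetic mean. Rotations use the normalized weighted
mean of quaternions after flipping each to the hemisphere of the window's
first sample — valid for the small angular spreads inside a window, and
much cheaper than a Karcher mean. Window size counts samples rather than
seconds because the input is non-equidistant (9 samples for scoring, 3 for
the respiration analysis). At the trace edges windows become asymmetric,
which sacrifices exact linear-signal preservation there; interior outputs
reproduce linear drifts to machine precision on equidistant input.

Clock offsets between acquisition systems are recovered by minimizing the
motion trace difference (below) between the shifted trace and the
comparison trace on a common 8 Hz grid: a coarse ±15 s grid at 0.125 s
steps followed by bounded scalar refinement. MTD rather than per-pose
differences makes the search blind to each method's reference pose. A
minimum at the search boundary is flagged. Mapping a trace to another
coordinate system conjugates each pose (`M ∘ T ∘ M⁻¹`): poses are
space-relative motions, not points.

## Metrics

**Head pose difference (HPD).** The RMS displacement induced by the
relative transform `D = b∘a⁻¹` over a ball modelling the head
(population-average face-to-centre distance 82.5 mm; centre from the
scan origin): `hpd² = (r²/5)·tr(AᵀA) + ‖t_D + A c‖²` with `A = R_D − I`.
This equals the mean squared displacement over the ball exactly (verified
against a Monte-Carlo oracle), is symmetric, and is invariant to a common
change of reference pose.

**Motion score.** Resample at slope 0.1 /s, window 9, to exactly 8 Hz
anchored at the interval start; sum consecutive-pose HPDs per 1 s bin;
average complete bins (a trailing partial bin is dropped, not rescaled).
Units mm/s. Scoring a session excludes inter-sequence breaks; sequences
too short to resample are reported missing rather than zero.

**Motion trace difference (MTD).** For traces on shared timestamps, form
within-method relative transforms `D_ij = T_j∘T_i⁻¹` for every pair i<j
and average `hpd(D^A_ij, D^B_ij)`. Using only relative transforms removes
each method's reference pose. All pairs are used by default (O(N²), fine
at ~10³ samples); a `pair_stride` approximation exists for long traces and
for the inner loop of clock synchronization. Comparison against fMRI
realignment traces first averages the camera trace over each fMRI frame
(slope-0 window over the frame span); the stated frame length is
ambiguous between the 530 ms repetition time and a 570 ms averaging
window, so the frame duration is an explicit parameter defaulting to
0.53 s.

**Respiration mutual information.** Resample the trace (slope 0.1 /s,
window 3) to 8 Hz, linearly interpolate the 256 Hz respiration channel to
the same timestamps, decompose poses into 3 translation and 4 quaternion
components with sequence-wide sign continuity (flip any quaternion whose
dot with its predecessor is negative), and estimate MI between the
respiration series and each of the 7 components with a Kraskov-style
k-nearest-neighbour estimator (k = 3, seeded sub-numerical jitter for
ties; scikit-learn implementation). Units are nats; per-component
negative estimates are estimator noise and are clipped to zero before
summation. Significance is assessed against a permutation null
(shuffled respiration). The estimator saturates near its sample-size
ceiling (~3.7 nats at n≈2000) under noiseless deterministic dependence.

## Synthetic scenes

The generator emulates the acquisition the pipeline targets; what it
deliberately does not model bounds what passing tests show about real data.

* **Reference cloud** — a half-ellipsoid face patch (~140×180 mm, 40 mm
  dome) with nose and brow ridges, sampled on a jittered depth-image
  raster. Curvature makes all six rigid DOF observable: the point-to-plane
  Jacobian Gram matrix (normals from local PCA, lever arms centred and
  scaled by the head radius) has condition number ≈120 for the face and is
  singular for the flat-plane degeneracy control. Point-to-point Gram
  matrices cannot express this sliding degeneracy, which is why the
  normal-based form is used.
* **Ground-truth motion** — breathing (sinusoidal translation, default
  0.1 mm at 0.3 Hz along a mostly-superior axis), linear drift, Poisson-
  timed raised-cosine displacement bursts, and a random-walk rotation
  about the head centre whose per-125 ms RMS ball displacement defaults to
  5/30 mm — anchoring the motion scale to the 5 mm outlier cutoff sitting
  at ≈30 standard deviations of inter-frame motion. Pose at t=0 is the
  identity; frames are the head pose applied to the reference.
* **Frames** — ~8 Hz timestamps with Gaussian timing jitter, isotropic
  0.1 mm sensor noise, an optional slowly-oscillating non-rigid bump on a
  contiguous patch (skin/eye motion — the robust criterion's target), a
  contiguous occluded patch, and uniform outliers in the face bounding box
  inflated by 30 mm.
* **Respiration** — gain × breathing latent(t − lag) + noise at 256 Hz.
* **fMRI-like trace** — ground truth averaged per frame window plus seeded
  pose noise, writable in the realignment-parameter dialect.
* **Cohort** — the longitudinal model below with configurable
  coefficients; defaults are the in-scanner motion effects the model is
  built to detect, with time in minutes (the natural unit for per-cent-
  per-minute slopes).

Not modelled: depth-sensor physics beyond Gaussian noise and outliers
(multipath, flying pixels), photorealistic face geometry, non-stationary
breathing, scanner-table vibration. Tests passing on these scenes
demonstrate the estimator mechanics (robustness, observability,
calibration), not performance on any particular camera.

## Longitudinal model

Per-sequence motion scores enter a random-intercept linear mixed model:

    Y_ij = β1 + β2 t_ij + β3 BMI_i + β4 age_i + β5 sex_i
         + β6 t_ij·BMI_i + β7 t_ij·age_i + β8 t_ij·sex_i + b_i + e_ij

with Y motion (mm/s), t minutes from the first acquisition, BMI and age
centred within sample, sex coded with female as the reference level, and
b_i ~ N(0, σ_b²). Estimation delegates to statsmodels' MixedLM (REML by
default); this module's own contract is the design matrix, the coding, and
parameter-recovery behaviour, which the tests verify by confidence-interval
coverage over seeded replicates (200 subjects × 300 one-second samples per
replicate). A singular design raises an error naming the collinear columns.
Coefficients are also reportable as percent of grand-mean motion.
Companion helpers give exact small-sample Wilcoxon signed-rank contrasts,
early-to-late paired Pearson correlations (bins with under 90% availability
discarded), and motion-vs-image-quality correlations.

## Numerical choices and problem sizes

* All lengths mm, times s (model time in minutes in the cohort model),
  angles radians; quaternions scalar-first with no global hemisphere
  convention.
* The relative transform in HPD is `b∘a⁻¹`; symmetry and right-invariance
  hold for either convention.
* Kabsch uses SVD with determinant correction; non-finite solves raise
  rather than propagate NaN.
* Validation problem sizes: ~2000-point references, 50-seed replicate
  sets, 50 s traces for synchronization, 250 s records for MI, 200-shuffle
  permutation nulls, 25–50 mixed-model replicates — sizes at which every
  stochastic assertion holds with comfortable margin while the whole suite
  runs on one CPU in minutes.

## Known limitations

Point-to-point ICP only (no point-to-plane or feature channels); the
anchor assumes pillow-pivot mechanics and can bias other motion regimes;
quaternion averaging assumes small within-window rotations; the MI
estimate saturates for near-deterministic coupling; the camera↔anatomical
mapping and the fMRI realignment itself are inputs, not estimated here.
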