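"""Head-motion summary metrics.

Three metrics summarize a motion trace:

* **motion score** — mean per-second summed head pose difference (HPD) of an
  8 Hz-resampled trace over a scan interval, in mm/s; the scalar used in all
  downstream statistics.
* **motion trace difference (MTD)** — compares two traces of the same session
  (e.g. camera vs fMRI realignment) independently of each method's reference
  pose, by averaging the HPD between corresponding within-method relative
  transforms over all sample pairs.
* **respiration mutual information** — summed mutual information between a
  chest-sensor respiration signal and the 7 motion components (3 translations
  + 4 quaternion components), a sensitivity check for sub-millimetre,
  breathing-coupled head motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import mutual_info_regression

from .geometry import BallModel, RigidTransform
from .trace import MotionTrace, ResampleSpec, resample

__all__ = [
    "MotionScore",
    "RespirationSignal",
    "motion_score",
    "mtd",
    "fmri_frame_average",
    "respiration_mi",
    "MOTION_SCORE_SPEC",
    "MI_RESAMPLE_SPEC",
]

#: Resampling used for motion scoring: slope 0.1 /s, 9-sample window, 8 Hz.
MOTION_SCORE_SPEC = ResampleSpec(window_size=9, slope=0.1, output_rate=8.0)
#: Resampling used before mutual information: slope 0.1 /s, 3-sample window.
MI_RESAMPLE_SPEC = ResampleSpec(window_size=3, slope=0.1, output_rate=8.0)


@dataclass(frozen=True)
class MotionScore:
    """Per-interval motion score in mm/s."""

    value: float
    interval: tuple
    n_seconds_used: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("motion score must be non-negative")


@dataclass
class RespirationSignal:
    """Scalar chest-sensor signal: timestamps (s) and values (sensor units)."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float).reshape(-1)
        self.values = np.asarray(self.values, float).reshape(-1)
        if self.timestamps.size != self.values.size:
            raise ValueError("timestamp/value length mismatch")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("respiration timestamps must be increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite respiration values")


# ----------------------------------------------------------------------


def motion_score(trace: MotionTrace, interval, ball: BallModel) -> MotionScore:
    """Average per-second head displacement (mm/s) during ``interval``.

    The trace is resampled (triangle slope 0.1 /s, 9-sample window) to head
    poses at exactly 8 Hz anchored at the interval start; the HPD between
    consecutive poses is summed within each 1 s bin, and the score is the
    mean over complete bins inside the interval (a trailing partial bin is
    dropped, not rescaled).
    """
    start, end = float(interval[0]), float(interval[1])
    if end <= start:
        raise ValueError("empty interval")
    v = trace.valid_only()
    if len(v) == 0 or v.times[0] > start or v.times[-1] < end:
        raise ValueError(
            f"interval [{start}, {end}] s not covered by trace support "
            f"[{v.times[0] if len(v) else np.nan}, "
            f"{v.times[-1] if len(v) else np.nan}] s")
    rate = MOTION_SCORE_SPEC.output_rate
    n_out = int(np.floor((end - start) * rate)) + 1
    t_out = start + np.arange(n_out) / rate
    spec = ResampleSpec(window_size=MOTION_SCORE_SPEC.window_size,
                        slope=MOTION_SCORE_SPEC.slope,
                        output_rate=None, output_times=t_out)
    rs = resample(trace, spec)
    from .geometry import hpd_many
    steps = hpd_many(rs.rotations[:-1], rs.translations[:-1],
                     rs.rotations[1:], rs.translations[1:], ball)
    # step k spans [t_k, t_{k+1}); bin by the left endpoint, 1 s bins
    bins = np.floor(rs.times[:-1] - start + 1e-9).astype(int)
    steps_per_bin = int(round(rate))
    n_bins = int(np.floor(end - start + 1e-9))
    sums = []
    for b in range(n_bins):
        mask = bins == b
        if mask.sum() == steps_per_bin:  # complete bins only
            sums.append(steps[mask].sum())
    if not sums:
        raise ValueError("interval too short for a complete 1 s bin")
    return MotionScore(value=float(np.mean(sums)), interval=(start, end),
                       n_seconds_used=len(sums))


def mtd(trace_a: MotionTrace, trace_b: MotionTrace, ball: BallModel,
        *, pair_stride: int = 1) -> float:
    """Motion trace difference (mm) between two traces on shared timestamps.

    For every sample pair i < j the within-method relative transforms
    ``D_ij = T_j ∘ T_i⁻¹`` are formed for each trace and the result is the
    mean HPD between corresponding relative transforms. Because only
    relative transforms enter, the value is independent of each method's
    reference pose, and symmetric in the two traces.

    ``pair_stride`` > 1 subsamples the i-index of the pair set for very long
    traces (an approximation, off by default).
    """
    if len(trace_a) != len(trace_b) or not np.allclose(
            trace_a.times, trace_b.times, atol=1e-9):
        raise ValueError("traces must share timestamps (resample first)")
    both = trace_a.valid & trace_b.valid
    n = int(both.sum())
    if n < 2:
        raise ValueError("need at least 2 common valid samples")
    Ra, ta = trace_a.rotations[both], trace_a.translations[both]
    Rb, tb = trace_b.rotations[both], trace_b.translations[both]
    ii, jj = np.triu_indices(n, k=1)
    if pair_stride > 1:
        keep = (ii % pair_stride) == 0
        ii, jj = ii[keep], jj[keep]

    def rel(R, t):
        # D_ij = T_j ∘ T_i⁻¹ : R = R_j R_iᵀ ; t = t_j − R t_i
        Rd = np.einsum("nij,nkj->nik", R[jj], R[ii])
        td = t[jj] - np.einsum("nij,nj->ni", Rd, t[ii])
        return Rd, td

    Rda, tda = rel(Ra, ta)
    Rdb, tdb = rel(Rb, tb)
    from .geometry import hpd_many
    return float(np.mean(hpd_many(Rda, tda, Rdb, tdb, ball)))


def fmri_frame_average(trace: MotionTrace, frame_times,
                       frame_duration: float) -> MotionTrace:
    """Average the trace over each fMRI frame window.

    ``frame_times`` are frame midpoints (s); each output pose is the uniform
    (slope-0) average of the valid samples within ±frame_duration/2 of the
    midpoint. Frames containing no samples are marked invalid.
    """
    frame_times = np.asarray(frame_times, float).reshape(-1)
    if frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    v = trace.valid_only()
    half = frame_duration / 2.0
    n = frame_times.size
    R = np.tile(np.eye(3), (n, 1, 1))
    t = np.full((n, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, mid in enumerate(frame_times):
        lo = np.searchsorted(v.times, mid - half)
        hi = np.searchsorted(v.times, mid + half, side="right")
        if hi <= lo:
            continue
        spec = ResampleSpec(window_size=hi - lo, slope=0.0,
                            output_rate=None, output_times=np.array([mid]))
        sub = resample(v.subset(np.arange(lo, hi)), spec)
        R[i] = sub.rotations[0]
        t[i] = sub.translations[0]
        ok[i] = True
    return MotionTrace(frame_times, R, t, ok, trace.space_label,
                       trace.reference_note)


def respiration_mi(trace: MotionTrace, resp: RespirationSignal,
                   *, n_neighbors: int = 3, seed: int = 0,
                   min_overlap: float = 60.0):
    """Summed mutual information (nats) between respiration and head motion.

    The trace is resampled (slope 0.1 /s, 3-sample window) to 8 Hz over the
    overlap with the respiration record; the respiration signal is linearly
    interpolated onto the same timestamps. Poses are decomposed into 3
    translation and 4 quaternion components with sequence-wide sign
    continuity (each quaternion flipped if its dot product with the previous
    one is negative). MI between respiration and each of the 7 components is
    estimated with a Kraskov-style k-nearest-neighbour estimator (k=3,
    seeded jitter for ties); per-component negatives are clipped to 0 and
    the total is the sum.

    Returns ``(total, components)`` with ``components`` a dict keyed by
    ``tx, ty, tz, qw, qx, qy, qz``.
    """
    v = trace.valid_only()
    lo = max(v.times[0], resp.timestamps[0])
    hi = min(v.times[-1], resp.timestamps[-1])
    if hi - lo < min_overlap:
        raise ValueError(
            f"only {hi - lo:.1f} s of overlap; need >= {min_overlap} s")
    rate = MI_RESAMPLE_SPEC.output_rate
    t_out = lo + np.arange(int((hi - lo) * rate) + 1) / rate
    spec = ResampleSpec(window_size=MI_RESAMPLE_SPEC.window_size,
                        slope=MI_RESAMPLE_SPEC.slope,
                        output_rate=None, output_times=t_out)
    rs = resample(v, spec)
    y = np.interp(t_out, resp.timestamps, resp.values)

    q = rs.quaternions()
    flips = np.cumprod(np.where(np.einsum("ni,ni->n", q[1:], q[:-1]) < 0,
                                -1.0, 1.0))
    q[1:] *= flips[:, None]
    X = np.column_stack([rs.translations, q])
    names = ["tx", "ty", "tz", "qw", "qx", "qy", "qz"]
    components = {}
    for k, name in enumerate(names):
        col = X[:, k]
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            components[name] = 0.0  # constant series carry no information
            continue
        mi = mutual_info_regression(col.reshape(-1, 1), y,
                                    n_neighbors=n_neighbors,
                                    random_state=seed)[0]
        components[name] = float(max(mi, 0.0))
    total = float(sum(components.values()))
    return total, components
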