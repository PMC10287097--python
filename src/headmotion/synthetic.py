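"""Seeded synthetic scenes for the head-tracking pipeline.

Real in-scanner depth recordings are access-restricted, so every consumer of
the pipeline is exercised against generated data with known ground truth:

* a face-like reference cloud (half-ellipsoid patch with nose and brow
  ridges, raster-ordered like a depth image) whose curvature makes all six
  rigid degrees of freedom observable;
* a continuous ground-truth head pose composed of breathing (sinusoidal
  translation), linear drift, Poisson-timed smooth displacement bursts and a
  small random-walk rotation about the head centre, calibrated so the
  per-125 ms displacement scale matches the conservative 5 mm outlier cutoff
  being ≈30 standard deviations of typical inter-frame motion;
* noisy camera frames at ~8 Hz with timing jitter, sensor noise, a localized
  non-rigid surface perturbation (skin/eye motion), partial occlusion and
  distant uniform outliers;
* a 256 Hz chest-respiration channel coupled to the breathing latent;
* an fMRI-like comparison trace (frame-averaged truth plus pose noise);
* longitudinal cohort samples from the random-intercept mixed model of
  motion versus session time, BMI, age and sex.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import BallModel, DEFAULT_HEAD_RADIUS_MM, RigidTransform, invert
from .metrics import RespirationSignal, fmri_frame_average
from .registration import AnchorPoint, PointCloud
from .trace import MotionTrace

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "make_face_cloud",
    "observability_condition",
    "crop_anterior_patch",
    "head_ball",
    "occiput_anchor",
    "make_truth_trace",
    "camera_times",
    "render_frames",
    "make_respiration",
    "make_fmri_like_trace",
    "make_cohort",
    "DEFAULT_COHORT_BETAS",
]

_ROTWALK_DT = 0.125  # s, one nominal camera interval


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of a synthetic scan scene (units in field names' docs).

    Defaults emulate the acquisition this pipeline targets: ~8 Hz
    non-equidistant camera sampling, 0.1 mm sensor noise, sub-millimetre
    breathing at 0.3 Hz, a 256 Hz respiration channel, and a random-walk
    rotation whose per-125 ms RMS head displacement is 5/30 mm (the outlier
    cutoff sitting at ≈30 standard deviations of inter-frame motion).
    """

    n_points: int = 2000
    camera_rate: float = 8.0            # Hz (mean)
    timing_jitter_sd: float = 0.005     # s
    noise_sd: float = 0.1               # mm
    outlier_fraction: float = 0.0       # of total frame points
    occlusion_fraction: float = 0.0
    nonrigid_amplitude: float = 0.0     # mm
    breathing_amplitude: float = 0.1    # mm
    breathing_frequency: float = 0.3    # Hz
    drift_rate: float = 0.0             # mm/s
    burst_rate: float = 0.0             # events/min
    burst_magnitude: float = 1.0        # mm
    burst_duration: float = 0.4         # s
    rot_walk_step_disp_sd: float = 5.0 / 30.0  # mm RMS per 125 ms step
    resp_rate_hz: float = 256.0
    resp_noise_sd: float = 0.05         # sensor units
    resp_gain: float = 1.0
    resp_lag: float = 0.0               # s
    duration: float = 60.0              # s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("camera_rate", "timing_jitter_sd", "noise_sd",
                     "nonrigid_amplitude", "breathing_amplitude",
                     "breathing_frequency", "drift_rate", "burst_rate",
                     "burst_magnitude", "burst_duration",
                     "rot_walk_step_disp_sd", "resp_rate_hz",
                     "resp_noise_sd", "resp_lag", "duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("outlier_fraction", "occlusion_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        return cls(**json.loads(text))


# ----------------------------------------------------------------------
# reference cloud


def make_face_cloud(config: ScenarioConfig, *, flat: bool = False) -> PointCloud:
    """Reference cloud: a partial-face surface sampled on a depth-image grid.

    A half-ellipsoid dome (~140 × 180 mm footprint, 40 mm depth) carries a
    nose ridge and a brow ridge so that no rigid motion leaves the surface
    invariant. Grid positions get a small seeded jitter (a perfectly regular
    raster would make nearest-neighbour ties systematic). ``flat=True`` is a
    degeneracy control: a plane, for which in-plane sliding is unobservable.
    """
    if config.n_points < 500:
        raise ValueError("need n_points >= 500 for a usable reference")
    fill = np.pi * 0.95 / 4.0
    m = int(np.ceil(np.sqrt(config.n_points / fill)))
    rng = np.random.default_rng(config.seed)
    u, v = np.meshgrid(np.linspace(-1, 1, m), np.linspace(-1, 1, m),
                       indexing="xy")
    du = 2.0 / (m - 1)
    u = u + rng.normal(0.0, 0.25 * du, u.shape)
    v = v + rng.normal(0.0, 0.25 * du, v.shape)
    r2 = u ** 2 + v ** 2
    keep = r2 <= 0.95
    grid_index = np.flatnonzero(keep.ravel())
    u, v = u[keep], v[keep]
    x = 70.0 * u
    y = 90.0 * v
    if flat:
        z = np.zeros_like(x)
    else:
        z = 40.0 * np.sqrt(np.maximum(0.0, 1.0 - (u ** 2 + v ** 2) / 0.95))
        z += 14.0 * np.exp(-(x ** 2 / (2 * 8.0 ** 2)
                             + (y + 15.0) ** 2 / (2 * 12.0 ** 2)))
        z += 5.0 * np.exp(-(x ** 2 / (2 * 28.0 ** 2)
                            + (y - 25.0) ** 2 / (2 * 7.0 ** 2)))
    pts = np.column_stack([x, y, z])
    return PointCloud(pts, grid_index=grid_index, timestamp=0.0)


def observability_condition(points: np.ndarray,
                            radius: float = DEFAULT_HEAD_RADIUS_MM,
                            k_neighbors: int = 12) -> float:
    """Condition number of the 6-DOF surface-registration Gram matrix.

    Surface normals are estimated by local PCA; each point contributes the
    point-to-plane Jacobian row ``[n, p̃ × n]`` with ``p̃`` the centred
    position scaled by the head ``radius`` (so rotations are measured by the
    displacement they cause at head scale). A well-conditioned face patch
    stays below ~1e3; a flat plane is rank-deficient (in-plane sliding and
    in-plane rotation move no point along its normal).
    """
    p = np.asarray(points, float)
    tree = cKDTree(p)
    _, idx = tree.query(p, k=k_neighbors + 1)
    normals = np.empty_like(p)
    for i in range(p.shape[0]):
        nb = p[idx[i]]
        nb = nb - nb.mean(0)
        _, vecs = np.linalg.eigh(nb.T @ nb)
        normals[i] = vecs[:, 0]
    ps = (p - p.mean(0)) / radius
    J = np.hstack([normals, np.cross(ps, normals)])
    G = J.T @ J
    return float(np.linalg.cond(G))


def crop_anterior_patch(cloud: PointCloud, radius_mm: float = 32.0) -> PointCloud:
    """Keep only the points near the face apex (most anterior point) —
    emulates a narrow camera view through the head coil."""
    apex = cloud.points[np.argmax(cloud.points[:, 2])]
    d = np.hypot(cloud.points[:, 0] - apex[0], cloud.points[:, 1] - apex[1])
    return cloud.take(np.flatnonzero(d <= radius_mm))


def head_ball(reference: PointCloud,
              radius: float = DEFAULT_HEAD_RADIUS_MM) -> BallModel:
    """Head ball: centre one head-radius behind the face apex."""
    apex = reference.points[np.argmax(reference.points[:, 2])]
    return BallModel(center=apex - np.array([0.0, 0.0, radius]), radius=radius)


def occiput_anchor(ball: BallModel) -> AnchorPoint:
    """Back-of-head anchor: one radius posterior to the head centre."""
    return AnchorPoint(ball.center - np.array([0.0, 0.0, ball.radius]))


# ----------------------------------------------------------------------
# ground-truth motion


@dataclass
class GroundTruth:
    """Continuous ground-truth head pose and its latent components.

    ``head_pose_at(t)`` is the motion of the head (reference → position at
    time t); rendered frames are that motion applied to the reference.
    ``trace(times)`` returns the registration-convention poses (frame →
    reference, i.e. the inverses) that a tracker should recover.
    """

    config: ScenarioConfig
    ball: BallModel
    walk_times: np.ndarray
    walk_rotvecs: np.ndarray
    burst_times: np.ndarray
    burst_dirs: np.ndarray
    breathing_axis: np.ndarray

    def breathing_latent(self, t) -> np.ndarray:
        c = self.config
        return np.sin(2 * np.pi * c.breathing_frequency * np.asarray(t, float))

    def translation_at(self, t) -> np.ndarray:
        c = self.config
        t = np.atleast_1d(np.asarray(t, float))
        d = (c.breathing_amplitude * self.breathing_latent(t)[:, None]
             * self.breathing_axis)
        d += c.drift_rate * t[:, None] * np.array([0.0, 0.0, 1.0])
        for t0, u in zip(self.burst_times, self.burst_dirs):
            phase = (t - t0) / self.config.burst_duration
            bump = np.where((phase >= 0) & (phase <= 1),
                            0.5 * (1 - np.cos(2 * np.pi * phase)), 0.0)
            d += self.config.burst_magnitude * bump[:, None] * u
        return d

    def rotvec_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        out = np.empty((t.size, 3))
        for k in range(3):
            out[:, k] = np.interp(t, self.walk_times, self.walk_rotvecs[:, k])
        return out

    def head_pose_at(self, t) -> list:
        t = np.atleast_1d(np.asarray(t, float))
        trans = self.translation_at(t)
        rv = self.rotvec_at(t)
        poses = []
        for k in range(t.size):
            rot = RigidTransform.rotation_about(rv[k], self.ball.center)
            poses.append(RigidTransform(rot.rotation,
                                        rot.translation + trans[k]))
        return poses

    def trace(self, times, space_label: str = "camera") -> MotionTrace:
        poses = [invert(p) for p in self.head_pose_at(times)]
        return MotionTrace.from_poses(np.atleast_1d(times), poses,
                                      space_label=space_label,
                                      reference_note="ground truth")

    def event_log(self) -> pd.DataFrame:
        return pd.DataFrame({"burst_time_s": self.burst_times})


def make_truth_trace(config: ScenarioConfig,
                     ball: Optional[BallModel] = None) -> GroundTruth:
    """Build the continuous ground-truth motion for a scenario.

    Components: (i) breathing — sinusoidal translation along a fixed,
    mostly-superior axis; (ii) linear drift along z; (iii) Poisson-timed
    raised-cosine displacement bursts in random directions; (iv) random-walk
    rotation about the head centre whose per-step (125 ms) RMS ball
    displacement equals ``rot_walk_step_disp_sd``. The pose at t = 0 is the
    identity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    if ball is None:
        ball = BallModel(center=np.array([0.0, 0.0, 55.0 - DEFAULT_HEAD_RADIUS_MM]))
    n_steps = int(np.ceil(config.duration / _ROTWALK_DT)) + 1
    walk_times = _ROTWALK_DT * np.arange(n_steps)
    # small rotation δ about the centre displaces the ball by RMS
    # 2r·sqrt((1−cosδ)/5) ≈ (2/√10)·r·δ ; 3 iid rotvec components of sd σ
    # give E‖δ‖² = 3σ², hence σ = target / ((2/√10)·r·√3).
    sigma = config.rot_walk_step_disp_sd / ((2.0 / np.sqrt(10.0))
                                            * ball.radius * np.sqrt(3.0))
    steps = rng.normal(0.0, sigma, (n_steps, 3))
    steps[0] = 0.0
    walk_rotvecs = np.cumsum(steps, axis=0)

    n_bursts = rng.poisson(config.burst_rate * config.duration / 60.0) \
        if config.burst_rate > 0 else 0
    burst_times = np.sort(rng.uniform(0.0, config.duration, n_bursts))
    dirs = rng.normal(size=(n_bursts, 3))
    burst_dirs = dirs / np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True),
                                   1e-12) if n_bursts else dirs.reshape(0, 3)

    axis = np.array([0.0, 0.6, 0.8])  # breathing: mostly along the body axis
    axis /= np.linalg.norm(axis)
    return GroundTruth(config=config, ball=ball, walk_times=walk_times,
                       walk_rotvecs=walk_rotvecs, burst_times=burst_times,
                       burst_dirs=burst_dirs, breathing_axis=axis)


# ----------------------------------------------------------------------
# frame rendering


def camera_times(config: ScenarioConfig) -> np.ndarray:
    """Non-equidistant camera timestamps: nominal rate plus seeded jitter."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    n = int(np.floor(config.duration * config.camera_rate))
    t = np.arange(n) / config.camera_rate
    t = t + rng.normal(0.0, config.timing_jitter_sd, n)
    t[0] = 0.0
    t = np.sort(t)
    # strictness guard for the (measure-zero) tie case
    for k in range(1, n):
        if t[k] <= t[k - 1]:
            t[k] = t[k - 1] + 1e-6
    return t


def render_frames(reference: PointCloud, truth: GroundTruth,
                  config: ScenarioConfig,
                  times: Optional[np.ndarray] = None) -> list:
    """Render the camera frames of a scene.

    Each frame at camera time t is the head pose applied to the (optionally
    non-rigidly perturbed, partially occluded) reference, plus isotropic
    Gaussian sensor noise, plus uniform distant outliers inside the face
    bounding box inflated by 30 mm. Occlusion and the non-rigid bump are
    spatially contiguous patches chosen once per scene; the bump amplitude
    oscillates slowly in time (skin/eye motion).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 43]))
    if times is None:
        times = camera_times(config)
    pts = reference.points
    n = pts.shape[0]
    gidx = reference.grid_index if reference.grid_index is not None \
        else np.arange(n)

    # per-scene occlusion patch
    keep = np.ones(n, dtype=bool)
    if config.occlusion_fraction > 0:
        center = pts[rng.integers(n)]
        d = np.linalg.norm(pts - center, axis=1)
        n_occ = int(round(config.occlusion_fraction * n))
        keep[np.argsort(d)[:n_occ]] = False
    # per-scene non-rigid bump
    if config.nonrigid_amplitude > 0:
        bump_center = pts[rng.integers(n)]
        d2 = np.sum((pts - bump_center) ** 2, axis=1)
        bump_weight = np.exp(-d2 / (2 * 15.0 ** 2))
        bump_phase = rng.uniform(0, 2 * np.pi)
    lo = pts.min(0) - 30.0
    hi = pts.max(0) + 30.0

    frames = []
    poses = truth.head_pose_at(times)
    for t, pose in zip(times, poses):
        p = pts[keep]
        g = gidx[keep]
        if config.nonrigid_amplitude > 0:
            amp = config.nonrigid_amplitude * np.sin(
                2 * np.pi * 0.25 * t + bump_phase)
            p = p + (amp * bump_weight[keep])[:, None] * np.array([0, 0, 1.0])
        p = pose.apply(p)
        if config.noise_sd > 0:
            p = p + rng.normal(0.0, config.noise_sd, p.shape)
        if config.outlier_fraction > 0:
            n_out = int(round(config.outlier_fraction * p.shape[0]
                              / (1.0 - config.outlier_fraction)))
            out = rng.uniform(lo, hi, (n_out, 3))
            p = np.vstack([p, out])
            g = np.concatenate([g, gidx.max() + 1 + np.arange(n_out)])
        frames.append(PointCloud(p, grid_index=g, timestamp=float(t)))
    return frames


# ----------------------------------------------------------------------
# auxiliary channels


def make_respiration(truth: GroundTruth,
                     config: ScenarioConfig) -> RespirationSignal:
    """Chest-sensor channel: scaled, lagged breathing latent plus noise."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 61]))
    n = int(np.floor(config.duration * config.resp_rate_hz))
    t = np.arange(n) / config.resp_rate_hz
    values = config.resp_gain * truth.breathing_latent(t - config.resp_lag)
    if config.resp_noise_sd > 0:
        values = values + rng.normal(0.0, config.resp_noise_sd, n)
    return RespirationSignal(t, values)


def make_fmri_like_trace(truth: GroundTruth, config: ScenarioConfig,
                         frame_duration: float = 0.53,
                         noise_sd_pose: float = 0.0,
                         t0: float = 0.0) -> MotionTrace:
    """fMRI-realignment-like comparison trace.

    The ground truth (sampled densely at 32 Hz) is averaged over consecutive
    frame windows; optional small pose noise (``noise_sd_pose`` mm on the
    translation, the same magnitude as head-surface displacement on the
    rotation) emulates realignment error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 71]))
    n_frames = int(np.floor((config.duration - t0) / frame_duration))
    mids = t0 + (np.arange(n_frames) + 0.5) * frame_duration
    dense_t = np.arange(0.0, config.duration, 1.0 / 32.0)
    dense = truth.trace(dense_t)
    out = fmri_frame_average(dense, mids, frame_duration)
    if noise_sd_pose > 0:
        rot_sd = noise_sd_pose / DEFAULT_HEAD_RADIUS_MM
        for i in range(len(out)):
            if not out.valid[i]:
                continue
            dR = Rotation.from_rotvec(rng.normal(0, rot_sd, 3)).as_matrix()
            out.rotations[i] = dR @ out.rotations[i]
            out.translations[i] = out.translations[i] + rng.normal(
                0, noise_sd_pose, 3)
    out.space_label = "camera"
    out.reference_note = "synthetic fMRI-like realignment"
    return out


# ----------------------------------------------------------------------
# cohort generator (longitudinal mixed model)

#: Fixed effects (intercept; time; BMI; age; sex[male]; time×BMI; time×age;
#: time×sex[male]) with time in minutes, motion in mm/s. Non-intercept values
#: follow the longitudinal in-scanner motion effects this model is built to
#: detect (≈0.6 %/min time slope, BMI and age cross-sections, male-slower
#: time interaction); the intercept is the grand-mean motion level.
DEFAULT_COHORT_BETAS = (0.29, 0.001751, 0.004397, 0.002077, 0.0089,
                        0.000060, 0.000002, -0.000199)


def make_cohort(n_subjects: int = 200, n_timepoints: int = 300,
                betas=DEFAULT_COHORT_BETAS,
                sd_random_intercept: float = 0.05, sd_noise: float = 0.1,
                seed: int = 0) -> pd.DataFrame:
    """Cohort table for the longitudinal model.

    Per subject: BMI ~ N(26, 4²), age ~ N(55, 14²) (centred within sample
    before use), sex ~ Bernoulli(½) with female as reference level, a random
    intercept b_i ~ N(0, sd²); per 1 s sampling point j (t in minutes):

        Y_ij = β1 + β2·t + β3·BMI_c + β4·age_c + β5·male
             + β6·t·BMI_c + β7·t·age_c + β8·t·male + b_i + e_ij
    """
    rng = np.random.default_rng(seed)
    b1, b2, b3, b4, b5, b6, b7, b8 = betas
    bmi = rng.normal(26.0, 4.0, n_subjects)
    age = rng.normal(55.0, 14.0, n_subjects)
    male = rng.integers(0, 2, n_subjects)
    bmi_c = bmi - bmi.mean()
    age_c = age - age.mean()
    b_i = rng.normal(0.0, sd_random_intercept, n_subjects)
    t = np.arange(n_timepoints) / 60.0  # 1 s sampling, minutes
    rows = []
    for i in range(n_subjects):
        e = rng.normal(0.0, sd_noise, n_timepoints)
        y = (b1 + b2 * t + b3 * bmi_c[i] + b4 * age_c[i] + b5 * male[i]
             + b6 * t * bmi_c[i] + b7 * t * age_c[i] + b8 * t * male[i]
             + b_i[i] + e)
        rows.append(pd.DataFrame({
            "subject_id": f"sub-{i:04d}",
            "time": t,
            "motion": y,
            "bmi_centered": bmi_c[i],
            "age_centered": age_c[i],
            "sex": "male" if male[i] else "female",
        }))
    return pd.concat(rows, ignore_index=True)
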