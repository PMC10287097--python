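"""Motion-trace data model and post-processing.

A motion trace is a time-stamped sequence of head poses (rigid transforms
relative to a reference pose). Camera sampling is non-equidistant, so
downstream metrics first resample the trace onto an equidistant grid with a
sliding triangular-weight window applied directly to the translation vectors
and (sign-aligned) quaternions. Clock offsets between acquisition systems are
recovered by minimizing the reference-free motion trace difference over a
bounded search window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from .geometry import BallModel, RigidTransform, compose, invert

__all__ = [
    "MotionTrace",
    "ResampleSpec",
    "SequenceTable",
    "SyncResult",
    "resample",
    "synchronize",
    "map_to_space",
    "annotate",
]


@dataclass
class MotionTrace:
    """Time-ordered rigid poses: ``times`` (s), stacked ``rotations``
    (N,3,3), ``translations`` (N,3) in mm, and a per-sample ``valid`` flag.

    Timestamps must be strictly increasing. Invalid samples may hold NaN
    translations; every consumer skips them.
    """

    times: np.ndarray
    rotations: np.ndarray
    translations: np.ndarray
    valid: Optional[np.ndarray] = None
    space_label: str = "camera"
    reference_note: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float).reshape(-1)
        n = self.times.size
        self.rotations = np.asarray(self.rotations, float).reshape(n, 3, 3)
        self.translations = np.asarray(self.translations, float).reshape(n, 3)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, bool).reshape(n)
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_poses(cls, times, poses: Sequence[RigidTransform], **kw) -> "MotionTrace":
        R = np.stack([p.rotation for p in poses])
        t = np.stack([p.translation for p in poses])
        return cls(np.asarray(times, float), R, t, **kw)

    def pose(self, i: int) -> RigidTransform:
        return RigidTransform(self.rotations[i], self.translations[i])

    def poses(self) -> list:
        return [self.pose(i) for i in range(len(self))]

    def subset(self, mask) -> "MotionTrace":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return MotionTrace(self.times[idx], self.rotations[idx],
                           self.translations[idx], self.valid[idx],
                           self.space_label, self.reference_note)

    def valid_only(self) -> "MotionTrace":
        return self.subset(self.valid)

    def shifted(self, offset: float) -> "MotionTrace":
        """Same poses with ``offset`` seconds added to every timestamp."""
        return MotionTrace(self.times + offset, self.rotations,
                           self.translations, self.valid,
                           self.space_label, self.reference_note)

    def quaternions(self) -> np.ndarray:
        """(N, 4) scalar-first quaternions, no sign convention applied."""
        q = Rotation.from_matrix(self.rotations).as_quat()  # (x,y,z,w)
        return np.column_stack([q[:, 3], q[:, :3]])

    def start(self) -> float:
        return float(self.times[self.valid][0])

    def end(self) -> float:
        return float(self.times[self.valid][-1])


@dataclass(frozen=True)
class ResampleSpec:
    """Triangular sliding-window resampling parameters.

    ``window_size`` counts samples (the window is the nearest valid samples
    to each output time — the input is non-equidistant, so a fixed time span
    would hold a varying sample count). ``slope`` is the triangle slope in
    1/s: weight = max(0, 1 − slope·|Δt|), renormalized; slope 0 is a plain
    average over the window. Output times come from ``output_rate`` (Hz,
    grid anchored at the first valid sample) or are given explicitly.
    """

    window_size: int = 9
    slope: float = 0.1
    output_rate: Optional[float] = 8.0
    output_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.output_times is None and self.output_rate is None:
            raise ValueError("need output_rate or output_times")


@dataclass
class SequenceTable:
    """Scan-sequence intervals: rows of (name, start_s, end_s), non-overlapping."""

    names: list
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, float).reshape(-1)
        self.ends = np.asarray(self.ends, float).reshape(-1)
        if not (len(self.names) == self.starts.size == self.ends.size):
            raise ValueError("sequence table column length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("sequence end must be after start")
        order = np.argsort(self.starts)
        for a, b in zip(order[:-1], order[1:]):
            if self.starts[b] < self.ends[a]:
                raise ValueError(
                    f"sequences {self.names[a]!r} and {self.names[b]!r} overlap")

    def __len__(self) -> int:
        return len(self.names)

    def rows(self):
        return list(zip(self.names, self.starts, self.ends))


# ----------------------------------------------------------------------
# resampling


def _window_indices(times: np.ndarray, t_out: float, k: int):
    """Indices of the k samples of ``times`` (sorted) nearest to ``t_out``."""
    n = times.size
    j = np.searchsorted(times, t_out)
    lo, hi = j, j  # window is times[lo:hi]
    while hi - lo < k:
        take_left = hi >= n or (lo > 0 and
                                t_out - times[lo - 1] <= times[hi] - t_out)
        if take_left:
            lo -= 1
        else:
            hi += 1
    return lo, hi


def resample(trace: MotionTrace, spec: ResampleSpec) -> MotionTrace:
    """Resample a trace with a triangular sliding window.

    For each output time the ``window_size`` nearest valid samples are
    averaged: translations by a weighted arithmetic mean, rotations by a
    weighted mean of quaternions sign-aligned to the window's first sample,
    then renormalized. Windows at the trace edges are asymmetric (they still
    use the nearest ``window_size`` samples), which sacrifices exact
    linear-signal preservation there.
    """
    v = trace.valid_only()
    n = len(v)
    if n < spec.window_size:
        raise ValueError(
            f"{n} valid samples but window_size={spec.window_size}")
    if spec.output_times is not None:
        t_out = np.asarray(spec.output_times, float).reshape(-1)
    else:
        dt = 1.0 / spec.output_rate
        n_out = int(np.floor((v.times[-1] - v.times[0]) / dt)) + 1
        t_out = v.times[0] + dt * np.arange(n_out)

    quats = v.quaternions()
    R_out = np.empty((t_out.size, 3, 3))
    t_mm = np.empty((t_out.size, 3))
    q_buf = np.empty((t_out.size, 4))
    for i, tau in enumerate(t_out):
        lo, hi = _window_indices(v.times, tau, spec.window_size)
        dtw = np.abs(v.times[lo:hi] - tau)
        w = np.maximum(0.0, 1.0 - spec.slope * dtw)
        ws = w.sum()
        if ws <= 0:
            raise ValueError(
                f"all triangular weights vanish at output time {tau:g} s "
                f"(slope too steep for the window span)")
        w = w / ws
        t_mm[i] = w @ v.translations[lo:hi]
        qw = quats[lo:hi].copy()
        sign = np.where(qw @ qw[0] < 0, -1.0, 1.0)
        q = w @ (qw * sign[:, None])
        q_buf[i] = q / np.linalg.norm(q)
    R_out = Rotation.from_quat(
        np.column_stack([q_buf[:, 1:], q_buf[:, 0]])).as_matrix()
    return MotionTrace(t_out, R_out, t_mm, None,
                       trace.space_label, trace.reference_note)


# ----------------------------------------------------------------------
# synchronization


@dataclass
class SyncResult:
    """Recovered clock offset (seconds) to add to trace_a's timestamps."""

    offset: float
    objective: float
    at_boundary: bool = False


def synchronize(trace_a: MotionTrace, trace_b: MotionTrace,
                max_offset: float = 15.0,
                ball: Optional[BallModel] = None,
                *, grid_step: float = 0.125, rate: float = 8.0,
                spec: Optional[ResampleSpec] = None,
                pair_stride: int = 1) -> SyncResult:
    """Find the clock offset aligning ``trace_a`` to ``trace_b``.

    Minimizes the reference-free motion trace difference (MTD) between
    ``trace_a`` shifted by the candidate offset and ``trace_b``, both
    resampled to common equidistant timestamps, over a coarse grid
    (±``max_offset`` s, step ``grid_step``) followed by bounded scalar
    refinement around the best grid point. The MTD objective makes the
    search insensitive to each method's reference pose.
    """
    from .metrics import mtd  # local import to avoid a cycle

    if ball is None:
        ball = BallModel()
    if spec is None:
        spec = ResampleSpec(window_size=3, slope=0.1, output_rate=rate)

    def objective(offset: float) -> float:
        a = trace_a.shifted(offset)
        lo = max(a.start(), trace_b.start())
        hi = min(a.end(), trace_b.end())
        if hi - lo < spec.window_size / rate:
            return np.inf
        t_common = lo + np.arange(int((hi - lo) * rate) + 1) / rate
        sp = ResampleSpec(window_size=spec.window_size, slope=spec.slope,
                          output_rate=None, output_times=t_common)
        ra = resample(a, sp)
        rb = resample(trace_b, sp)
        return mtd(ra, rb, ball, pair_stride=pair_stride)

    offsets = np.arange(-max_offset, max_offset + grid_step / 2, grid_step)
    vals = np.array([objective(o) for o in offsets])
    if not np.any(np.isfinite(vals)):
        raise ValueError("traces do not overlap within the search window")
    k = int(np.argmin(vals))
    lo_b = offsets[max(k - 1, 0)]
    hi_b = offsets[min(k + 1, offsets.size - 1)]
    res = minimize_scalar(objective, bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": 1e-3})
    best, val = float(res.x), float(res.fun)
    if vals[k] < val:
        best, val = float(offsets[k]), float(vals[k])
    at_boundary = abs(abs(best) - max_offset) < grid_step
    return SyncResult(offset=best, objective=val, at_boundary=at_boundary)


# ----------------------------------------------------------------------
# space mapping and annotation


def map_to_space(trace: MotionTrace, mapping: RigidTransform,
                 new_label: str = "anatomical") -> MotionTrace:
    """Express the trace in another coordinate system.

    Poses are space-relative motions, not points, so each pose T becomes the
    conjugation ``mapping ∘ T ∘ mapping⁻¹``; timestamps are unchanged.
    """
    M, Mi = mapping, invert(mapping)
    R = np.einsum("ij,njk,kl->nil", M.rotation, trace.rotations, Mi.rotation)
    # t' = M.R @ (T.R @ Mi.t + T.t) + M.t
    t = (np.einsum("ij,njk,k->ni", M.rotation, trace.rotations, Mi.translation)
         + trace.translations @ M.rotation.T + M.translation)
    return MotionTrace(trace.times, R, t, trace.valid.copy(),
                       new_label, trace.reference_note)


def annotate(trace: MotionTrace, table: SequenceTable) -> dict:
    """Split a trace by scan sequence.

    Each sample falls into at most one ``[start, end)`` interval; samples
    outside every interval are collected under the ``"break"`` key.
    """
    labels = np.full(len(trace), "break", dtype=object)
    for name, start, end in table.rows():
        labels[(trace.times >= start) & (trace.times < end)] = name
    out = {}
    for name in list(table.names) + ["break"]:
        mask = labels == name
        out[name] = trace.subset(mask)
    return out
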