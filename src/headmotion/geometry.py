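"""Rigid-transform algebra and the head pose difference (HPD) metric.

All lengths are millimetres, times seconds, angles radians. A head pose is a
rigid transform mapping a frame's camera coordinates into the reference
coordinate system: ``p_out = rotation @ p + translation``.

The HPD between two poses is the root-mean-square displacement, over a ball
modelling the head, induced by the relative transform between them (Jenkinson's
RMS deviation for rigid transformations). It collapses the six rigid degrees
of freedom into a single millimetre-valued distance that weights rotation by
the lever arms actually present inside the head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "BallModel",
    "DEFAULT_HEAD_RADIUS_MM",
    "compose",
    "invert",
    "to_quaternion",
    "from_quaternion",
    "hpd",
    "hpd_many",
]

#: Population-average distance from the face surface to the head centre.
DEFAULT_HEAD_RADIUS_MM = 82.5

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``p -> rotation @ p + translation`` (mm).

    ``rotation`` must be a proper orthogonal 3x3 matrix (checked at
    construction within 1e-9 unless ``validate=False`` is passed via
    :meth:`unchecked`).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max |R^T R - I| = {err:g})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # ------------------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation given as axis*angle vector (radians)."""
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, dtype=float))

    @classmethod
    def rotation_about(cls, rotvec, pivot) -> "RigidTransform":
        """Rotation by ``rotvec`` about an axis through ``pivot`` (mm)."""
        R = Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix()
        pivot = np.asarray(pivot, dtype=float)
        return cls(R, pivot - R @ pivot)

    # ------------------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (np.abs(self.rotation - other.rotation).max() <= tol
                and np.abs(self.translation - other.translation).max() <= tol)


@dataclass(frozen=True)
class BallModel:
    """Head model for displacement metrics: a ball of ``radius`` mm at
    ``center`` (anatomical/scanner coordinates, mm)."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = DEFAULT_HEAD_RADIUS_MM

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite ball center")
        if not self.radius > 0:
            raise ValueError("ball radius must be positive")
        object.__setattr__(self, "center", c)


# ----------------------------------------------------------------------
# transform algebra


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``a ∘ b``:  (a∘b)(p) = a(b(p))."""
    return RigidTransform(a.rotation @ b.rotation,
                          a.rotation @ b.translation + a.translation)


def invert(t: RigidTransform) -> RigidTransform:
    Rt = t.rotation.T
    return RigidTransform(Rt, -Rt @ t.translation)


def to_quaternion(t: RigidTransform) -> np.ndarray:
    """Unit quaternion of the rotation part, scalar-first ``(w, x, y, z)``.

    No hemisphere convention is imposed; sign continuity along sequences is
    the caller's concern (see :mod:`headmotion.trace`).
    """
    q = Rotation.from_matrix(t.rotation).as_quat()  # scipy: (x, y, z, w)
    return np.array([q[3], q[0], q[1], q[2]])


def from_quaternion(q, translation=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build a transform from a scalar-first quaternion (normalized here)."""
    q = np.asarray(q, dtype=float).reshape(4)
    n = np.linalg.norm(q)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("degenerate quaternion")
    w, x, y, z = q / n
    R = Rotation.from_quat([x, y, z, w]).as_matrix()
    return RigidTransform(R, np.asarray(translation, dtype=float))


# ----------------------------------------------------------------------
# head pose difference


def hpd(a: RigidTransform, b: RigidTransform, ball: BallModel) -> float:
    """RMS displacement (mm) over ``ball`` of the relative transform b∘a⁻¹.

    With ``D = b ∘ a⁻¹``, ``A = D.rotation − I`` and ``c = ball.center``::

        hpd² = (radius²/5) · tr(AᵀA) + ‖D.translation + A·c‖²

    which is exactly the mean squared displacement ``E‖D(p) − p‖²`` for ``p``
    uniform in the ball. Symmetric in its arguments and invariant to
    right-composition of both poses by a common transform (a change of the
    reference pose).
    """
    D = compose(b, invert(a))
    A = D.rotation - np.eye(3)
    off = D.translation + A @ ball.center
    val = (ball.radius ** 2 / 5.0) * np.trace(A.T @ A) + off @ off
    return float(np.sqrt(max(val, 0.0)))


def hpd_many(Ra: np.ndarray, ta: np.ndarray, Rb: np.ndarray, tb: np.ndarray,
             ball: BallModel) -> np.ndarray:
    """Vectorized :func:`hpd` over stacked pose arrays.

    Parameters are ``(N, 3, 3)`` rotations and ``(N, 3)`` translations of the
    two pose sequences; returns ``(N,)`` displacements in mm.
    """
    Ra = np.asarray(Ra, float)
    Rb = np.asarray(Rb, float)
    ta = np.asarray(ta, float)
    tb = np.asarray(tb, float)
    # D = b ∘ a⁻¹ :  R = Rb Raᵀ, t = tb − R ta
    R = np.einsum("nij,nkj->nik", Rb, Ra)
    t = tb - np.einsum("nij,nj->ni", R, ta)
    A = R - np.eye(3)
    off = t + np.einsum("nij,j->ni", A, ball.center)
    val = (ball.radius ** 2 / 5.0) * np.einsum("nij,nij->n", A, A) \
        + np.einsum("ni,ni->n", off, off)
    return np.sqrt(np.maximum(val, 0.0))
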