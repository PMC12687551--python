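"""Rigid transforms and the tibiofemoral joint pose.

The joint pose describes the femoral component frame K_f relative to the
tibial insert frame K_t.  Coordinates follow a right-handed convention for a
right knee: +X anterior, +Y proximal (tibial longitudinal axis), +Z lateral.
Flexion is prescribed; the five free degrees of freedom are the three
translations (AP, SI, ML) and the varus-valgus and internal-external
rotations.  The rotation is composed joint-coordinate style:
flexion (about Z) -> varus-valgus (about the flexed X axis) -> IE (about the
resulting Y axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RigidTransform", "JointPose", "rot_x", "rot_y", "rot_z"]


def rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    u = axis / n
    K = np.array([[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: q -> R @ q + t (lengths in mm)."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0.0:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def translation(cls, v) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(v, dtype=float))

    @classmethod
    def rotation(cls, axis, angle_deg: float, pivot=None) -> "RigidTransform":
        """Rotation about ``axis`` through ``pivot`` (default: the origin)."""
        R = _axis_angle_matrix(axis, np.deg2rad(angle_deg))
        if pivot is None:
            t = np.zeros(3)
        else:
            p = np.asarray(pivot, dtype=float)
            t = p - R @ p
        return cls(R, t)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.R, np.eye(3), atol=1e-12)
            and np.allclose(self.t, 0.0, atol=1e-12)
        )


@dataclass(frozen=True)
class JointPose:
    """Pose of the femoral frame K_f in the tibial frame K_t.

    ``flexion_deg`` is the prescribed (rheonomic) degree of freedom; the other
    five are free and solved for by the equilibrium solver.  Angles in
    degrees, translations in mm.
    """

    flexion_deg: float = 0.0
    vv_deg: float = 0.0   # varus-valgus (rotation about the flexed AP axis)
    ie_deg: float = 0.0   # internal-external (rotation about the femoral SI axis)
    ap_mm: float = 0.0    # +anterior translation of the femoral origin
    si_mm: float = 0.0    # +superior
    ml_mm: float = 0.0    # +lateral (right knee)

    @property
    def R(self) -> np.ndarray:
        return (
            rot_z(np.deg2rad(self.flexion_deg))
            @ rot_x(np.deg2rad(self.vv_deg))
            @ rot_y(np.deg2rad(self.ie_deg))
        )

    @property
    def t(self) -> np.ndarray:
        return np.array([self.ap_mm, self.si_mm, self.ml_mm])

    def transform(self) -> RigidTransform:
        return RigidTransform(self.R, self.t)

    # -- free-DOF vector interface used by the solver -----------------------
    # x = [ap, si, ml, vv_rad * ROT_SCALE, ie_rad * ROT_SCALE]
    ROT_SCALE = 50.0  # mm per radian; conditions the rotational coordinates

    def free_vector(self) -> np.ndarray:
        s = self.ROT_SCALE
        return np.array(
            [
                self.ap_mm,
                self.si_mm,
                self.ml_mm,
                np.deg2rad(self.vv_deg) * s,
                np.deg2rad(self.ie_deg) * s,
            ]
        )

    def with_free_vector(self, x, flexion_deg=None) -> "JointPose":
        s = self.ROT_SCALE
        return replace(
            self,
            flexion_deg=self.flexion_deg if flexion_deg is None else flexion_deg,
            ap_mm=float(x[0]),
            si_mm=float(x[1]),
            ml_mm=float(x[2]),
            vv_deg=float(np.rad2deg(x[3] / s)),
            ie_deg=float(np.rad2deg(x[4] / s)),
        )

    def apply(self, points) -> np.ndarray:
        return self.transform().apply(points)
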