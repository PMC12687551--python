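"""Penalty contact between the parametric condyles and tibial dishes.

Each compartment is a closed-form interference query: the condyle surface is
the envelope of spheres (radius = frontal radius) along the sagittal guide
curve, the dish is a spherical cup, so penetration is

    depth = max_g |g - c| + r_frontal - R_dish

over guide points g, with the maximiser available in closed form per arc.
The normal force follows a Hertz-type penalty law  F = k_c * depth**(3/2)
with potential (2/5) k_c depth**(5/2); contact is frictionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import ImplantGeometry
from .kinematics import JointPose, RigidTransform

__all__ = [
    "CompartmentContact",
    "ContactState",
    "penetration",
    "contact_force",
    "contact_energy",
    "DEFAULT_K_C",
]

# Default penalty stiffness (N / mm^1.5): ~1 kN at ~0.5 mm penetration.
DEFAULT_K_C = 3000.0


@dataclass(frozen=True)
class CompartmentContact:
    """Contact of one condyle/dish pair, in the tibial frame."""

    side: str
    depth: float = 0.0                 # mm, >= 0
    point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.zeros(3))
    force: float = 0.0                 # N, along +normal on the femur
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cup_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def in_contact(self) -> bool:
        return self.depth > 0.0


@dataclass(frozen=True)
class ContactState:
    medial: CompartmentContact
    lateral: CompartmentContact
    force_on_tibia: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torque_on_tibia: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def compartments(self):
        return (self.medial, self.lateral)

    @property
    def axial_force(self) -> float:
        """Axial contact force on the tibia (magnitude), SI component."""
        return float(abs(self.force_on_tibia[1]))

    @property
    def total_normal_force(self) -> float:
        return self.medial.force + self.lateral.force


def _femoral_world(pose: JointPose, geometry: ImplantGeometry) -> RigidTransform:
    """Transform from femoral component coordinates to the evaluation frame.

    Without mounts the evaluation frame is K_t and the transform is the pose
    itself.  With mounts (geometry-shift route) evaluation happens in the
    tibial bone frame: the bone-relative pose is recovered by conjugating the
    implant-relative pose with the mount transforms.
    """
    X = pose.transform()
    if geometry.mount_f is None and geometry.mount_t is None:
        return X
    T_f = geometry.mount_f or RigidTransform.identity()
    T_t = geometry.mount_t or RigidTransform.identity()
    B = T_t @ X @ T_f.inverse()      # femoral bone frame in tibial bone frame
    return B @ T_f                   # femoral component coords -> tibial bone frame


def _dish_center_world(geometry: ImplantGeometry, side: str) -> np.ndarray:
    return geometry.dish_center_effective(side)


def _deepest_guide_point(condyle, c_xy: np.ndarray):
    """Guide point (sagittal) farthest from the planar cup-center projection."""
    best = None
    for a, rho, lo, hi in condyle.guide_arcs():
        w = a - c_xy
        nw = np.hypot(w[0], w[1])
        if nw < 1e-12:
            theta = 0.5 * (lo + hi)
        else:
            theta = np.arctan2(-w[0], -w[1])
        theta = min(max(theta, lo), hi)
        g = a + rho * np.array([-np.sin(theta), -np.cos(theta)])
        dist = np.hypot(*(g - c_xy))
        if best is None or dist > best[0]:
            best = (dist, g, theta)
    return best[1], best[2]


def penetration(pose: JointPose, geometry: ImplantGeometry) -> ContactState:
    """Geometric interference of both compartments at the given pose.

    Depths are zero when the surfaces are separated; the contact normal lies
    along the line of closest approach and points from the insert into the
    femur (the direction of the push on the femoral component).
    """
    F_w = _femoral_world(pose, geometry)
    F_inv = F_w.inverse()
    comps = {}
    for side, condyle, dish in geometry.compartments():
        c_w = _dish_center_world(geometry, side)
        c_f = F_inv.apply(c_w)
        g_xy, _ = _deepest_guide_point(condyle, c_f[:2])
        g_comp = np.array([g_xy[0], g_xy[1], condyle.ml_offset])
        g_w = F_w.apply(g_comp)
        sep = g_w - c_w
        dist = float(np.linalg.norm(sep))
        depth = dist + condyle.frontal_radius - dish.radius
        # the dish is a downward-opening cap: interference only counts when
        # the condyle sphere sits on the concave side of the cup center
        cap_axis = np.array([0.0, -1.0, 0.0])
        if geometry.mount_t is not None:
            cap_axis = geometry.mount_t.R @ cap_axis
        if depth <= 0.0 or dist < 1e-12 or sep @ cap_axis <= 0.0:
            comps[side] = CompartmentContact(side=side, sphere_center=g_w,
                                             cup_center=c_w)
            continue
        u = sep / dist
        comps[side] = CompartmentContact(
            side=side,
            depth=float(depth),
            point=c_w + dish.radius * u,
            normal=-u,
            sphere_center=g_w,
            cup_center=c_w,
        )
    return ContactState(medial=comps["medial"], lateral=comps["lateral"])


def contact_force(state: ContactState, k_c: float = DEFAULT_K_C) -> ContactState:
    """Apply the penalty law and aggregate the wrench on the tibia."""
    if k_c <= 0.0:
        raise ValueError("penalty stiffness k_c must be positive")
    comps = []
    force = np.zeros(3)
    torque = np.zeros(3)
    for comp in state.compartments():
        if comp.depth < 0.0:
            raise RuntimeError("negative penetration depth")
        f = k_c * comp.depth ** 1.5
        comps.append(replace(comp, force=float(f)))
        if f > 0.0:
            f_tib = -f * comp.normal           # reaction on the tibia
            force += f_tib
            torque += np.cross(comp.point, f_tib)
    return ContactState(
        medial=comps[0], lateral=comps[1],
        force_on_tibia=force, torque_on_tibia=torque,
    )


def contact_energy(state: ContactState, k_c: float = DEFAULT_K_C) -> float:
    """Penalty potential (N*mm): sum of (2/5) k_c depth^(5/2)."""
    if k_c <= 0.0:
        raise ValueError("penalty stiffness k_c must be positive")
    return float(
        sum(0.4 * k_c * comp.depth ** 2.5 for comp in state.compartments())
    )
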