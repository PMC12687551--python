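"""Packaged model fixtures: ligament parameters, synthetic anatomy, geometry.

The ligament stiffness/reference-strain table ships as a CSV data file and is
the single source of those numbers.  Insertion points and implant surfaces
are synthetic: they are anatomically plausible for a right knee with a
bicondylar, PCL-retaining fixed-bearing design, but make no claim of
subject-specific fidelity.  Coordinates are right-handed, +X anterior,
+Y proximal (tibial longitudinal axis), +Z lateral; the tibial origin lies on
the insert dwell-point midline and the femoral origin on the flexion axis
midway between the condyles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import JointPose, RigidTransform
from .ligaments import InextensibleCoupling, LigamentBundle, LigamentSet

__all__ = [
    "FrameDefinitions",
    "CondyleProfile",
    "DishProfile",
    "ImplantGeometry",
    "default_ligament_set",
    "symmetric_ligament_set",
    "synthetic_insertions",
    "parametric_geometry",
    "export_stl",
    "nominal_seating_pose",
    "packaged_table",
]


# --------------------------------------------------------------------------
# coordinate frames


@dataclass(frozen=True)
class FrameDefinitions:
    """Body-fixed implant frames K_f (femoral) and K_t (tibial insert).

    Axis semantics: AP = +X (anterior), SI = +Y (proximal; the tibial
    longitudinal/mechanical axis), ML = +Z (lateral, right knee).  The
    flexion axis is the femoral Z axis.
    """

    origin_f: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes_f: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin_t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes_t: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        for name in ("axes_f", "axes_t"):
            A = np.asarray(getattr(self, name), float).reshape(3, 3)
            if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
                raise ValueError(f"{name}: axis triad must be orthonormal")
            if np.linalg.det(A) < 0.0:
                raise ValueError(f"{name}: axis triad must be right-handed")
            object.__setattr__(self, name, A)
        for name in ("origin_f", "origin_t"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), float).reshape(3)
            )

    def resolve_axis(self, axis: str, component: str = "tibial") -> np.ndarray:
        """Unit vector for an anatomical axis name in the component's frame."""
        A = self.axes_f if component == "femoral" else self.axes_t
        idx = {"AP": 0, "SI": 1, "ML": 2, "long": 1}.get(axis)
        if idx is None:
            raise ValueError(f"unknown anatomical axis {axis!r}")
        return A[:, idx]


# --------------------------------------------------------------------------
# parametric implant geometry


@dataclass(frozen=True)
class CondyleProfile:
    """Sagittal two-arc condyle profile swept with a frontal radius.

    The articular surface is the envelope of spheres of radius
    ``frontal_radius`` whose centers run along a sagittal guide curve made of
    two tangent circular arcs: a large distal arc (contacting near extension)
    and a smaller posterior arc (contacting in deep flexion).  ``ml_offset``
    places the guide plane laterally (+) or medially (-).
    """

    distal_radius: float = 36.0      # mm, sagittal surface radius near extension
    posterior_radius: float = 24.0   # mm, sagittal surface radius in flexion
    transition_deg: float = 30.0     # flexion-like angle where the arcs meet
    frontal_radius: float = 22.0     # mm, coronal surface radius
    ml_offset: float = 22.0          # mm, guide-plane Z offset
    theta_min_deg: float = -25.0     # anterior end of the guide arc
    theta_max_deg: float = 125.0     # posterior end of the guide arc
    distal_center: tuple = (0.0, 10.0)  # sagittal (x, y) of the distal arc center

    def __post_init__(self):
        if min(self.distal_radius, self.posterior_radius, self.frontal_radius) <= 0:
            raise ValueError("condyle radii must be positive")
        if self.posterior_radius > self.distal_radius:
            raise ValueError("posterior radius must not exceed the distal radius")
        if self.frontal_radius >= self.posterior_radius:
            raise ValueError("frontal radius must be smaller than both sagittal radii")

    @staticmethod
    def _u(theta: np.ndarray) -> np.ndarray:
        """Radial surface direction: distal at theta=0, posterior for theta>0."""
        return np.stack([-np.sin(theta), -np.cos(theta)], axis=-1)

    def guide_arcs(self):
        """Sagittal guide arcs as (center_xy, rho, theta_lo, theta_hi) in rad."""
        rho_d = self.distal_radius - self.frontal_radius
        rho_p = self.posterior_radius - self.frontal_radius
        a_d = np.asarray(self.distal_center, float)
        th_t = np.deg2rad(self.transition_deg)
        # tangency: posterior arc center lies along the radial direction at
        # the transition angle, so the two arcs meet with a common tangent
        a_p = a_d + (rho_d - rho_p) * np.array([-np.sin(th_t), -np.cos(th_t)])
        return [
            (a_d, rho_d, np.deg2rad(self.theta_min_deg), th_t),
            (a_p, rho_p, th_t, np.deg2rad(self.theta_max_deg)),
        ]

    def guide_point(self, theta_rad: float) -> np.ndarray:
        """Sagittal (x, y) of the guide curve at parameter angle theta."""
        for a, rho, lo, hi in self.guide_arcs():
            if lo - 1e-12 <= theta_rad <= hi + 1e-12:
                return a + rho * np.array([-np.sin(theta_rad), -np.cos(theta_rad)])
        raise ValueError("theta outside the guide arc range")

    def surface_radius(self, theta_rad: float) -> float:
        """Sagittal surface radius of curvature at parameter angle theta."""
        if theta_rad <= np.deg2rad(self.transition_deg):
            return self.distal_radius
        return self.posterior_radius


@dataclass(frozen=True)
class DishProfile:
    """Spherical tibial dish compartment (concave-up cup)."""

    radius: float = 55.0
    center: np.ndarray = field(default_factory=lambda: np.array([0.0, 55.0, 22.0]))

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("dish radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))


@dataclass(frozen=True)
class ImplantGeometry:
    """Two condyles articulating on two dish compartments.

    ``mount_f`` / ``mount_t`` are optional rigid transforms of the component
    within its bone (used by the direct geometry-shift malposition route);
    ``None`` means the component sits at its planned position.
    """

    condyle_medial: CondyleProfile
    condyle_lateral: CondyleProfile
    dish_medial: DishProfile
    dish_lateral: DishProfile
    insert_thickness: float = 9.0
    mount_f: RigidTransform | None = None
    mount_t: RigidTransform | None = None

    def __post_init__(self):
        for c, d in ((self.condyle_medial, self.dish_medial),
                     (self.condyle_lateral, self.dish_lateral)):
            if d.radius <= c.frontal_radius:
                raise ValueError(
                    "dish radius must exceed the condyle frontal radius "
                    "(conforming but non-congruent articulation)"
                )

    def compartments(self):
        return [
            ("medial", self.condyle_medial, self.dish_medial),
            ("lateral", self.condyle_lateral, self.dish_lateral),
        ]

    def dish_center_effective(self, side: str) -> np.ndarray:
        """Dish center in the tibial bone frame, including any mount."""
        d = self.dish_medial if side == "medial" else self.dish_lateral
        return d.center if self.mount_t is None else self.mount_t.apply(d.center)

    def with_mounts(self, mount_f=None, mount_t=None) -> "ImplantGeometry":
        return replace(self, mount_f=mount_f, mount_t=mount_t)


def parametric_geometry(params: dict | None = None) -> ImplantGeometry:
    """Build an ImplantGeometry from a flat parameter dict.

    Recognised keys (all optional, defaults give a symmetric TKR-like
    geometry): distal_radius, posterior_radius, transition_deg,
    frontal_radius, ml_offset, dish_radius, dish_height, insert_thickness;
    any of them may be prefixed ``medial_``/``lateral_`` to differ per side.
    """
    p = dict(params or {})

    def side(prefix, key, default):
        return p.get(prefix + key, p.get(key, default))

    def condyle(prefix, sign):
        return CondyleProfile(
            distal_radius=side(prefix, "distal_radius", 36.0),
            posterior_radius=side(prefix, "posterior_radius", 24.0),
            transition_deg=side(prefix, "transition_deg", 30.0),
            frontal_radius=side(prefix, "frontal_radius", 22.0),
            ml_offset=sign * abs(side(prefix, "ml_offset", 22.0)),
        )

    def dish(prefix, sign):
        r = side(prefix, "dish_radius", 55.0)
        h = side(prefix, "dish_height", None)
        cy = r if h is None else h
        return DishProfile(
            radius=r,
            center=np.array([0.0, cy, sign * abs(side(prefix, "ml_offset", 22.0))]),
        )

    return ImplantGeometry(
        condyle_medial=condyle("medial_", -1.0),
        condyle_lateral=condyle("lateral_", +1.0),
        dish_medial=dish("medial_", -1.0),
        dish_lateral=dish("lateral_", +1.0),
        insert_thickness=p.get("insert_thickness", 9.0),
    )


def nominal_seating_pose(geometry: ImplantGeometry, penetration: float = 0.3) -> JointPose:
    """Extension pose with the condyles seated in the dishes.

    Closed-form for the symmetric default: the distal guide point sits
    ``dish_radius - frontal_radius + penetration`` below the dish center.
    Used as the solver's initial guess.
    """
    c = geometry.condyle_lateral
    d = geometry.dish_lateral
    g = c.guide_point(0.0)          # sagittal (x, y), distal contact
    si = d.center[1] - (d.radius - c.frontal_radius + penetration) - g[1]
    return JointPose(flexion_deg=0.0, si_mm=float(si), ap_mm=float(d.center[0] - g[0]))


# --------------------------------------------------------------------------
# ligament fixtures

_SITES = {
    # name: (p_fem, p_tib) in mm; femoral origin on the flexion axis,
    # tibial origin on the insert dwell-point midline.
    "PCL_a": ((16.0, -24.0, -4.0), (-18.0, -28.0, -4.0)),
    "PCL_po": ((12.0, -24.0, -1.0), (-19.0, -27.0, 1.0)),
    "MCL_a": ((4.0, 6.0, -38.0), (6.0, -40.0, -30.0)),
    "MCL_c": ((0.0, 5.0, -38.0), (2.0, -42.0, -30.0)),
    "MCL_po": ((-5.0, 4.0, -38.0), (-4.0, -40.0, -30.0)),
    "opMCL": ((-14.0, -2.0, -28.0), (-16.0, -22.0, -24.0)),
    "dMCL_a": ((2.0, -4.0, -36.0), (4.0, -14.0, -32.0)),
    "dMCL_po": ((-6.0, -4.0, -36.0), (-4.0, -14.0, -32.0)),
    "LCL_a": ((4.0, 6.0, 38.0), (-4.0, -38.0, 33.0)),
    "LCL_s": ((0.0, 7.0, 38.0), (-6.0, -38.0, 33.0)),
    "LCL_po": ((-5.0, 5.0, 38.0), (-8.0, -37.0, 33.0)),
    "OPL_pr": ((-16.0, -2.0, 10.0), (-18.0, -18.0, -16.0)),
    "OPL_d": ((-16.0, -6.0, 6.0), (-18.0, -20.0, -18.0)),
    "APL": ((-15.0, -3.0, 24.0), (-10.0, -34.0, 30.0)),
    "PCAP_l": ((-17.0, -5.0, 20.0), (-20.0, -10.0, 19.0)),
    "PCAP_m": ((-17.0, -5.0, -20.0), (-20.0, -10.0, -19.0)),
}

# Patellar-ligament coupling: distal patellar apex surrogate (femoral frame,
# tracks the trochlea in the idealised mechanism) to the tibial tuberosity.
_PL_PROXIMAL = np.array([42.0, -10.0, 0.0])
_PL_DISTAL = np.array([30.0, -55.0, 0.0])


def packaged_table() -> pd.DataFrame:
    """The packaged ligament stiffness / reference-strain table."""
    with resources.files("kneesim.data").joinpath("ligament_table.csv").open() as fh:
        return pd.read_csv(fh)


def synthetic_insertions(seed: int = 0, anatomy_scale: float = 1.0) -> dict:
    """Deterministic synthetic insertion layout.

    Returns ``{bundle name: (p_fem, p_tib)}``.  A small seeded jitter
    (sigma = 0.8 mm) keeps the layout loosely sagittal-mirror-plausible but
    not exactly symmetric; ``anatomy_scale`` scales all coordinates.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, (pf, pt) in _SITES.items():
        jf = rng.normal(0.0, 0.8, size=3)
        jt = rng.normal(0.0, 0.8, size=3)
        out[name] = (
            anatomy_scale * (np.asarray(pf) + jf),
            anatomy_scale * (np.asarray(pt) + jt),
        )
    return out


def default_ligament_set(seed: int = 0, anatomy_scale: float = 1.0) -> LigamentSet:
    """The packaged 16-bundle elastic set plus the PL coupling descriptor.

    Stiffnesses, reference strains and the transition parameter come from the
    packaged table; insertion points from the synthetic layout.
    """
    table = packaged_table()
    sites = synthetic_insertions(seed=seed, anatomy_scale=anatomy_scale)
    bundles = []
    for _, row in table.iterrows():
        pf, pt = sites[row["name"]]
        bundles.append(
            LigamentBundle(
                name=row["name"], p_fem=pf, p_tib=pt,
                K=float(row["K"]), eps_ref=float(row["eps_ref"]),
                eps1=float(row["eps1"]),
            )
        )
    coupling = InextensibleCoupling(
        name="PL",
        p_proximal=anatomy_scale * _PL_PROXIMAL,
        p_distal=anatomy_scale * _PL_DISTAL,
        length=float(np.linalg.norm(_PL_PROXIMAL - _PL_DISTAL) * anatomy_scale),
    )
    return LigamentSet(bundles, pl_coupling=coupling)


def symmetric_ligament_set() -> LigamentSet:
    """An exactly sagittal-mirror-symmetric set for symmetry checks.

    Three bundle pairs (collateral, posterior cruciate, posterior capsule)
    mirrored in Z, with representative stiffnesses and reference strains.
    """
    templates = [
        ("COL", (0.0, 6.0, -38.0), (2.0, -40.0, -31.0), 3000.0, 0.06),
        ("PCL", (14.0, -24.0, -4.0), (-18.0, -28.0, -4.0), 2101.2, -0.33),
        ("CAP", (-17.0, -5.0, -20.0), (-20.0, -10.0, -19.0), 5000.0, 0.06),
    ]
    bundles = []
    for name, pf, pt, K, eref in templates:
        pf, pt = np.asarray(pf), np.asarray(pt)
        bundles.append(LigamentBundle(f"{name}_m", pf, pt, K, eref))
        bundles.append(
            LigamentBundle(f"{name}_l", pf * [1, 1, -1], pt * [1, 1, -1], K, eref)
        )
    coupling = InextensibleCoupling(
        "PL", _PL_PROXIMAL, _PL_DISTAL,
        float(np.linalg.norm(_PL_PROXIMAL - _PL_DISTAL)),
    )
    return LigamentSet(bundles, pl_coupling=coupling)


# --------------------------------------------------------------------------
# STL export


def _condyle_mesh(profile: CondyleProfile, n_theta=80, n_psi=24):
    thetas = np.linspace(
        np.deg2rad(profile.theta_min_deg), np.deg2rad(profile.theta_max_deg), n_theta
    )
    psis = np.linspace(np.deg2rad(-60.0), np.deg2rad(60.0), n_psi)
    guide = np.array([profile.guide_point(t) for t in thetas])  # (n_theta, 2)
    u = profile._u(thetas)                                      # sagittal radial dir
    verts = np.empty((n_theta, n_psi, 3))
    for j, psi in enumerate(psis):
        sag = guide + profile.frontal_radius * np.cos(psi) * u
        verts[:, j, 0] = sag[:, 0]
        verts[:, j, 1] = sag[:, 1]
        verts[:, j, 2] = profile.ml_offset + profile.frontal_radius * np.sin(psi)
    return _grid_to_mesh(verts)


def _dish_mesh(dish: DishProfile, cap_deg=26.0, n_a=28, n_b=48):
    alphas = np.linspace(1e-3, np.deg2rad(cap_deg), n_a)
    betas = np.linspace(0.0, 2 * np.pi, n_b)
    verts = np.empty((n_a, n_b, 3))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            d = np.array([np.sin(a) * np.cos(b), -np.cos(a), np.sin(a) * np.sin(b)])
            verts[i, j] = dish.center + dish.radius * d
    return _grid_to_mesh(verts)


def _grid_to_mesh(verts_grid: np.ndarray):
    n, m, _ = verts_grid.shape
    verts = verts_grid.reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        for j in range(m - 1):
            a = i * m + j
            faces.append([a, a + 1, a + m])
            faces.append([a + 1, a + m + 1, a + m])
    return verts, np.asarray(faces)


def export_stl(geometry: ImplantGeometry, path, resolution: int = 1) -> None:
    """Tessellate the parametric surfaces and write a binary STL file.

    The patches are open surfaces (articular faces only), which standard STL
    readers accept; ``resolution`` scales the tessellation density.
    """
    import trimesh

    meshes = []
    for _, condyle, dish in geometry.compartments():
        v, f = _condyle_mesh(condyle, 80 * resolution, 24 * resolution)
        meshes.append(trimesh.Trimesh(vertices=v, faces=f, process=False))
        v, f = _dish_mesh(dish, n_a=28 * resolution, n_b=48 * resolution)
        meshes.append(trimesh.Trimesh(vertices=v, faces=f, process=False))
    mesh = trimesh.util.concatenate(meshes)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path, file_type="stl")
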