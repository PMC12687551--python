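"""Quasi-static equilibrium of the implanted tibiofemoral joint.

The joint has five free degrees of freedom (AP/SI/ML translation,
varus-valgus and internal-external rotation); flexion is prescribed as a
rheonomic constraint and swept from 0 to 80 degrees.  Because the load case
is passive and slow and gravity is neglected, equilibria coincide with
stationary points of the total potential

    E = sum of ligament strain energies
      + penalty contact potential
      + quadriceps cable potential (constant tension * path length)
      + external axial preload potential,

which is minimised per flexion step with an analytic gradient (the gradient
is exactly the negative generalized force, i.e. the residual wrench), then
polished with damped Newton steps on the gradient so that converged residuals
are far below the contract tolerances (0.1 N force, 1 N*mm torque).

The reference configuration is the 0-degree equilibrium under ligament
tension and an axial preload: it is solved with the ligament force magnitudes
pinned at their tabulated reference strains while an external axial force is
calibrated until the axial contact force equals the configured preload; the
zero-strain lengths are then assigned from the chord lengths at that pose,
which makes the pose an exact fixed point of the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .anatomy import (
    FrameDefinitions,
    ImplantGeometry,
    default_ligament_set,
    nominal_seating_pose,
    parametric_geometry,
    symmetric_ligament_set,
)
from .contact import DEFAULT_K_C, contact_force, penetration
from .kinematics import JointPose, RigidTransform, rot_x, rot_z
from .ligaments import LigamentSet, fiber_force, strain_energy, zero_strain_length

__all__ = [
    "SolverSettings",
    "QuadricepsMechanism",
    "JointModel",
    "FlexionSweepResult",
    "SolverError",
    "total_energy",
    "solve_equilibrium",
    "reference_configuration",
    "flexion_sweep",
    "quadriceps_wrench",
    "build_default_model",
    "build_symmetric_model",
]


class SolverError(RuntimeError):
    """Equilibrium search failed; carries the last diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class SolverSettings:
    """Solver and load-case settings.

    ``preload_N`` is the target axial contact force in the reference
    configuration; ``quadriceps_N`` the constant tension of the quadriceps
    cable (zero-cost when the patella option is off).
    """

    preload_N: float = 1000.0
    quadriceps_N: float = 40.0
    flexion_step_deg: float = 1.0
    flexion_max_deg: float = 80.0
    force_tol_N: float = 0.1
    torque_tol_Nmm: float = 1.0
    max_iter: int = 400
    k_c: float = DEFAULT_K_C
    patella: bool = True
    seed: int = 0
    n_restarts: int = 3

    def __post_init__(self):
        if self.force_tol_N <= 0 or self.torque_tol_Nmm <= 0:
            raise ValueError("residual tolerances must be positive")
        if self.flexion_step_deg <= 0:
            raise ValueError("flexion step must be positive")


@dataclass(frozen=True)
class QuadricepsMechanism:
    """Idealised quadriceps-patella mechanism.

    A cable of constant tension runs from a femur-fixed proximal anchor,
    over a femur-fixed circular trochlear pulley (the patellar surface plus
    patellar thickness lumped into one wrap radius), to the tibial
    tuberosity; the distal segment is the inextensible patellar ligament.
    The cable is planar in the sagittal plane.  Attachment coordinates are
    machine-fixed (implant frames): on the physical simulator the quadriceps
    and PL mounts cannot follow a simulated implant malposition.
    """

    anchor_f: np.ndarray = field(default_factory=lambda: np.array([5.0, 150.0]))
    wrap_center_f: np.ndarray = field(default_factory=lambda: np.zeros(2))
    wrap_radius: float = 45.0
    tuberosity_t: np.ndarray = field(default_factory=lambda: np.array([30.0, -55.0, 0.0]))
    tension: float = 40.0

    def __post_init__(self):
        object.__setattr__(self, "anchor_f", np.asarray(self.anchor_f, float).reshape(2))
        object.__setattr__(self, "wrap_center_f", np.asarray(self.wrap_center_f, float).reshape(2))
        object.__setattr__(self, "tuberosity_t", np.asarray(self.tuberosity_t, float).reshape(3))
        if self.wrap_radius <= 0 or self.tension < 0:
            raise ValueError("wrap radius must be positive and tension non-negative")


def _wrap_length_dir(p: np.ndarray, quad: QuadricepsMechanism):
    """Cable length from anchor to endpoint ``p`` (femoral sagittal coords)
    around the anterior side of the trochlear pulley, and the unit direction
    from ``p`` toward its departure point on the cable."""
    o, r, a = quad.wrap_center_f, quad.wrap_radius, quad.anchor_f
    rel_p, rel_a = p - o, a - o
    d_p, d_a = np.hypot(*rel_p), np.hypot(*rel_a)
    if d_p <= r * 1.01 or d_a <= r * 1.01:
        raise SolverError("quadriceps attachment lies on or inside the pulley")
    chord = a - p
    nc = np.hypot(*chord)
    # signed offset of the pulley center from the directed line p -> a;
    # positive = center on the left; the cable is constrained to the
    # anterior (right-hand) side, so it wraps unless the line clears the
    # pulley anteriorly.
    sd = (chord[0] * (o[1] - p[1]) - chord[1] * (o[0] - p[0])) / nc
    if sd <= -r:
        return nc, chord / nc
    phi_p = np.arctan2(rel_p[1], rel_p[0])
    phi_a = np.arctan2(rel_a[1], rel_a[0])
    alpha_p = np.arccos(r / d_p)
    alpha_a = np.arccos(r / d_a)
    t_p = phi_p + alpha_p               # counter-clockwise (anterior) wrap
    t_a = phi_a - alpha_a
    arc = (t_a - t_p) % (2.0 * np.pi)
    tl_p = np.sqrt(d_p**2 - r**2)
    tl_a = np.sqrt(d_a**2 - r**2)
    tp_point = o + r * np.array([np.cos(t_p), np.sin(t_p)])
    u = (tp_point - p) / tl_p
    return tl_p + tl_a + r * arc, u


def quadriceps_wrench(pose: JointPose, quad: QuadricepsMechanism, tension=None):
    """Force and torque on the tibia from the quadriceps-patella cable.

    The cable applies its pull at the tibial tuberosity, directed toward the
    cable's departure point; the wrench scales linearly with the tension.
    Returns ``(force (3,), torque (3,), cable_length)``.
    """
    Q = quad.tension if tension is None else tension
    R, t = pose.R, pose.t
    p3 = R.T @ (quad.tuberosity_t - t)
    L, u2 = _wrap_length_dir(p3[:2], quad)
    u_w = R @ np.array([u2[0], u2[1], 0.0])
    force = Q * u_w
    torque = np.cross(quad.tuberosity_t, force)
    return force, torque, float(L)


# --------------------------------------------------------------------------
# the joint model


@dataclass
class JointModel:
    """Everything the equilibrium solver needs.

    ``geometry`` may carry mount transforms (geometry-shift malposition
    route), in which case ligament chords are evaluated through the bone
    frames; the solver's pose variable is always the implant-relative pose
    K_f in K_t, on which flexion is prescribed.
    """

    ligset: LigamentSet
    geometry: ImplantGeometry
    frames: FrameDefinitions = field(default_factory=FrameDefinitions)
    quad: Optional[QuadricepsMechanism] = None
    patella_on: bool = True
    k_c: float = DEFAULT_K_C
    F_ext: float = 0.0
    reference_pose: Optional[JointPose] = None

    @property
    def has_mounts(self) -> bool:
        return self.geometry.mount_f is not None or self.geometry.mount_t is not None

    def _mounts(self):
        T_f = self.geometry.mount_f or RigidTransform.identity()
        T_t = self.geometry.mount_t or RigidTransform.identity()
        return T_f, T_t

    def ligament_forces_at(self, pose: JointPose) -> np.ndarray:
        """Per-bundle tensions at an implant-relative pose.

        With geometry mounts the chords run between bone-frame insertion
        points, so the pose is first converted to the bone-relative pose.
        """
        lig = self.ligset
        if not self.has_mounts:
            return lig.forces(pose)
        T_f, T_t = self._mounts()
        B = T_t @ pose.transform() @ T_f.inverse()
        q_fem = lig.P_fem @ B.R.T + B.t
        l = np.linalg.norm(q_fem - lig.P_tib, axis=1)
        return fiber_force((l - lig.l0) / lig.l0, lig.K, lig.eps1)


def _rotation_axes(pose: JointPose):
    """World-frame axes of the free rotational coordinates."""
    phi = np.deg2rad(pose.flexion_deg)
    vv = np.deg2rad(pose.vv_deg)
    Rz = rot_z(phi)
    a_vv = Rz @ np.array([1.0, 0.0, 0.0])
    a_ie = Rz @ rot_x(vv) @ np.array([0.0, 1.0, 0.0])
    return a_vv, a_ie


def _energy_grad(x, flexion_deg, model: JointModel, pinned=False):
    """Total potential and its gradient w.r.t. the free-DOF vector.

    Force points are accumulated as (location, dE/dlocation) pairs; the
    translational gradient is their sum and the rotational gradients are
    moments about the free rotation axes.  ``pinned`` freezes ligament force
    magnitudes at the tabulated reference strains (used while establishing
    the reference configuration, before l0 exists).
    """
    pose = JointPose(flexion_deg=flexion_deg).with_free_vector(x, flexion_deg)
    R, t = pose.R, pose.t
    lig = model.ligset
    E = 0.0
    g_t = np.zeros(3)
    m_vv = 0.0
    m_ie = 0.0
    a_vv, a_ie = _rotation_axes(pose)

    if model.has_mounts:
        T_f, T_t = model._mounts()
        X = pose.transform()
        B = T_t @ X @ T_f.inverse()
        R_lig, t_lig = B.R, B.t
        Rt, tt = T_t.R, T_t.t
    else:
        R_lig, t_lig = R, t
        Rt, tt = None, None

    def add_point(q, dEdq, bone_frame):
        nonlocal g_t, m_vv, m_ie
        if bone_frame and Rt is not None:
            h = Rt.T @ dEdq
            y = Rt.T @ (q - tt)
        else:
            h = dEdq
            y = q
        g_t = g_t + h
        r = y - t
        m_vv += h @ np.cross(a_vv, r)
        m_ie += h @ np.cross(a_ie, r)

    # -- ligaments ---------------------------------------------------------
    if len(lig):
        q_fem = lig.P_fem @ R_lig.T + t_lig
        d = q_fem - lig.P_tib
        l = np.linalg.norm(d, axis=1)
        safe = np.where(l > 1e-12, l, 1.0)
        u = d / safe[:, None]
        if pinned:
            F = fiber_force(lig.eps_ref, lig.K, lig.eps1)
            E += float(F @ l)
        else:
            if not lig.initialized:
                raise SolverError("ligament zero-strain lengths not initialised")
            eps = (l - lig.l0) / lig.l0
            E += float(np.sum(strain_energy(eps, lig.K, lig.eps1, lig.l0)))
            F = fiber_force(eps, lig.K, lig.eps1)
        for i in np.nonzero(F > 0.0)[0]:
            add_point(q_fem[i], F[i] * u[i], bone_frame=True)

    # -- contact -----------------------------------------------------------
    state = penetration(pose, model.geometry)
    for comp in state.compartments():
        if comp.depth > 0.0:
            E += 0.4 * model.k_c * comp.depth**2.5
            dEdq = model.k_c * comp.depth**1.5 * (-comp.normal)
            add_point(comp.sphere_center, dEdq, bone_frame=True)

    # -- quadriceps cable --------------------------------------------------
    if model.patella_on and model.quad is not None and model.quad.tension > 0:
        Q = model.quad.tension
        p3 = R.T @ (model.quad.tuberosity_t - t)
        L, u2 = _wrap_length_dir(p3[:2], model.quad)
        E += Q * L
        u_w = R @ np.array([u2[0], u2[1], 0.0])
        add_point(model.quad.tuberosity_t, Q * u_w, bone_frame=False)

    # -- external axial preload (compressive, through the femoral origin) --
    E += model.F_ext * t[1]
    g_t = g_t + np.array([0.0, model.F_ext, 0.0])

    s = JointPose.ROT_SCALE
    grad = np.array([g_t[0], g_t[1], g_t[2], m_vv / s, m_ie / s])
    return E, grad


def total_energy(pose: JointPose, model: JointModel) -> float:
    """Total potential (N*mm) at a pose of the initialised model."""
    E, _ = _energy_grad(pose.free_vector(), pose.flexion_deg, model)
    return E


def _residuals(grad) -> tuple[float, float]:
    s = JointPose.ROT_SCALE
    return float(np.max(np.abs(grad[:3]))), float(s * np.max(np.abs(grad[3:])))


def _newton_polish(x, flexion_deg, model, pinned, iters=12, tol=1e-8):
    """Damped Newton on the gradient; Hessian by finite differences."""
    h = 1e-5
    for _ in range(iters):
        E0, g0 = _energy_grad(x, flexion_deg, model, pinned)
        if np.max(np.abs(g0)) < tol:
            break
        H = np.empty((5, 5))
        for j in range(5):
            xp = x.copy()
            xp[j] += h
            _, gp = _energy_grad(xp, flexion_deg, model, pinned)
            H[:, j] = (gp - g0) / h
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 1e-9 * np.eye(5), -g0)
        except np.linalg.LinAlgError:
            break
        alpha = 1.0
        for _ in range(8):
            E1, g1 = _energy_grad(x + alpha * step, flexion_deg, model, pinned)
            if E1 <= E0 + 1e-12 * max(1.0, abs(E0)) or np.max(np.abs(g1)) < np.max(np.abs(g0)):
                x = x + alpha * step
                break
            alpha *= 0.5
        else:
            break
    return x


def solve_equilibrium(
    model: JointModel,
    flexion_deg: float,
    warm_start: JointPose,
    settings: SolverSettings | None = None,
    pinned: bool = False,
):
    """Minimise the total potential over the five free DOF at fixed flexion.

    Returns ``(pose, info)`` where ``info`` holds residuals, iteration count
    and a possible degenerate-landscape warning.  Raises ``SolverError`` when
    the residual tolerances cannot be met.
    """
    settings = settings or SolverSettings()
    rng = np.random.default_rng(settings.seed)
    x0 = warm_start.free_vector()
    best = None
    for attempt in range(settings.n_restarts + 1):
        res = minimize(
            _energy_grad,
            x0,
            args=(flexion_deg, model, pinned),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": settings.max_iter, "ftol": 1e-15, "gtol": 1e-10},
        )
        x = _newton_polish(res.x, flexion_deg, model, pinned)
        E, g = _energy_grad(x, flexion_deg, model, pinned)
        rf, rt = _residuals(g)
        cand = (E, x, rf, rt, res.nit)
        if best is None or E < best[0]:
            best = cand
        if rf <= settings.force_tol_N and rt <= settings.torque_tol_Nmm:
            best = cand
            break
        x0 = warm_start.free_vector() + rng.normal(0.0, 0.5, size=5)
    E, x, rf, rt, nit = best
    pose = JointPose(flexion_deg=flexion_deg).with_free_vector(x, flexion_deg)
    state = penetration(pose, model.geometry)
    degenerate = (
        not any(c.in_contact for c in state.compartments())
        and abs(E) < 1e-9
        and rf < 1e-9
    )
    info = {
        "residual_force_N": rf,
        "residual_torque_Nmm": rt,
        "iterations": int(nit),
        "energy": float(E),
        "degenerate": bool(degenerate),
    }
    if not degenerate and (rf > settings.force_tol_N or rt > settings.torque_tol_Nmm):
        raise SolverError(
            f"equilibrium not converged at flexion {flexion_deg:g} deg "
            f"(residuals {rf:.3g} N / {rt:.3g} N*mm)",
            info,
        )
    return pose, info


def reference_configuration(model: JointModel, settings: SolverSettings | None = None):
    """Establish the 0-degree reference configuration.

    For an uninitialised model (reference strains tabulated, l0 unknown):
    solve the pinned-strain equilibrium while calibrating the external axial
    force until the axial contact force matches the configured preload, then
    assign every bundle's zero-strain length from its chord length at the
    converged pose (Eq. inversion l0 = l_ref / (1 + eps_ref)).  For an
    already-initialised model (malposition variants) the stored external
    force is kept and the full equilibrium is solved.

    Returns ``(pose, info)`` and updates the model in place.
    """
    settings = settings or SolverSettings()
    start = model.reference_pose or nominal_seating_pose(model.geometry)
    if model.ligset.initialized:
        pose, info = solve_equilibrium(model, 0.0, start, settings)
        model.reference_pose = pose
        return pose, info

    pose, info = None, None
    for _ in range(25):
        pose, info = solve_equilibrium(model, 0.0, start, settings, pinned=True)
        state = contact_force(penetration(pose, model.geometry), model.k_c)
        err = settings.preload_N - state.axial_force
        if abs(err) < 0.5 * settings.force_tol_N:
            break
        model.F_ext += err
        start = pose
    l_ref = model.ligset.chord_lengths(pose)
    model.ligset = model.ligset.with_l0(zero_strain_length(l_ref, model.ligset.eps_ref))
    model.reference_pose = pose
    return pose, info


@dataclass
class FlexionSweepResult:
    """Trajectory of a passive flexion sweep."""

    flexion_deg: np.ndarray
    poses: list
    contact_states: list
    ligament_forces: np.ndarray        # (n_steps, n_bundles), N
    bundle_names: list
    residual_force_N: np.ndarray
    residual_torque_Nmm: np.ndarray
    warnings: list

    def __len__(self):
        return len(self.flexion_deg)

    @property
    def free_dofs(self) -> np.ndarray:
        return np.array(
            [[p.ap_mm, p.si_mm, p.ml_mm, p.vv_deg, p.ie_deg] for p in self.poses]
        )

    @property
    def axial_force(self) -> np.ndarray:
        return np.array([s.axial_force for s in self.contact_states])


def flexion_sweep(model: JointModel, settings: SolverSettings | None = None) -> FlexionSweepResult:
    """Sweep flexion from 0 to the configured maximum, warm-starting each
    equilibrium from the previous step.  Deterministic for fixed settings."""
    settings = settings or SolverSettings()
    if model.reference_pose is None or not model.ligset.initialized:
        reference_configuration(model, settings)
    angles = np.arange(
        0.0, settings.flexion_max_deg + 0.5 * settings.flexion_step_deg,
        settings.flexion_step_deg,
    )
    poses, states, lig_F, res_f, res_t, warns = [], [], [], [], [], []
    warm = model.reference_pose
    prev = None
    for ang in angles:
        try:
            pose, info = solve_equilibrium(model, float(ang), warm, settings)
        except SolverError as exc:
            raise SolverError(
                f"sweep failed at flexion {ang:g} deg: {exc}", exc.diagnostics
            ) from exc
        state = contact_force(penetration(pose, model.geometry), model.k_c)
        poses.append(pose)
        states.append(state)
        lig_F.append(model.ligament_forces_at(pose))
        res_f.append(info["residual_force_N"])
        res_t.append(info["residual_torque_Nmm"])
        if prev is not None:
            dt = np.abs(pose.t - prev.t)
            dr = np.abs([pose.vv_deg - prev.vv_deg, pose.ie_deg - prev.ie_deg])
            if np.max(dt) > 2.0 or np.max(dr) > 2.0:
                warns.append(
                    f"continuation jump at {ang:g} deg "
                    f"(max {np.max(dt):.2f} mm / {np.max(dr):.2f} deg)"
                )
        prev = pose
        warm = pose
    return FlexionSweepResult(
        flexion_deg=angles,
        poses=poses,
        contact_states=states,
        ligament_forces=np.array(lig_F),
        bundle_names=list(model.ligset.names),
        residual_force_N=np.array(res_f),
        residual_torque_Nmm=np.array(res_t),
        warnings=warns,
    )


# --------------------------------------------------------------------------
# model builders


def build_default_model(
    seed: int = 0,
    patella: bool = True,
    geometry_params: dict | None = None,
    quadriceps_N: float = 40.0,
    k_c: float = DEFAULT_K_C,
) -> JointModel:
    """The packaged synthetic joint model (ligaments, geometry, quadriceps)."""
    return JointModel(
        ligset=default_ligament_set(seed=seed),
        geometry=parametric_geometry(geometry_params),
        quad=QuadricepsMechanism(tension=quadriceps_N),
        patella_on=patella,
        k_c=k_c,
    )


def build_symmetric_model(patella: bool = True, k_c: float = DEFAULT_K_C) -> JointModel:
    """An exactly sagittal-mirror-symmetric model for symmetry oracles."""
    return JointModel(
        ligset=symmetric_ligament_set(),
        geometry=parametric_geometry(),
        quad=QuadricepsMechanism(),
        patella_on=patella,
        k_c=k_c,
    )
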