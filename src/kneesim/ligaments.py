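"""Virtual ligament fibers and the nonlinear force-strain law.

Each ligament bundle is a one-dimensional tension-only force element acting
along the straight chord between an insertion point fixed in the femoral
component frame and one fixed in the tibial insert frame.  The force law is
piecewise: zero when unstrained, quadratic in the toe region
(0 < eps <= 2*eps1) and linear beyond, with C1 continuity at both section
boundaries:

    F(eps) = 0                          eps <= 0
           = K / (4 eps1) * eps**2      0 < eps <= 2 eps1
           = K * (eps - eps1)           eps > 2 eps1

The stiffness K is in newtons per unit strain, so F is in newtons.  Strain is
defined against the zero-strain length l0: eps = (l - l0) / l0.  The
reference strain eps_ref is the strain measured in the reference
configuration (the 0-degree equilibrium), i.e. eps_ref = (l_ref - l0) / l0,
which inverts to l0 = l_ref / (1 + eps_ref).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import JointPose

__all__ = [
    "LigamentBundle",
    "InextensibleCoupling",
    "LigamentSet",
    "fiber_force",
    "fiber_strain",
    "zero_strain_length",
    "strain_energy",
    "ligament_wrench",
    "read_ligament_table",
    "write_ligament_table",
]


# --------------------------------------------------------------------------
# scalar/array force law


def _check_params(K, eps1) -> None:
    if np.any(np.asarray(K) <= 0.0):
        raise ValueError("ligament stiffness K must be positive")
    if np.any(np.asarray(eps1) <= 0.0):
        raise ValueError("transition parameter eps1 must be positive")


def fiber_force(eps, K, eps1=0.03):
    """Tension (N) of a fiber at strain ``eps``.

    Vectorised over any argument.  Slack fibers (eps <= 0) carry exactly zero
    force; the toe region is quadratic up to a strain of 2*eps1 and the law is
    linear above, continuous and once-differentiable at both boundaries.
    """
    _check_params(K, eps1)
    eps, K, eps1 = np.broadcast_arrays(
        np.asarray(eps, dtype=float), np.asarray(K, dtype=float),
        np.asarray(eps1, dtype=float),
    )
    quad = K / (4.0 * eps1) * eps**2
    lin = K * (eps - eps1)
    out = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * eps1, quad, lin))
    return out if out.ndim else float(out)


def fiber_strain(q_fem, q_tib, l0):
    """Engineering strain of the chord between two world-frame points."""
    l0 = np.asarray(l0, dtype=float)
    if np.any(l0 <= 0.0):
        raise ValueError("zero-strain length l0 must be positive")
    d = np.linalg.norm(np.asarray(q_fem, float) - np.asarray(q_tib, float), axis=-1)
    out = (d - l0) / l0
    return out if np.ndim(out) else float(out)


def zero_strain_length(l_ref, eps_ref):
    """Invert the reference-strain definition: l0 = l_ref / (1 + eps_ref)."""
    l_ref = np.asarray(l_ref, dtype=float)
    eps_ref = np.asarray(eps_ref, dtype=float)
    if np.any(eps_ref <= -1.0):
        raise ValueError("reference strain must be greater than -1")
    if np.any(l_ref <= 0.0):
        raise ValueError("reference length must be positive")
    out = l_ref / (1.0 + eps_ref)
    return out if out.ndim else float(out)


def strain_energy(eps, K, eps1=0.03, l0=1.0):
    """Elastic potential (N*mm) stored in a fiber at strain ``eps``.

    The potential is the strain integral of the force law scaled by l0 so
    that dE/dl = F (the solver minimises the sum of these).  Zero for slack
    fibers and continuously differentiable everywhere.
    """
    _check_params(K, eps1)
    if np.any(np.asarray(l0) <= 0.0):
        raise ValueError("zero-strain length l0 must be positive")
    eps, K, eps1, l0 = np.broadcast_arrays(
        np.asarray(eps, dtype=float), np.asarray(K, dtype=float),
        np.asarray(eps1, dtype=float), np.asarray(l0, dtype=float),
    )
    # integral of the quadratic branch: K eps^3 / (12 eps1)
    u_quad = K * eps**3 / (12.0 * eps1)
    # at eps = 2 eps1 the quadratic branch has accumulated (2/3) K eps1^2
    u_lin = K * (2.0 / 3.0 * eps1**2 + 0.5 * ((eps - eps1) ** 2 - eps1**2))
    u = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * eps1, u_quad, u_lin))
    out = l0 * u
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# bundle containers


@dataclass(frozen=True)
class LigamentBundle:
    """One ligament fiber.

    Insertion points are in mm: ``p_fem`` in the femoral component frame K_f,
    ``p_tib`` in the tibial insert frame K_t.  ``l0`` (zero-strain length) is
    unset until the model is initialised at its reference configuration.
    """

    name: str
    p_fem: np.ndarray
    p_tib: np.ndarray
    K: float
    eps_ref: float
    eps1: float = 0.03
    l0: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "p_fem", np.asarray(self.p_fem, float).reshape(3))
        object.__setattr__(self, "p_tib", np.asarray(self.p_tib, float).reshape(3))
        if self.K <= 0.0:
            raise ValueError(f"{self.name}: stiffness K must be positive")
        if self.eps1 <= 0.0:
            raise ValueError(f"{self.name}: eps1 must be positive")
        if self.eps_ref <= -1.0:
            raise ValueError(f"{self.name}: reference strain must exceed -1")
        if self.l0 is not None and self.l0 <= 0.0:
            raise ValueError(f"{self.name}: l0 must be positive")

    @property
    def ligament(self) -> str:
        """Anatomical ligament name (bundle suffix stripped)."""
        return self.name.split("_")[0]


@dataclass(frozen=True)
class InextensibleCoupling:
    """Length-preserving coupling (the patellar ligament).

    Connects the distal patellar apex to the tibial tuberosity; in the
    simulator it is realised as the distal, inextensible segment of the
    quadriceps-patella cable mechanism.
    """

    name: str
    p_proximal: np.ndarray   # patellar apex surrogate, femoral frame (mm)
    p_distal: np.ndarray     # tibial tuberosity, tibial frame (mm)
    length: float            # fixed length (mm)

    def __post_init__(self):
        object.__setattr__(self, "p_proximal", np.asarray(self.p_proximal, float).reshape(3))
        object.__setattr__(self, "p_distal", np.asarray(self.p_distal, float).reshape(3))
        if self.length <= 0.0:
            raise ValueError("coupling length must be positive")


class LigamentSet:
    """Ordered collection of ligament bundles plus the optional PL coupling."""

    def __init__(self, bundles, pl_coupling: InextensibleCoupling | None = None):
        bundles = list(bundles)
        names = [b.name for b in bundles]
        if len(set(names)) != len(names):
            raise ValueError("bundle names must be unique")
        self.bundles = bundles
        self.pl_coupling = pl_coupling
        self._rebuild_arrays()

    def _rebuild_arrays(self):
        b = self.bundles
        self.names = [x.name for x in b]
        self.P_fem = np.array([x.p_fem for x in b]) if b else np.zeros((0, 3))
        self.P_tib = np.array([x.p_tib for x in b]) if b else np.zeros((0, 3))
        self.K = np.array([x.K for x in b])
        self.eps1 = np.array([x.eps1 for x in b])
        self.eps_ref = np.array([x.eps_ref for x in b])
        self.l0 = np.array(
            [np.nan if x.l0 is None else x.l0 for x in b], dtype=float
        )

    def __len__(self):
        return len(self.bundles)

    def __iter__(self):
        return iter(self.bundles)

    def __getitem__(self, name: str) -> LigamentBundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def initialized(self) -> bool:
        return len(self) > 0 and not np.any(np.isnan(self.l0))

    def copy(self) -> "LigamentSet":
        return LigamentSet([replace(b) for b in self.bundles], self.pl_coupling)

    def chord_lengths(self, pose: JointPose) -> np.ndarray:
        q_fem = pose.apply(self.P_fem)
        return np.linalg.norm(q_fem - self.P_tib, axis=1)

    def strains(self, pose: JointPose) -> np.ndarray:
        if not self.initialized:
            raise RuntimeError("zero-strain lengths are not initialised")
        return (self.chord_lengths(pose) - self.l0) / self.l0

    def forces(self, pose: JointPose) -> np.ndarray:
        return fiber_force(self.strains(pose), self.K, self.eps1)

    def with_l0(self, l0: np.ndarray) -> "LigamentSet":
        l0 = np.asarray(l0, dtype=float)
        bundles = [replace(b, l0=float(v)) for b, v in zip(self.bundles, l0)]
        return LigamentSet(bundles, self.pl_coupling)

    def with_insertions(self, P_fem=None, P_tib=None) -> "LigamentSet":
        P_fem = self.P_fem if P_fem is None else np.asarray(P_fem, float)
        P_tib = self.P_tib if P_tib is None else np.asarray(P_tib, float)
        bundles = [
            replace(b, p_fem=pf, p_tib=pt)
            for b, pf, pt in zip(self.bundles, P_fem, P_tib)
        ]
        return LigamentSet(bundles, self.pl_coupling)

    def with_eps_ref(self, eps_ref: np.ndarray) -> "LigamentSet":
        bundles = [
            replace(b, eps_ref=float(e)) for b, e in zip(self.bundles, eps_ref)
        ]
        return LigamentSet(bundles, self.pl_coupling)


def ligament_wrench(pose: JointPose, ligset: LigamentSet, frames=None):
    """Resultant ligament force and torque on the tibia.

    Each taut fiber pulls its tibial insertion toward its femoral insertion
    along the chord; torque is taken about the tibial frame origin.  Returns
    ``(force (3,), torque (3,))`` in N and N*mm.  ``frames`` is accepted for
    interface symmetry; the wrench is always expressed in K_t.
    """
    if not ligset.initialized:
        raise RuntimeError("ligament set must be initialised (l0 set)")
    q_fem = pose.apply(ligset.P_fem)
    d = q_fem - ligset.P_tib
    l = np.linalg.norm(d, axis=1)
    eps = (l - ligset.l0) / ligset.l0
    F = fiber_force(eps, ligset.K, ligset.eps1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(l[:, None] > 0.0, d / np.where(l == 0.0, 1.0, l)[:, None], 0.0)
    f_vec = F[:, None] * u                      # force on tibia, per fiber
    force = f_vec.sum(axis=0)
    torque = np.cross(ligset.P_tib, f_vec).sum(axis=0)
    return force, torque


# --------------------------------------------------------------------------
# table I/O

_COLUMNS = [
    "name", "K", "eps_ref", "eps1",
    "p_fem_x", "p_fem_y", "p_fem_z", "p_tib_x", "p_tib_y", "p_tib_z",
]


def read_ligament_table(path) -> LigamentSet:
    """Read a ligament bundle table (CSV or JSON) with row-level validation."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ligament table is missing columns: {missing}")
    bundles, errors = [], []
    for i, row in df.iterrows():
        try:
            bundles.append(
                LigamentBundle(
                    name=str(row["name"]),
                    p_fem=[row["p_fem_x"], row["p_fem_y"], row["p_fem_z"]],
                    p_tib=[row["p_tib_x"], row["p_tib_y"], row["p_tib_z"]],
                    K=float(row["K"]),
                    eps_ref=float(row["eps_ref"]),
                    eps1=float(row["eps1"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i} ({row.get('name', '?')}): {exc}")
    if errors:
        raise ValueError("invalid ligament table:\n" + "\n".join(errors))
    return LigamentSet(bundles)


def write_ligament_table(ligset: LigamentSet, path) -> None:
    """Write bundle parameters and insertions as CSV (the export format used
    when handing transformed insertion points and recomputed reference
    strains to an external virtual ligament model)."""
    rows = []
    for b in ligset:
        rows.append(
            {
                "name": b.name, "K": b.K, "eps_ref": b.eps_ref, "eps1": b.eps1,
                "p_fem_x": b.p_fem[0], "p_fem_y": b.p_fem[1], "p_fem_z": b.p_fem[2],
                "p_tib_x": b.p_tib[0], "p_tib_y": b.p_tib[1], "p_tib_z": b.p_tib[2],
                "l0": np.nan if b.l0 is None else b.l0,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
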