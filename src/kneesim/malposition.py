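"""Implant malposition via inverse-transformed ligament insertion clusters.

A malposition places an implant component at a rigid transform T relative to
its planned position in the bone.  Two equivalent representations exist:

* geometry shift (the in-body ground truth): the implant surfaces move by T
  while the bone-fixed insertion points stay put;
* insertion shift (the method usable on a physical joint simulator, where
  the mounted implant cannot move): the implant stays put and the insertion
  points on that bone are mapped through T^-1.

After shifting insertions, the chord lengths in the reference configuration
change, so the reference strains must be recomputed from the unchanged
zero-strain lengths: eps_ref = (l_ref - l0) / l0.  The zero-strain length is
a property of the ligament and never changes under malposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import FrameDefinitions, ImplantGeometry
from .kinematics import JointPose, RigidTransform
from .ligaments import LigamentSet

__all__ = [
    "RigidTransform",
    "MalpositionSpec",
    "spec_to_transform",
    "apply_to_insertions",
    "recompute_reference_strains",
    "direct_geometry_malposition",
    "variation_matrix",
]

_COMPONENTS = ("femoral", "tibial")
_MODES = ("translation", "rotation")
_AXES = ("AP", "ML", "SI", "long")


@dataclass(frozen=True)
class MalpositionSpec:
    """One implant position variation.

    ``magnitude`` is signed: mm for translations (positive = anterior for AP,
    lateral for ML, superior for SI) and degrees for rotations (positive =
    internal twist of the tibial insert about the tibial longitudinal axis).
    """

    component: str = "femoral"
    mode: str = "translation"
    axis: str = "AP"
    magnitude: float = 0.0
    label: str | None = None

    def __post_init__(self):
        if self.component not in _COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.axis not in _AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.label is None:
            unit = "deg" if self.mode == "rotation" else "mm"
            object.__setattr__(
                self, "label",
                f"{self.component}_{self.mode}_{self.axis}_{self.magnitude:+g}{unit}",
            )

    @property
    def is_identity(self) -> bool:
        return self.magnitude == 0.0


REFERENCE = MalpositionSpec(magnitude=0.0, label="reference")


def spec_to_transform(
    spec: MalpositionSpec,
    frames: FrameDefinitions | None = None,
    pivot=None,
) -> RigidTransform:
    """Rigid transform of the implant relative to its bone.

    Expressed in the component's implant-fixed frame.  Rotations act about
    the resolved anatomical axis through the frame origin (the dwell-point
    midline for the tibial insert); an alternative ``pivot`` may be given.
    """
    frames = frames or FrameDefinitions()
    axis = frames.resolve_axis(spec.axis, spec.component)
    if spec.mode == "translation":
        return RigidTransform.translation(spec.magnitude * axis)
    return RigidTransform.rotation(axis, spec.magnitude, pivot=pivot)


def apply_to_insertions(
    ligset: LigamentSet,
    spec: MalpositionSpec,
    frames: FrameDefinitions | None = None,
    pivot=None,
) -> LigamentSet:
    """Shift the malpositioned component's insertion cluster by the inverse.

    Femoral specs move the femoral insertion points, tibial specs the tibial
    points; the other side is untouched.  For a pure translation by s the
    cluster moves by exactly -s.  The quadriceps/PL attachment points are not
    part of the elastic bundle set and are handled by the study runner.
    """
    T_inv = spec_to_transform(spec, frames, pivot=pivot).inverse()
    if spec.component == "femoral":
        return ligset.with_insertions(P_fem=T_inv.apply(ligset.P_fem))
    return ligset.with_insertions(P_tib=T_inv.apply(ligset.P_tib))


def recompute_reference_strains(
    ligset: LigamentSet, reference_pose: JointPose
) -> LigamentSet:
    """Re-measure reference lengths and update the reference strains.

    The zero-strain length l0 of every bundle is kept fixed (it is a
    ligament property); each bundle's reference length l_ref is measured at
    ``reference_pose`` with the current insertion points and
    eps_ref = (l_ref - l0) / l0.
    """
    if not ligset.initialized:
        raise RuntimeError(
            "zero-strain lengths must be initialised before recomputing "
            "reference strains"
        )
    l_ref = ligset.chord_lengths(reference_pose)
    return ligset.with_eps_ref((l_ref - ligset.l0) / ligset.l0)


def direct_geometry_malposition(
    geometry: ImplantGeometry,
    spec: MalpositionSpec,
    frames: FrameDefinitions | None = None,
    pivot=None,
) -> ImplantGeometry:
    """Transform the implant surfaces instead of the insertions.

    Returns a geometry whose malpositioned component carries a composed
    mount transform; ligaments are untouched.  This is the in-body ground
    truth used as the equivalence oracle for ``apply_to_insertions``.
    """
    T = spec_to_transform(spec, frames, pivot=pivot)
    if spec.component == "femoral":
        prev = geometry.mount_f or RigidTransform.identity()
        return geometry.with_mounts(mount_f=T @ prev, mount_t=geometry.mount_t)
    prev = geometry.mount_t or RigidTransform.identity()
    return geometry.with_mounts(mount_f=geometry.mount_f, mount_t=T @ prev)


def variation_matrix() -> list[MalpositionSpec]:
    """The study's implant position variations plus the reference entry.

    Anterior/posterior shift of the femoral component by +/-3 mm,
    mediolateral shift of the femoral component by +/-3 and +/-6 mm, twist of
    the tibial insert about the tibial longitudinal axis by +/-3 and +/-6
    degrees, and insert thickness variation as superior/inferior translation
    of the insert by +/-1 and +/-2 mm: 14 variants and the identity
    reference.
    """
    specs = [REFERENCE]
    for m in (-3.0, +3.0):
        specs.append(MalpositionSpec("femoral", "translation", "AP", m))
    for m in (-6.0, -3.0, +3.0, +6.0):
        specs.append(MalpositionSpec("femoral", "translation", "ML", m))
    for m in (-6.0, -3.0, +3.0, +6.0):
        specs.append(MalpositionSpec("tibial", "rotation", "long", m))
    for m in (-2.0, -1.0, +1.0, +2.0):
        specs.append(MalpositionSpec("tibial", "translation", "SI", m))
    return specs
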