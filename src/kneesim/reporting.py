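"""Outcome extraction, variation studies and directional trend checks.

Outcome profiles mirror the quantities evaluated in malposition studies:
axial tibiofemoral contact force magnitude, anteroposterior position of the
femur relative to the tibia, mediolateral position of the tibia relative to
the femur, tibial internal-external rotation, and per-ligament summed bundle
forces.  Kinematic outcomes are expressed between the BONE frames: for a
malpositioned component the implant-relative solver pose is composed with
the inverse implant-in-bone transform, which is how such studies report
"shift of the implant relative to the bone" effects.

Trend expectations are data (a packaged YAML file), not code: each entry
names a variant, an outcome, a flexion window and an expected direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anatomy import FrameDefinitions
from .kinematics import RigidTransform
from .malposition import (
    MalpositionSpec,
    REFERENCE,
    apply_to_insertions,
    direct_geometry_malposition,
    recompute_reference_strains,
    spec_to_transform,
    variation_matrix,
)
from .solver import (
    FlexionSweepResult,
    JointModel,
    QuadricepsMechanism,
    SolverError,
    SolverSettings,
    build_default_model,
    flexion_sweep,
    reference_configuration,
)

__all__ = [
    "OutcomeProfile",
    "TrendExpectation",
    "TrendResult",
    "StudyResult",
    "extract_outcomes",
    "make_variant_model",
    "run_variation_study",
    "load_trend_suite",
    "trend_check",
    "check_trends",
    "write_outputs",
]


# --------------------------------------------------------------------------
# outcome extraction


@dataclass(frozen=True)
class OutcomeProfile:
    """Per-flexion-step outcome measures for one model variant."""

    label: str
    flexion_deg: np.ndarray
    axial_force_N: np.ndarray
    ap_femur_mm: np.ndarray      # AP position of the femoral origin in the tibial frame
    ml_tibia_mm: np.ndarray      # ML position of the tibial origin in the femoral frame
    ie_tibia_deg: np.ndarray     # internal(+)/external(-) rotation of the tibia
    ligament_sums_N: dict
    spec: MalpositionSpec = REFERENCE

    def __len__(self):
        return len(self.flexion_deg)

    def outcome(self, name: str) -> np.ndarray:
        mapping = {
            "axial_force": self.axial_force_N,
            "ap_femur": self.ap_femur_mm,
            "ml_tibia": self.ml_tibia_mm,
            "ie_tibia": self.ie_tibia_deg,
        }
        if name in mapping:
            return mapping[name]
        if name in self.ligament_sums_N:
            return self.ligament_sums_N[name]
        raise KeyError(f"unknown outcome {name!r}")


def _decompose_ie(R: np.ndarray) -> float:
    """IE angle (deg) of the flexion -> varus-valgus -> IE decomposition."""
    return float(np.rad2deg(np.arctan2(-R[2, 0], R[2, 2])))


def extract_outcomes(
    sweep: FlexionSweepResult,
    frames: FrameDefinitions | None = None,
    spec: MalpositionSpec = REFERENCE,
    label: str | None = None,
    ml_positive_lateral: bool = True,
) -> OutcomeProfile:
    """Reduce a converged sweep to the standard outcome profile.

    ``spec`` identifies the malposition the sweep was run with; kinematics
    are converted from the implant-relative pose to the bone-relative pose by
    composing with the implant-in-bone transform, so that outcomes describe
    femur-versus-tibia (bone) motion.  Bundle forces are summed per ligament
    (name prefix before the underscore).
    """
    frames = frames or FrameDefinitions()
    T = spec_to_transform(spec, frames)
    T_f = T if spec.component == "femoral" else RigidTransform.identity()
    T_t = T if spec.component == "tibial" else RigidTransform.identity()
    T_f_inv = T_f.inverse()

    ap, ml, ie = [], [], []
    for pose in sweep.poses:
        B = T_t @ pose.transform() @ T_f_inv
        ap.append(B.t[0])
        p_t_in_f = -B.R.T @ B.t
        ml.append(p_t_in_f[2] if ml_positive_lateral else -p_t_in_f[2])
        ie.append(-_decompose_ie(B.R))

    sums: dict[str, np.ndarray] = {}
    for j, name in enumerate(sweep.bundle_names):
        lig = name.split("_")[0]
        sums.setdefault(lig, np.zeros(len(sweep)))
        sums[lig] = sums[lig] + sweep.ligament_forces[:, j]

    return OutcomeProfile(
        label=label or spec.label,
        flexion_deg=np.asarray(sweep.flexion_deg, float),
        axial_force_N=sweep.axial_force,
        ap_femur_mm=np.asarray(ap),
        ml_tibia_mm=np.asarray(ml),
        ie_tibia_deg=np.asarray(ie),
        ligament_sums_N=sums,
        spec=spec,
    )


# --------------------------------------------------------------------------
# variation study


def _transformed_quad(quad: QuadricepsMechanism, spec, frames) -> QuadricepsMechanism:
    """Move the quadriceps/PL attachments with the bone (optional flag)."""
    T_inv = spec_to_transform(spec, frames).inverse()
    if spec.component == "tibial":
        return dc_replace(quad, tuberosity_t=T_inv.apply(quad.tuberosity_t))
    a = T_inv.apply(np.array([*quad.anchor_f, 0.0]))[:2]
    o = T_inv.apply(np.array([*quad.wrap_center_f, 0.0]))[:2]
    return dc_replace(quad, anchor_f=a, wrap_center_f=o)


def make_variant_model(
    nominal: JointModel,
    spec: MalpositionSpec,
    method: str = "insertion-shift",
    transform_muscle_points: bool = False,
) -> JointModel:
    """Build a malposition variant of an initialised nominal model.

    ``insertion-shift``: insertion clusters mapped through the inverse
    transform, geometry untouched.  ``geometry-shift``: implant surfaces
    carry the mount transform, insertions untouched (the equivalence
    oracle).  The calibrated external preload force is inherited unchanged.
    """
    if not nominal.ligset.initialized or nominal.reference_pose is None:
        raise RuntimeError("nominal model must have an established reference")
    if method not in ("insertion-shift", "geometry-shift"):
        raise ValueError(f"unknown malposition method {method!r}")
    quad = nominal.quad
    if transform_muscle_points and quad is not None and not spec.is_identity:
        quad = _transformed_quad(quad, spec, nominal.frames)
    if method == "insertion-shift":
        ligset = apply_to_insertions(nominal.ligset, spec, nominal.frames)
        geometry = nominal.geometry
    else:
        ligset = nominal.ligset.copy()
        geometry = direct_geometry_malposition(nominal.geometry, spec, nominal.frames)
    return JointModel(
        ligset=ligset,
        geometry=geometry,
        frames=nominal.frames,
        quad=quad,
        patella_on=nominal.patella_on,
        k_c=nominal.k_c,
        F_ext=nominal.F_ext,
        reference_pose=nominal.reference_pose,
    )


@dataclass
class StudyResult:
    """Profiles and diagnostics of a variation study."""

    profiles: dict                      # label -> OutcomeProfile
    sweeps: dict                        # label -> FlexionSweepResult
    specs: list
    method: str
    failures: dict = field(default_factory=dict)

    @property
    def reference(self) -> OutcomeProfile:
        return self.profiles["reference"]


def run_variation_study(
    model: JointModel | None = None,
    settings: SolverSettings | None = None,
    specs: list | None = None,
    method: str = "insertion-shift",
    transform_muscle_points: bool = False,
    keep_sweeps: bool = True,
) -> StudyResult:
    """Run the reference and every variant over equal flexion grids.

    Per-variant solver failures are recorded and the study continues.  For
    the insertion-shift method each variant's reference strains are
    recomputed at its own reference pose (the bookkeeping handed to a
    virtual ligament model); zero-strain lengths are inherited from the
    nominal model and never change.
    """
    settings = settings or SolverSettings()
    model = model or build_default_model(patella=settings.patella)
    if not model.ligset.initialized:
        reference_configuration(model, settings)
    specs = list(specs) if specs is not None else variation_matrix()

    profiles, sweeps, failures = {}, {}, {}
    ref_sweep = flexion_sweep(model, settings)
    profiles["reference"] = extract_outcomes(
        ref_sweep, model.frames, REFERENCE, label="reference"
    )
    sweeps["reference"] = ref_sweep

    for spec in specs:
        if spec.is_identity:
            continue
        try:
            vm = make_variant_model(model, spec, method, transform_muscle_points)
            pose_v, _ = reference_configuration(vm, settings)
            if method == "insertion-shift":
                vm.ligset = recompute_reference_strains(vm.ligset, pose_v)
            sweep = flexion_sweep(vm, settings)
        except SolverError as exc:
            failures[spec.label] = str(exc)
            continue
        profiles[spec.label] = extract_outcomes(sweep, model.frames, spec)
        if keep_sweeps:
            sweeps[spec.label] = sweep
    return StudyResult(
        profiles=profiles,
        sweeps=sweeps if keep_sweeps else {},
        specs=specs,
        method=method,
        failures=failures,
    )


# --------------------------------------------------------------------------
# trend checks


_DIRECTIONS = (
    "increase",
    "decrease",
    "opposite-sign",
    "same-sign-comparable",
    "no-large-change",
)


@dataclass(frozen=True)
class TrendExpectation:
    """One directional expectation for a variant-versus-reference comparison."""

    id: str
    variant: str
    outcome: str
    window: tuple
    direction: str
    min_effect: float = 0.0
    comparable: tuple | None = None     # (lo, hi) fractions of the magnitude
    advisory: bool = False
    patella_on_only: bool = False
    note: str = ""

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown trend direction {self.direction!r}")


@dataclass(frozen=True)
class TrendResult:
    expectation: TrendExpectation
    passed: bool
    mean_diff: float
    max_abs_diff: float
    detail: str = ""


def load_trend_suite(path=None) -> list[TrendExpectation]:
    """Load the packaged (or a user-supplied) trend expectation file."""
    if path is None:
        with resources.files("kneesim.data").joinpath("trends.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out = []
    for e in raw["expectations"]:
        out.append(
            TrendExpectation(
                id=e["id"],
                variant=e["variant"],
                outcome=e["outcome"],
                window=tuple(e.get("window", (0.0, 80.0))),
                direction=e["direction"],
                min_effect=float(e.get("min_effect", 0.0)),
                comparable=tuple(e["comparable"]) if "comparable" in e else None,
                advisory=bool(e.get("advisory", False)),
                patella_on_only=bool(e.get("patella_on_only", False)),
                note=e.get("note", ""),
            )
        )
    return out


def trend_check(
    reference: OutcomeProfile,
    variant: OutcomeProfile,
    expectation: TrendExpectation,
) -> TrendResult:
    """Evaluate one directional expectation on matching flexion grids."""
    if len(reference) != len(variant) or not np.allclose(
        reference.flexion_deg, variant.flexion_deg
    ):
        raise ValueError("reference and variant flexion grids do not match")
    lo, hi = expectation.window
    mask = (reference.flexion_deg >= lo) & (reference.flexion_deg <= hi)
    r = reference.outcome(expectation.outcome)[mask]
    v = variant.outcome(expectation.outcome)[mask]
    diff = v - r
    mean = float(np.mean(diff))
    mx = float(np.max(np.abs(diff)))
    mag = variant.spec.magnitude
    d = expectation.direction

    if d == "increase":
        ok = mean > expectation.min_effect
        detail = f"mean diff {mean:+.2f} (> {expectation.min_effect:g} required)"
    elif d == "decrease":
        ok = mean < -expectation.min_effect
        detail = f"mean diff {mean:+.2f} (< -{expectation.min_effect:g} required)"
    elif d == "opposite-sign":
        ok = mean * mag < 0 and abs(mean) > expectation.min_effect
        detail = f"mean diff {mean:+.2f} vs magnitude {mag:+g}"
    elif d == "same-sign-comparable":
        lo_f, hi_f = expectation.comparable or (0.2, 1.5)
        ok = mean * mag > 0 and lo_f * abs(mag) <= abs(mean) <= hi_f * abs(mag)
        detail = (
            f"mean diff {mean:+.2f} vs magnitude {mag:+g} "
            f"(comparable band {lo_f:g}-{hi_f:g} x)"
        )
    else:  # no-large-change
        full = reference.outcome(expectation.outcome)
        scale = float(np.ptp(full)) or 1.0
        ok = abs(mean) < 0.10 * scale
        detail = f"|mean diff| {abs(mean):.2f} vs 10% of reference range {scale:.2f}"
    return TrendResult(expectation, bool(ok), mean, mx, detail)


def check_trends(
    study: StudyResult,
    suite: list | None = None,
    patella_on: bool = True,
) -> list[TrendResult]:
    """Run every applicable expectation of the suite against a study."""
    suite = suite if suite is not None else load_trend_suite()
    results = []
    for exp in suite:
        if exp.patella_on_only and not patella_on:
            continue
        if exp.variant not in study.profiles:
            results.append(
                TrendResult(exp, False, np.nan, np.nan, "variant profile missing")
            )
            continue
        results.append(
            trend_check(study.reference, study.profiles[exp.variant], exp)
        )
    return results


# --------------------------------------------------------------------------
# outputs

_SUMMARY_SCHEMA = {
    "required": ["method", "profiles", "trends", "failures"],
    "profile_required": ["label", "n_steps", "axial_force_range_N"],
}


def profile_frame(profile: OutcomeProfile) -> pd.DataFrame:
    data = {
        "flexion_deg": profile.flexion_deg,
        "axial_force_N": profile.axial_force_N,
        "ap_femur_mm": profile.ap_femur_mm,
        "ml_tibia_mm": profile.ml_tibia_mm,
        "ie_rot_deg": profile.ie_tibia_deg,
    }
    for name in sorted(profile.ligament_sums_N):
        data[f"{name}_N"] = profile.ligament_sums_N[name]
    return pd.DataFrame(data)


def validate_summary(summary: dict) -> None:
    for key in _SUMMARY_SCHEMA["required"]:
        if key not in summary:
            raise ValueError(f"summary is missing required key {key!r}")
    for p in summary["profiles"]:
        for key in _SUMMARY_SCHEMA["profile_required"]:
            if key not in p:
                raise ValueError(f"profile entry missing key {key!r}")


def write_outputs(
    study: StudyResult,
    outdir,
    trends: list | None = None,
    plots: bool = False,
) -> dict:
    """Write per-profile CSVs and a study-level JSON summary; return the
    summary dict.  Optional plots mirror the standard panel layout (axial
    force, AP femur, tibial rotation versus flexion)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, profile in study.profiles.items():
        profile_frame(profile).to_csv(outdir / f"profile_{label}.csv", index=False)
    summary = {
        "method": study.method,
        "profiles": [
            {
                "label": p.label,
                "n_steps": len(p),
                "axial_force_range_N": [
                    float(p.axial_force_N.min()),
                    float(p.axial_force_N.max()),
                ],
            }
            for p in study.profiles.values()
        ],
        "trends": [
            {
                "id": t.expectation.id,
                "passed": t.passed,
                "advisory": t.expectation.advisory,
                "mean_diff": None if np.isnan(t.mean_diff) else t.mean_diff,
                "detail": t.detail,
            }
            for t in (trends or [])
        ],
        "failures": study.failures,
    }
    validate_summary(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    if plots:
        _write_plots(study, outdir)
    return summary


def _write_plots(study: StudyResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for label, p in study.profiles.items():
        kw = {"lw": 2, "color": "k"} if label == "reference" else {"lw": 1}
        axes[0].plot(p.flexion_deg, p.axial_force_N, label=label, **kw)
        axes[1].plot(p.flexion_deg, p.ap_femur_mm, **kw)
        axes[2].plot(p.flexion_deg, p.ie_tibia_deg, **kw)
    axes[0].set_ylabel("axial contact force (N)")
    axes[1].set_ylabel("AP femur position (mm)")
    axes[2].set_ylabel("tibial rotation (deg)")
    for ax in axes:
        ax.set_xlabel("flexion (deg)")
    axes[0].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(outdir / "profiles.png", dpi=150)
    plt.close(fig)
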