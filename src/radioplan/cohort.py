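"""Synthetic phantom geometries and paired multi-condition dose grids.

This module replaces unpublished patient data with a seeded generator that
has the statistical structure the downstream analysis assumes:

* a geometric phantom (body, target, lungs, heart, esophagus, cord);
* a planned dose per patient: near-uniform inside the target with a small
  peripheral cold spot, exponential radial falloff outside — chosen so the
  gradient measure has a closed form and the coverage/homogeneity gates
  pass by construction;
* six calculation conditions derived from each base plan by parametric
  perturbations (global scale, low-dose-region scale, target-periphery
  shift, voxel noise). The perturbations emulate the *direction and rough
  size* of algorithm/contrast differences; they are calibration knobs, not
  a dose engine.

Seed scheme: every stochastic quantity derives from
``SeedSequence(master_seed, spawn_key=...)`` — ``(patient,)`` for phantom
and plan, ``(patient, condition_index)`` for condition noise. Re-running
with the same master seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .dvh import (
    conformity_index,
    differential_to_cumulative,
    gradient_measure,
    grid_to_differential_dvh,
    homogeneity_check,
    summary_metrics,
    volume_at_dose,
)
from .grids import DoseGrid, StructureMask

__all__ = [
    "PhantomSpec",
    "Phantom",
    "ConditionEffect",
    "CohortConfig",
    "PatientPlans",
    "Cohort",
    "CONDITIONS",
    "DEFAULT_EFFECTS",
    "generate_phantom",
    "generate_plan_dose",
    "apply_condition",
    "generate_cohort",
    "patient_phantom_spec",
    "cohort_metric_table",
]

#: The six calculation conditions, in canonical order.
CONDITIONS = ("AAA", "AAA_C", "AXB_Dm", "AXB_Dw", "AXB_C_Dm", "AXB_C_Dw")

STRUCTURES = ("Body", "PTV", "Lung_L", "Lung_R", "Lungs", "Heart", "Esophagus", "Cord")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic patient."""

    shape: tuple[int, int, int] = (44, 44, 44)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    ptv_center_mm: tuple[float, float, float] = (66.0, 66.0, 66.0)
    ptv_radius_mm: float = 18.0
    body_radii_mm: tuple[float, float, float] = (62.0, 62.0, 66.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ptv_radius_mm <= 0:
            raise ValueError("ptv_radius_mm must be positive")
        if any(r <= 0 for r in self.body_radii_mm):
            raise ValueError("body radii must be positive")


@dataclass
class Phantom:
    spec: PhantomSpec
    masks: dict[str, StructureMask]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.spec.spacing


@dataclass(frozen=True)
class ConditionEffect:
    """Parametric perturbation turning a base plan into one condition."""

    condition: str
    global_scale: float = 1.0
    target_min_shift_cgy: float = 0.0
    low_dose_scale: float = 1.0
    noise_sd_cgy: float = 20.0

    def __post_init__(self) -> None:
        if self.global_scale <= 0 or self.low_dose_scale <= 0:
            raise ValueError("scales must be positive")
        if self.noise_sd_cgy < 0:
            raise ValueError("noise_sd_cgy must be non-negative")


def _default_effects() -> dict[str, ConditionEffect]:
    # Directions/magnitudes calibrated to the reported cohort means:
    # contrast raises the target-periphery minimum (~ +550 cGy for AAA),
    # AXB sits below AAA, Dm reports ~1% below Dw, and the convolution
    # algorithm runs ~2% hot in the low-dose region.
    return {
        "AAA": ConditionEffect("AAA", 1.000, 0.0, 1.02),
        "AAA_C": ConditionEffect("AAA_C", 1.005, 555.0, 1.02),
        "AXB_Dm": ConditionEffect("AXB_Dm", 0.991, -150.0, 0.98),
        "AXB_Dw": ConditionEffect("AXB_Dw", 0.999, -110.0, 0.98),
        "AXB_C_Dm": ConditionEffect("AXB_C_Dm", 0.994, 325.0, 0.97),
        "AXB_C_Dw": ConditionEffect("AXB_C_Dw", 1.002, 376.0, 0.97),
    }


DEFAULT_EFFECTS = _default_effects()


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 20
    prescription_cgy: float = 5400.0
    n_fractions: int = 30
    effects: dict[str, ConditionEffect] = field(default_factory=_default_effects)
    master_seed: int = 0
    shape: tuple[int, int, int] = (44, 44, 44)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    falloff_mm: float = 25.0
    heterogeneity: float = 0.015
    cold_spot_depth_cgy: float = 800.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.prescription_cgy <= 0 or self.n_fractions <= 0:
            raise ValueError("prescription and n_fractions must be positive")
        missing = [c for c in CONDITIONS if c not in self.effects]
        if missing:
            raise ValueError(f"effects missing for conditions: {missing}")


@dataclass
class PatientPlans:
    patient: str
    phantom: Phantom
    base: DoseGrid
    conditions: dict[str, DoseGrid]


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[PatientPlans]
    manifest: dict


# ---------------------------------------------------------------------------
# phantom geometry


def _coord_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, radii) -> np.ndarray:
    q = sum(((c - c0) / r) ** 2 for c, c0, r in zip(coords, center, radii))
    return q <= 1.0


def _tube_z(coords, center_xy, radius) -> np.ndarray:
    x, y, _ = coords
    return (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministic set of structure masks for one synthetic patient.

    The target is a sphere centred in the thorax-like body; lungs, heart,
    esophagus and cord are parametric ellipsoids/tubes. The target must lie
    strictly inside the body and must not overlap the cord.
    """
    coords = _coord_grids(spec.shape, spec.spacing)
    center = tuple(0.5 * (n - 1) * s for n, s in zip(spec.shape, spec.spacing))
    cx, cy, cz = center

    body = _ellipsoid(coords, center, spec.body_radii_mm)
    ptv = _ellipsoid(coords, spec.ptv_center_mm, (spec.ptv_radius_mm,) * 3)
    lung_l = _ellipsoid(coords, (cx - 36, cy - 6, cz), (20, 32, 48)) & body & ~ptv
    lung_r = _ellipsoid(coords, (cx + 36, cy - 6, cz), (20, 32, 48)) & body & ~ptv
    heart = _ellipsoid(coords, (cx - 12, cy + 16, cz - 10), (18, 18, 22)) & body
    esophagus = _tube_z(coords, (cx + 4, cy + 28), 5.0) & body
    cord = _tube_z(coords, (cx, cy + 46), 5.0) & body

    if not ptv.any():
        raise ValueError("target mask is empty; enlarge ptv_radius_mm or refine grid")
    if (ptv & ~body).any():
        raise ValueError("target must lie strictly inside the body")
    overlap = (ptv & cord).sum() / ptv.sum()
    if overlap > 0.01:
        raise ValueError(f"target overlaps cord by {overlap:.1%} (> 1% tolerance)")

    arrays = {
        "Body": body,
        "PTV": ptv,
        "Lung_L": lung_l,
        "Lung_R": lung_r,
        "Lungs": lung_l | lung_r,
        "Heart": heart,
        "Esophagus": esophagus,
        "Cord": cord,
    }
    masks = {name: StructureMask(name, arr, spec.spacing) for name, arr in arrays.items()}
    return Phantom(spec, masks)


# ---------------------------------------------------------------------------
# plan dose


def _surface_distance_mm(ptv: np.ndarray, spacing) -> np.ndarray:
    """Distance to the target surface: positive outside, negative inside."""
    outside = distance_transform_edt(~ptv, sampling=spacing)
    inside = distance_transform_edt(ptv, sampling=spacing)
    return outside - inside


def _smooth_unit_field(shape, rng, sigma_vox: float = 3.0) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_plan_dose(
    phantom: Phantom,
    prescription_cgy: float,
    falloff_mm: float = 25.0,
    heterogeneity: float = 0.015,
    cold_spot_depth_cgy: float = 800.0,
    seed: int = 0,
    max_attempts: int = 3,
) -> DoseGrid:
    """Generate one plan-like dose grid satisfying the planning gates.

    Inside the target the dose is the prescription times a small positive
    heterogeneity (so the full-prescription coverage holds), minus one
    compact Gaussian cold spot at the target periphery (the plan's minimum,
    which the condition perturbations later shift). Outside, the dose falls
    off as exp(-distance/falloff_mm).

    The coverage (V95% >= 95%) and homogeneity (-5%/+7%) gates are
    re-verified post hoc; on failure the heterogeneity is halved and the
    plan regenerated, erroring after ``max_attempts``.
    """
    if prescription_cgy <= 0:
        raise ValueError("prescription must be positive")
    spec = phantom.spec
    ptv = phantom.masks["PTV"]
    body = phantom.masks["Body"]
    sdist = _surface_distance_mm(ptv.voxels, spec.spacing)

    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(attempt,)))
        amp = heterogeneity / (2**attempt)

        dose = prescription_cgy * np.exp(-np.maximum(sdist, 0.0) / falloff_mm)
        h = np.clip(0.02 + amp * _smooth_unit_field(spec.shape, rng), 0.004, 0.055)
        dose[ptv.voxels] = prescription_cgy * (1.0 + h[ptv.voxels])

        # peripheral cold spot: a small ball tangent to the target surface
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        r_c = 0.18 * spec.ptv_radius_mm
        cs_center = np.asarray(spec.ptv_center_mm) + (spec.ptv_radius_mm - r_c) * direction
        coords = _coord_grids(spec.shape, spec.spacing)
        d2 = sum((c - c0) ** 2 for c, c0 in zip(coords, cs_center))
        dip = cold_spot_depth_cgy * np.exp(-d2 / r_c**2)
        dose[ptv.voxels] -= dip[ptv.voxels]

        dose = np.clip(dose, 0.0, None)
        dose[~body.voxels] = 0.0
        grid = DoseGrid(dose, spec.spacing)

        cdvh = differential_to_cumulative(grid_to_differential_dvh(grid, ptv))
        coverage_ok = volume_at_dose(cdvh, 0.95 * prescription_cgy) >= 95.0
        homo = homogeneity_check(summary_metrics(grid, ptv), prescription_cgy)
        if coverage_ok and homo.passed:
            return grid

    raise RuntimeError(
        f"plan generation failed coverage/homogeneity gates after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# condition perturbations


def apply_condition(
    base: DoseGrid,
    effect: ConditionEffect,
    seed: int = 0,
    *,
    ptv: StructureMask | None = None,
    prescription_cgy: float | None = None,
    periphery_mm: float = 12.0,
) -> DoseGrid:
    """Perturb a base plan into one calculation condition.

    dose' = dose * global_scale, additionally scaled by ``low_dose_scale``
    where the base dose is below 20% of the prescription, shifted by
    ``target_min_shift_cgy`` within ``periphery_mm`` of the target surface,
    plus white Gaussian noise. Deterministic per seed. Negative results are
    clipped to zero; if more than 1% of in-body voxels clip, a warning is
    emitted.
    """
    rng = np.random.default_rng(seed)
    dose = base.values * effect.global_scale

    if effect.low_dose_scale != 1.0:
        if prescription_cgy is None:
            raise ValueError("low_dose_scale != 1 requires prescription_cgy")
        low = base.values < 0.2 * prescription_cgy
        dose[low] *= effect.low_dose_scale

    if effect.target_min_shift_cgy != 0.0:
        if ptv is None:
            raise ValueError("target_min_shift requires the target mask")
        ptv.check_congruent(base)
        sdist = _surface_distance_mm(ptv.voxels, base.spacing)
        periphery = np.abs(sdist) <= periphery_mm
        dose[periphery] += effect.target_min_shift_cgy

    if effect.noise_sd_cgy > 0:
        dose = dose + rng.normal(0.0, effect.noise_sd_cgy, size=dose.shape)

    nonzero = base.values > 0
    clipped = (dose < 0) & nonzero
    if nonzero.any() and clipped.sum() > 0.01 * nonzero.sum():
        warnings.warn(
            f"{effect.condition}: {clipped.sum()} voxels "
            f"({clipped.sum() / nonzero.sum():.1%}) clipped to zero dose",
            stacklevel=2,
        )
    dose = np.clip(dose, 0.0, None)
    dose[base.values == 0] = 0.0
    return DoseGrid(dose, base.spacing, base.origin)


# ---------------------------------------------------------------------------
# cohort assembly


def patient_phantom_spec(config: CohortConfig, idx: int) -> PhantomSpec:
    rng = np.random.default_rng(np.random.SeedSequence(config.master_seed, spawn_key=(idx,)))
    radius = float(rng.uniform(15.0, 21.0))
    return PhantomSpec(
        shape=config.shape,
        spacing=config.spacing,
        ptv_center_mm=tuple(
            0.5 * (n - 1) * s for n, s in zip(config.shape, config.spacing)
        ),
        ptv_radius_mm=radius,
        seed=idx,
    )


def _condition_seed(master_seed: int, patient_idx: int, cond_idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(patient_idx, 1000 + cond_idx))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``n_patients`` phantoms, base plans, and all six conditions.

    The manifest records every derived seed and effect parameter; re-running
    with the same master seed reproduces the cohort exactly.
    """
    patients: list[PatientPlans] = []
    manifest_patients = []
    for p in range(config.n_patients):
        spec = patient_phantom_spec(config, p)
        phantom = generate_phantom(spec)
        plan_seed = int(
            np.random.SeedSequence(config.master_seed, spawn_key=(p, 500)).generate_state(1)[0]
        )
        base = generate_plan_dose(
            phantom,
            config.prescription_cgy,
            falloff_mm=config.falloff_mm,
            heterogeneity=config.heterogeneity,
            cold_spot_depth_cgy=config.cold_spot_depth_cgy,
            seed=plan_seed,
        )
        conditions = {}
        cond_seeds = {}
        for c, name in enumerate(CONDITIONS):
            seed = int(_condition_seed(config.master_seed, p, c).generate_state(1)[0])
            cond_seeds[name] = seed
            conditions[name] = apply_condition(
                base,
                config.effects[name],
                seed=seed,
                ptv=phantom.masks["PTV"],
                prescription_cgy=config.prescription_cgy,
            )
        patient_id = f"P{p + 1:03d}"
        patients.append(PatientPlans(patient_id, phantom, base, conditions))
        manifest_patients.append(
            {
                "patient": patient_id,
                "ptv_radius_mm": spec.ptv_radius_mm,
                "plan_seed": plan_seed,
                "condition_seeds": cond_seeds,
            }
        )
    manifest = {
        "master_seed": config.master_seed,
        "n_patients": config.n_patients,
        "prescription_cgy": config.prescription_cgy,
        "n_fractions": config.n_fractions,
        "conditions": list(CONDITIONS),
        "effects": {
            name: {
                "global_scale": e.global_scale,
                "target_min_shift_cgy": e.target_min_shift_cgy,
                "low_dose_scale": e.low_dose_scale,
                "noise_sd_cgy": e.noise_sd_cgy,
            }
            for name, e in config.effects.items()
        },
        "patients": manifest_patients,
    }
    return Cohort(config, patients, manifest)


# ---------------------------------------------------------------------------
# metric extraction


def cohort_metric_table(
    cohort: Cohort,
    metrics: tuple[str, ...] = ("PTV_Min", "PTV_Max", "PTV_Mean", "PTV_D2", "PTV_D50", "PTV_D98"),
) -> pd.DataFrame:
    """Tidy per-patient x per-condition metric table.

    Supported metric names: ``<Structure>_<Min|Max|Mean|Median|Mode|STD|
    D2|D50|D98>`` and ``<Structure>_V<dose_cGy>``.
    """
    rows = []
    for pat in cohort.patients:
        for cond_name, grid in pat.conditions.items():
            cache: dict[str, object] = {}
            for metric in metrics:
                structure, _, stat = metric.rpartition("_")
                mask = pat.phantom.masks.get(structure)
                if mask is None:
                    raise KeyError(f"unknown structure in metric {metric!r}")
                if structure not in cache:
                    cache[structure] = summary_metrics(grid, mask)
                sm = cache[structure]
                if stat == "CI":
                    value = conformity_index(
                        grid,
                        mask,
                        cohort.config.prescription_cgy,
                        body=pat.phantom.masks["Body"],
                    )
                elif stat == "GM":
                    value = gradient_measure(
                        grid, pat.phantom.masks["Body"], cohort.config.prescription_cgy
                    )
                elif stat.startswith("V") and stat[1:].replace(".", "").isdigit():
                    cdvh = differential_to_cumulative(grid_to_differential_dvh(grid, mask))
                    value = volume_at_dose(cdvh, float(stat[1:]))
                else:
                    attr = {
                        "Min": "d_min",
                        "Max": "d_max",
                        "Mean": "d_mean",
                        "Median": "d_median",
                        "Mode": "d_mode",
                        "STD": "d_std",
                        "D2": "d2",
                        "D50": "d50",
                        "D98": "d98",
                    }.get(stat)
                    if attr is None:
                        raise KeyError(f"unknown statistic in metric {metric!r}")
                    value = getattr(sm, attr)
                rows.append(
                    {
                        "patient": pat.patient,
                        "condition": cond_name,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
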