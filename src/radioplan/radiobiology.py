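"""Radiobiological outcome models: EUD, TCP and NTCP.

Implemented model families
--------------------------
* Mechanistic Poisson TCP for a uniformly irradiated clonogen population:
  ``TCP = exp(-N * exp(-alpha * D))``.
* Phenomenological Poisson TCP parameterised by the 50%-control dose D50
  and the normalised slope gamma50:
  ``TCP(D) = (1/2) ** exp(2 * gamma50 * (1 - D / D50) / ln 2)``,
  extended to heterogeneous DVHs as the volume-weighted product over bins
  (computed in the log domain).
* LKB (probit) NTCP: ``NTCP = Phi(t)`` with
  ``t = (EUD - TD50) / (m * TD50)`` and EUD the generalised power mean of
  the DVH with exponent ``a`` (``a = 1/n`` for LKB models).
* Poisson-LQ NTCP: the Poisson DVH form applied to an organ-at-risk DVH.

Conventions
-----------
* All doses are cGy internally; ``alpha_beta`` is accepted in Gy and
  converted at registry load.
* For "-LQ"-labelled (poisson_lq) models the per-bin EQD2 correction is
  applied by default; for lyman models it is off by default (their
  TD50/m values were fitted to physical dose). Both are overridable.
* gamma50 is not part of the published parameter set for the poisson_lq
  models; a literature-style default of 1.5 is used unless overridden, and
  the value used is always recorded in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import erfc

from .dvh import DifferentialDVH

__all__ = [
    "RadiobioModel",
    "MechanisticTCPParams",
    "FractionationScheme",
    "DEFAULT_GAMMA50",
    "load_default_registry",
    "load_registry",
    "eqd2_transform",
    "eud",
    "tcp_mechanistic",
    "tcp_poisson_uniform",
    "tcp_poisson_dvh",
    "ntcp_lkb",
    "ntcp_poisson_lq",
    "evaluate_outcomes",
]

LN2 = math.log(2.0)

#: Default normalised slope for poisson_lq models whose gamma50 is not part
#: of the published parameter set. Every output records the value used.
DEFAULT_GAMMA50 = 1.5


@dataclass(frozen=True)
class RadiobioModel:
    """One row of the model registry."""

    structure: str
    endpoint: str
    family: str  # "poisson_lq" | "lyman"
    d50: float  # cGy; D50 for poisson_lq, TD50(1) for lyman
    gamma50: float | None = None
    m: float | None = None
    n: float | None = None
    a: float | None = None
    alpha_beta_cgy: float | None = None
    eqd2: bool | None = None  # None -> family default

    def __post_init__(self) -> None:
        if self.family not in ("poisson_lq", "lyman"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.d50 <= 0:
            raise ValueError(f"{self.key}: d50 must be positive")
        if self.family == "lyman":
            if self.m is None or self.m <= 0:
                raise ValueError(f"{self.key}: lyman models require m > 0")
            if self.n is None and self.a is None:
                raise ValueError(f"{self.key}: lyman models require n (or a)")

    @property
    def key(self) -> str:
        return f"{self.structure}/{self.endpoint}"

    @property
    def eud_exponent(self) -> float:
        """EUD exponent: explicit ``a`` if set, else 1/n for lyman models."""
        if self.a is not None:
            return self.a
        if self.family == "lyman" and self.n:
            return 1.0 / self.n
        raise ValueError(f"{self.key}: no EUD exponent (set a, or n for lyman)")

    @property
    def apply_eqd2(self) -> bool:
        if self.eqd2 is not None:
            return self.eqd2
        return self.family == "poisson_lq" and self.alpha_beta_cgy is not None

    def resolved_gamma50(self, default: float | None = DEFAULT_GAMMA50) -> float:
        if self.gamma50 is not None:
            return self.gamma50
        if default is None:
            raise ValueError(
                f"{self.key}: gamma50 is required for poisson_lq models but is "
                "not set; provide it in the registry config"
            )
        return default


@dataclass(frozen=True)
class MechanisticTCPParams:
    """Clonogen count N and per-cGy radiosensitivity alpha."""

    n_clonogens: float
    alpha: float

    def __post_init__(self) -> None:
        if self.n_clonogens <= 0 or self.alpha <= 0:
            raise ValueError("n_clonogens and alpha must be positive")


@dataclass(frozen=True)
class FractionationScheme:
    prescription_cgy: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.prescription_cgy <= 0 or self.n_fractions <= 0:
            raise ValueError("prescription and n_fractions must be positive")

    @property
    def dose_per_fraction_cgy(self) -> float:
        return self.prescription_cgy / self.n_fractions


# ---------------------------------------------------------------------------
# registry


def _model_from_record(rec: dict) -> RadiobioModel:
    ab = rec.get("alpha_beta_gy")
    return RadiobioModel(
        structure=rec["structure"],
        endpoint=rec["endpoint"],
        family=rec["family"],
        d50=float(rec["d50_cgy"]),
        gamma50=rec.get("gamma50"),
        m=rec.get("m"),
        n=rec.get("n"),
        a=rec.get("a"),
        alpha_beta_cgy=None if ab is None else float(ab) * 100.0,
        eqd2=rec.get("eqd2"),
    )


def load_default_registry() -> list[RadiobioModel]:
    """The built-in model parameter table."""
    text = resources.files("radioplan").joinpath("data/models.yaml").read_text()
    return [_model_from_record(rec) for rec in yaml.safe_load(text)["models"]]


def load_registry(path=None, overrides: list[dict] | None = None) -> list[RadiobioModel]:
    """Load the default registry, merging user overrides by structure+endpoint."""
    models = {m.key: m for m in load_default_registry()}
    records: list[dict] = []
    if path is not None:
        with open(path) as fh:
            records.extend(yaml.safe_load(fh)["models"])
    if overrides:
        records.extend(overrides)
    for rec in records:
        key = f"{rec['structure']}/{rec['endpoint']}"
        if key in models and not all(k in rec for k in ("family", "d50_cgy")):
            base = models[key]
            merged = {
                "structure": base.structure,
                "endpoint": base.endpoint,
                "family": rec.get("family", base.family),
                "d50_cgy": rec.get("d50_cgy", base.d50),
                "gamma50": rec.get("gamma50", base.gamma50),
                "m": rec.get("m", base.m),
                "n": rec.get("n", base.n),
                "a": rec.get("a", base.a),
                "alpha_beta_gy": rec.get(
                    "alpha_beta_gy",
                    None if base.alpha_beta_cgy is None else base.alpha_beta_cgy / 100.0,
                ),
                "eqd2": rec.get("eqd2", base.eqd2),
            }
            models[key] = _model_from_record(merged)
        else:
            models[key] = _model_from_record(rec)
    return list(models.values())


# ---------------------------------------------------------------------------
# dose transforms


def eqd2_transform(
    dvh: DifferentialDVH,
    alpha_beta_cgy: float,
    scheme: FractionationScheme,
) -> DifferentialDVH:
    """Per-bin LQ conversion to equivalent dose in 2-Gy fractions.

    Each bin dose D maps to D * (d + ab) / (200 + ab), with d = D / n_fx
    the physical dose per fraction and ab = alpha/beta in cGy. Volumes are
    unchanged. Identity when d = 2 Gy exactly.
    """
    if alpha_beta_cgy <= 0:
        raise ValueError("alpha_beta must be positive")
    d_bins = dvh.bin_centers
    d_fx = d_bins / scheme.n_fractions
    return dvh.rebinned_doses(d_bins * (d_fx + alpha_beta_cgy) / (200.0 + alpha_beta_cgy))


# ---------------------------------------------------------------------------
# EUD


def eud(dvh: DifferentialDVH, a: float) -> float:
    """Generalised power-mean dose ``(sum v_i D_i^a)^(1/a)`` in cGy.

    Computed in a scale-invariant way (doses normalised by their maximum)
    so large exponents do not overflow.
    """
    if a == 0:
        raise ValueError("a must be nonzero (geometric-mean limit not implied)")
    v = dvh.relative_volume
    d = dvh.bin_centers
    occupied = v > 0
    v, d = v[occupied], d[occupied]
    d_max = d.max()
    if d_max == 0:
        return 0.0
    if a < 0 and np.any(d == 0):
        return 0.0  # negative-exponent mean is dominated by zero dose
    return float(d_max * np.power(np.sum(v * np.power(d / d_max, a)), 1.0 / a))


# ---------------------------------------------------------------------------
# TCP


def tcp_mechanistic(dose_cgy: float, params: MechanisticTCPParams) -> float:
    """Poisson TCP for uniform irradiation of N clonogens, exp(-N e^{-aD})."""
    if dose_cgy < 0:
        raise ValueError("dose must be non-negative")
    return math.exp(-params.n_clonogens * math.exp(-params.alpha * dose_cgy))


def _log2_tcp_uniform(dose_cgy, d50: float, gamma50: float):
    """log2 of the phenomenological Poisson TCP (vectorised)."""
    return -np.exp(2.0 * gamma50 * (1.0 - np.asarray(dose_cgy, dtype=float) / d50) / LN2)


def tcp_poisson_uniform(dose_cgy: float, d50: float, gamma50: float) -> float:
    """Two-parameter Poisson TCP at uniform dose: (1/2)^exp[2g50(1-D/D50)/ln2]."""
    if dose_cgy < 0:
        raise ValueError("dose must be non-negative")
    if d50 <= 0 or gamma50 <= 0:
        raise ValueError("d50 and gamma50 must be positive")
    return float(np.exp2(_log2_tcp_uniform(dose_cgy, d50, gamma50)))


def _dvh_for_model(
    dvh: DifferentialDVH, model: RadiobioModel, scheme: FractionationScheme | None
) -> DifferentialDVH:
    if model.apply_eqd2:
        if scheme is None:
            raise ValueError(f"{model.key}: EQD2 correction requires a fractionation scheme")
        return eqd2_transform(dvh, model.alpha_beta_cgy, scheme)
    return dvh


def tcp_poisson_dvh(
    dvh: DifferentialDVH,
    model: RadiobioModel,
    scheme: FractionationScheme | None = None,
    gamma50_default: float | None = DEFAULT_GAMMA50,
) -> float:
    """Poisson TCP over a heterogeneous DVH.

    Equals the volume-weighted product of per-bin uniform TCPs,
    prod_i TCP(D_i)^{v_i}, accumulated in the log domain.
    """
    if model.family != "poisson_lq":
        raise ValueError(f"{model.key}: tcp_poisson_dvh requires a poisson_lq model")
    g50 = model.resolved_gamma50(gamma50_default)
    work = _dvh_for_model(dvh, model, scheme)
    v = work.relative_volume
    log2_tcp = np.sum(v * _log2_tcp_uniform(work.bin_centers, model.d50, g50))
    return float(np.exp2(log2_tcp))


# ---------------------------------------------------------------------------
# NTCP


def _phi(t: float) -> float:
    """Standard normal CDF via the complementary error function."""
    return 0.5 * erfc(-t / math.sqrt(2.0))


def ntcp_lkb(
    dvh: DifferentialDVH,
    model: RadiobioModel,
    scheme: FractionationScheme | None = None,
) -> tuple[float, float]:
    """LKB probit NTCP. Returns (ntcp, eud_cgy).

    t = (EUD - TD50) / (m * TD50) with EUD computed at exponent a = 1/n.
    """
    if model.family != "lyman":
        raise ValueError(f"{model.key}: ntcp_lkb requires a lyman model")
    if model.m is None or model.m <= 0:
        raise ValueError(f"{model.key}: slope factor m must be positive")
    work = _dvh_for_model(dvh, model, scheme)
    eud_val = eud(work, model.eud_exponent)
    t = (eud_val - model.d50) / (model.m * model.d50)
    return _phi(t), eud_val


def ntcp_poisson_lq(
    dvh: DifferentialDVH,
    model: RadiobioModel,
    scheme: FractionationScheme | None = None,
    gamma50_default: float | None = DEFAULT_GAMMA50,
) -> float:
    """Poisson DVH response applied to an organ-at-risk DVH."""
    return tcp_poisson_dvh(dvh, model, scheme, gamma50_default)


# ---------------------------------------------------------------------------
# cohort evaluation


def evaluate_outcomes(
    cohort_dvhs: dict[tuple[str, str], dict[str, DifferentialDVH]],
    registry: list[RadiobioModel],
    scheme: FractionationScheme,
    gamma50_default: float | None = DEFAULT_GAMMA50,
) -> pd.DataFrame:
    """Evaluate every registry model for every patient x condition.

    Parameters
    ----------
    cohort_dvhs : mapping (patient, condition) -> {structure: DifferentialDVH}
    registry : model list; each model is applied to its own structure.
    scheme : fractionation used for EQD2-corrected models.

    Returns a tidy frame with columns patient, condition, structure,
    endpoint, family, eud_cgy, probability, gamma50_used, eqd2. Rows whose
    structure is missing are recorded with an ``error`` and NaN probability;
    the run continues.
    """
    rows = []
    for (patient, condition), dvhs in sorted(cohort_dvhs.items()):
        for model in registry:
            row = {
                "patient": patient,
                "condition": condition,
                "structure": model.structure,
                "endpoint": model.endpoint,
                "family": model.family,
                "eud_cgy": np.nan,
                "probability": np.nan,
                "gamma50_used": np.nan,
                "eqd2": model.apply_eqd2,
                "error": "",
            }
            dvh = dvhs.get(model.structure)
            if dvh is None:
                row["error"] = f"structure {model.structure!r} missing"
            elif model.family == "lyman":
                prob, eud_val = ntcp_lkb(dvh, model, scheme)
                row["probability"] = prob
                row["eud_cgy"] = eud_val
            else:
                g50 = model.resolved_gamma50(gamma50_default)
                row["probability"] = tcp_poisson_dvh(dvh, model, scheme, g50)
                row["eud_cgy"] = eud(_dvh_for_model(dvh, model, scheme), model.a or 1.0)
                row["gamma50_used"] = g50
            rows.append(row)
    return pd.DataFrame(rows)
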