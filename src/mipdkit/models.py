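"""Population pharmacokinetic model specifications and covariate evaluation.

A population PK model is described structurally (one or two compartments),
by its typical parameter values (clearance CL in L/h, central volume V1 in L
or L/kg, inter-compartmental clearance Q in L/h, peripheral volume V2 in L),
by covariate equations that map patient covariates onto individual typical
values, by inter-individual variability (IIV, lognormal random effects with
log-scale SD omega), and by a residual error model (additive and/or
proportional).

Covariate equations are stored as *named forms with coefficients* so that
model catalogues can round-trip through YAML and users can register their own
models (e.g. a locally developed cefotaxime model) without writing code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Mapping, Optional


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class MissingCovariateError(ValueError):
    """A covariate required by the model's covariate equations is absent."""


class UnknownDrugError(KeyError):
    """Requested drug is not in the model registry."""


@dataclass(frozen=True)
class CovariateSet:
    """Patient covariates at a single point in time.

    ``clcr_ml_min``, when present (measured or externally derived creatinine
    clearance), takes precedence over the Cockcroft-Gault derivation.
    """

    weight_kg: float
    serum_creatinine_mg_dL: float
    age_years: float
    sex: Sex
    time: Optional[datetime] = None
    clcr_ml_min: Optional[float] = None
    albumin_g_L: Optional[float] = None
    sofa: Optional[int] = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")
        if self.serum_creatinine_mg_dL <= 0:
            raise ValueError(
                f"serum_creatinine_mg_dL must be > 0, got {self.serum_creatinine_mg_dL}"
            )
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex(self.sex))


@dataclass(frozen=True)
class CorrectionFactors:
    """Multiplicative MAP adjustments to the random-effect-bearing parameters.

    Defaults of exactly 1.0 leave the covariate-adjusted typical values
    untouched (the population prediction).
    """

    cl: float = 1.0
    v1: float = 1.0

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v1 <= 0:
            raise ValueError(f"correction factors must be > 0, got cl={self.cl} v1={self.v1}")

    def as_dict(self) -> dict[str, float]:
        return {"CL": self.cl, "V1": self.v1}


@dataclass(frozen=True)
class IndividualParameters:
    """Individual realization of a model's structural parameters."""

    cl_L_h: float
    v1_L: float
    q_L_h: Optional[float] = None
    v2_L: Optional[float] = None
    provenance: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, val in (
            ("cl_L_h", self.cl_L_h),
            ("v1_L", self.v1_L),
            ("q_L_h", self.q_L_h),
            ("v2_L", self.v2_L),
        ):
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be strictly positive, got {val}")
        if (self.q_L_h is None) != (self.v2_L is None):
            raise ValueError("q_L_h and v2_L must be given together")

    @property
    def n_compartments(self) -> int:
        return 1 if self.q_L_h is None else 2


@dataclass(frozen=True)
class ResidualError:
    """Residual (unexplained) error model linking predictions to observations.

    kind 'additive': sd = sigma_add; 'proportional': sd = sigma_prop * pred;
    'combined': variance = sigma_add^2 + (sigma_prop * pred)^2.
    """

    kind: str  # additive | proportional | combined
    sigma_add_mg_L: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual error kind {self.kind!r}")
        if self.kind in ("additive", "combined") and self.sigma_add_mg_L <= 0:
            raise ValueError("sigma_add_mg_L must be > 0 for additive/combined error")
        if self.kind in ("proportional", "combined") and self.sigma_prop <= 0:
            raise ValueError("sigma_prop must be > 0 for proportional/combined error")

    def variance(self, pred_mg_L: float) -> float:
        if self.kind == "additive":
            return self.sigma_add_mg_L**2
        if self.kind == "proportional":
            if pred_mg_L == 0:
                raise ValueError(
                    "proportional-only residual error undefined at predicted concentration 0"
                )
            return (self.sigma_prop * pred_mg_L) ** 2
        return self.sigma_add_mg_L**2 + (self.sigma_prop * pred_mg_L) ** 2


@dataclass(frozen=True)
class PKModelSpec:
    """Structural + statistical definition of a population PK model."""

    drug_name: str
    n_compartments: int
    typical_params: Mapping[str, float]
    covariate_model: Mapping[str, Mapping[str, object]]
    iiv: Mapping[str, float]
    residual_error: ResidualError
    source_id: str = ""
    baseline_interval_h: float = 12.0
    max_daily_frequency: int = 6

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError(f"n_compartments must be 1 or 2, got {self.n_compartments}")
        required = {"CL", "V1"} | ({"Q", "V2"} if self.n_compartments == 2 else set())
        missing = required - set(self.typical_params)
        if missing:
            raise ValueError(f"typical_params missing {sorted(missing)}")
        if self.n_compartments == 1 and ({"Q", "V2"} & set(self.typical_params)):
            raise ValueError("Q/V2 present but n_compartments is 1")
        for name, val in self.typical_params.items():
            if val <= 0:
                raise ValueError(f"typical parameter {name} must be > 0, got {val}")
        for name in self.iiv:
            if name not in self.typical_params:
                raise ValueError(f"IIV parameter {name!r} not in typical_params")
        if self.baseline_interval_h <= 0:
            raise ValueError("baseline_interval_h must be > 0")


def cockcroft_gault(cov: CovariateSet) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min, floored at 0.

    CLcr = (140 - age) * weight / (72 * SCR), multiplied by 0.85 for women.
    """
    if cov.serum_creatinine_mg_dL <= 0:
        raise ValueError("serum creatinine must be > 0")
    clcr = (140.0 - cov.age_years) * cov.weight_kg / (72.0 * cov.serum_creatinine_mg_dL)
    if cov.sex == Sex.FEMALE:
        clcr *= 0.85
    return max(clcr, 0.0)


def _resolve_clcr_ml_min(cov: CovariateSet) -> float:
    """Measured CLcr when available, else Cockcroft-Gault."""
    if cov.clcr_ml_min is not None:
        if cov.clcr_ml_min < 0:
            raise ValueError("measured clcr_ml_min must be >= 0")
        return cov.clcr_ml_min
    for name in ("age_years", "weight_kg", "serum_creatinine_mg_dL", "sex"):
        if getattr(cov, name, None) is None:
            raise MissingCovariateError(
                f"covariate {name!r} required to derive creatinine clearance"
            )
    return cockcroft_gault(cov)


def _cov_value(cov: CovariateSet, name: str) -> float:
    """Look up a named covariate for generic linear-combination forms."""
    if name in ("clcr_ml_min", "clcr"):
        return _resolve_clcr_ml_min(cov)
    val = getattr(cov, name, None)
    if val is None:
        raise MissingCovariateError(f"covariate {name!r} required by model but absent")
    return float(val)


# --- covariate equation forms -------------------------------------------------
# Each form maps (coefficients, covariates) -> individual typical value.

def _form_constant(c: Mapping[str, object], cov: CovariateSet) -> float:
    return float(c["theta"])  # type: ignore[arg-type]


def _form_per_kg(c: Mapping[str, object], cov: CovariateSet) -> float:
    # e.g. V1 = theta [L/kg] * body weight
    return float(c["theta"]) * _cov_value(cov, "weight_kg")  # type: ignore[arg-type]


def _form_linear_clcr(c: Mapping[str, object], cov: CovariateSet) -> float:
    # CL = theta * (CLcr / reference), CLcr in mL/min
    return float(c["theta"]) * _resolve_clcr_ml_min(cov) / float(c["clcr_ref_ml_min"])  # type: ignore[arg-type]


def _form_power_clcr(c: Mapping[str, object], cov: CovariateSet) -> float:
    # CL = theta * (CLcr / reference) ^ exponent
    ratio = _resolve_clcr_ml_min(cov) / float(c["clcr_ref_ml_min"])  # type: ignore[arg-type]
    return float(c["theta"]) * ratio ** float(c.get("exponent", 1.0))  # type: ignore[arg-type]


def _form_power_scr(c: Mapping[str, object], cov: CovariateSet) -> float:
    # CL = theta * (mSCR / reference) ^ exponent with mSCR = max(SCR, floor)
    scr = max(_cov_value(cov, "serum_creatinine_mg_dL"), float(c.get("scr_floor_mg_dL", 0.0)))  # type: ignore[arg-type]
    return float(c["theta"]) * (scr / float(c["scr_ref_mg_dL"])) ** float(c.get("exponent", -1.0))  # type: ignore[arg-type]


def _form_linear_clcr_offset(c: Mapping[str, object], cov: CovariateSet) -> float:
    # CL = theta0 + theta1 * (CLcr [L/h] / reference [L/h]); mL/min -> L/h is * 0.06
    clcr_L_h = _resolve_clcr_ml_min(cov) * 0.06
    return float(c["theta0"]) + float(c["theta1"]) * clcr_L_h / float(c["clcr_ref_L_h"])  # type: ignore[arg-type]


def _form_linear_combination(c: Mapping[str, object], cov: CovariateSet) -> float:
    # theta0 + sum_i coef_i * covariate_i — generic form for user-supplied models
    total = float(c.get("theta0", 0.0))  # type: ignore[arg-type]
    for name, coef in dict(c.get("coefficients", {})).items():  # type: ignore[arg-type]
        total += float(coef) * _cov_value(cov, name)
    return total


COVARIATE_FORMS = {
    "constant": _form_constant,
    "per_kg": _form_per_kg,
    "linear_clcr": _form_linear_clcr,
    "power_clcr": _form_power_clcr,
    "power_scr": _form_power_scr,
    "linear_clcr_offset": _form_linear_clcr_offset,
    "linear_combination": _form_linear_combination,
}


def compute_individual_parameters(
    model: PKModelSpec,
    cov: CovariateSet,
    corr: Optional[CorrectionFactors] = None,
) -> IndividualParameters:
    """Evaluate the model's covariate equations for one patient.

    Typical values are adjusted by the covariate equations and then multiplied
    elementwise by MAP correction factors (CL and V1 only; default 1.0).
    """
    corr = corr or CorrectionFactors()
    values: dict[str, float] = {}
    for name, typical in model.typical_params.items():
        entry = model.covariate_model.get(name)
        if entry is None:
            values[name] = float(typical)
            continue
        form = entry.get("form")
        if form not in COVARIATE_FORMS:
            raise ValueError(f"unknown covariate form {form!r} for parameter {name}")
        values[name] = COVARIATE_FORMS[form](entry, cov)  # type: ignore[index]
    values["CL"] *= corr.cl
    values["V1"] *= corr.v1
    for name, val in values.items():
        if not math.isfinite(val) or val <= 0:
            raise ValueError(
                f"{model.drug_name}: covariate model produced non-positive {name} = {val}"
            )
    provenance = {
        "drug": model.drug_name,
        "correction_factors": corr.as_dict(),
        "covariates": {
            "weight_kg": cov.weight_kg,
            "serum_creatinine_mg_dL": cov.serum_creatinine_mg_dL,
            "age_years": cov.age_years,
            "sex": cov.sex.value,
            "clcr_ml_min": cov.clcr_ml_min,
        },
    }
    return IndividualParameters(
        cl_L_h=values["CL"],
        v1_L=values["V1"],
        q_L_h=values.get("Q"),
        v2_L=values.get("V2"),
        provenance=provenance,
    )
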