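"""Built-in model registry and YAML catalogue round-tripping.

Ships literature population PK models for four ICU antibiotics (meropenem,
ciprofloxacin, ceftriaxone, vancomycin), keyed by drug name. Users may
register additional models (e.g. a locally developed cefotaxime model) either
programmatically or from a YAML catalogue.

The IIV omegas and residual sigmas below are documented placeholders in the
range typical for ICU antibiotic models: the source publications' variability
estimates are not carried in the structural summaries the registry was built
from. They drive only the synthetic-cohort generator and the MAP prior and
are overridable via YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import yaml

from .models import PKModelSpec, ResidualError, UnknownDrugError

__all__ = [
    "get_model",
    "list_models",
    "register_model",
    "model_to_dict",
    "model_from_dict",
    "load_catalogue",
    "dump_catalogue",
]


def _builtin_models() -> dict[str, PKModelSpec]:
    meropenem = PKModelSpec(
        drug_name="meropenem",
        n_compartments=1,
        typical_params={"CL": 11.1, "V1": 33.6},
        covariate_model={
            # CL = 11.1 * (mSCR/0.7)^-1 with mSCR = max(SCR, 0.4 mg/dL)
            "CL": {
                "form": "power_scr",
                "theta": 11.1,
                "scr_ref_mg_dL": 0.7,
                "exponent": -1.0,
                "scr_floor_mg_dL": 0.4,
            },
        },
        iiv={"CL": 0.30, "V1": 0.25},
        residual_error=ResidualError(kind="additive", sigma_add_mg_L=1.0),
        source_id="21366653",
        baseline_interval_h=8.0,
    )
    ciprofloxacin = PKModelSpec(
        drug_name="ciprofloxacin",
        n_compartments=2,
        typical_params={"CL": 18.0, "V1": 38.0, "Q": 60.0, "V2": 73.0},
        covariate_model={
            # CL = 18 * (CLcr/91.7)^theta2; the exponent is configurable
            # (the source's value is not carried here); at CLcr = 91.7 the
            # ratio is 1 and CL = 18 L/h regardless.
            "CL": {
                "form": "power_clcr",
                "theta": 18.0,
                "clcr_ref_ml_min": 91.7,
                "exponent": 1.0,
            },
        },
        iiv={"CL": 0.35, "V1": 0.30},
        residual_error=ResidualError(kind="proportional", sigma_prop=0.20),
        source_id="21653603",
        baseline_interval_h=12.0,
    )
    ceftriaxone = PKModelSpec(
        drug_name="ceftriaxone",
        n_compartments=2,
        typical_params={"CL": 0.56, "V1": 10.3, "Q": 5.28, "V2": 7.35},
        covariate_model={
            # CL = 0.56 + 0.32 * (CLcr/4.26) with CLcr expressed in L/h
            # (4.26 L/h ~ 71 mL/min reference). The source table's rendering
            # of this equation is ambiguous; flagged for verification against
            # the cited publication (PMID 21545483). At CLcr = 0 any
            # linear-in-CLcr reading returns theta_CL = 0.56 L/h.
            "CL": {
                "form": "linear_clcr_offset",
                "theta0": 0.56,
                "theta1": 0.32,
                "clcr_ref_L_h": 4.26,
            },
        },
        iiv={"CL": 0.30, "V1": 0.25},
        residual_error=ResidualError(kind="proportional", sigma_prop=0.20),
        source_id="21545483",
        baseline_interval_h=24.0,
    )
    vancomycin = PKModelSpec(
        drug_name="vancomycin",
        n_compartments=1,
        typical_params={"CL": 4.58, "V1": 107.1},  # V1 typical at 70 kg (1.53 L/kg)
        covariate_model={
            "CL": {"form": "linear_clcr", "theta": 4.58, "clcr_ref_ml_min": 100.0},
            "V1": {"form": "per_kg", "theta": 1.53},
        },
        iiv={"CL": 0.35, "V1": 0.25},
        residual_error=ResidualError(kind="combined", sigma_add_mg_L=1.0, sigma_prop=0.15),
        source_id="21402850",
        baseline_interval_h=12.0,
    )
    return {m.drug_name: m for m in (meropenem, ciprofloxacin, ceftriaxone, vancomycin)}


_REGISTRY: dict[str, PKModelSpec] = _builtin_models()


def list_models() -> list[str]:
    """Names of all registered drugs, sorted."""
    return sorted(_REGISTRY)


def get_model(drug_name: str) -> PKModelSpec:
    """Case-insensitive registry lookup."""
    key = drug_name.strip().lower()
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownDrugError(
            f"no PK model registered for {drug_name!r}; known drugs: {', '.join(list_models())}"
        ) from None


def register_model(model: PKModelSpec, overwrite: bool = False) -> None:
    key = model.drug_name.strip().lower()
    if key in _REGISTRY and not overwrite:
        raise ValueError(f"model for {key!r} already registered (pass overwrite=True)")
    _REGISTRY[key] = dataclasses.replace(model, drug_name=key)


def model_to_dict(model: PKModelSpec) -> dict:
    d = dataclasses.asdict(model)
    d["typical_params"] = dict(model.typical_params)
    d["covariate_model"] = {k: dict(v) for k, v in model.covariate_model.items()}
    d["iiv"] = dict(model.iiv)
    return d


def model_from_dict(d: dict) -> PKModelSpec:
    d = dict(d)
    re_ = d.pop("residual_error")
    if not isinstance(re_, ResidualError):
        re_ = ResidualError(**re_)
    return PKModelSpec(residual_error=re_, **d)


def dump_catalogue(path: Union[str, Path], models: list[PKModelSpec] | None = None) -> None:
    """Serialize models (default: the whole registry) as a YAML catalogue."""
    models = models if models is not None else [_REGISTRY[k] for k in list_models()]
    docs = [model_to_dict(m) for m in models]
    Path(path).write_text(yaml.safe_dump_all(docs, sort_keys=False))


def load_catalogue(path: Union[str, Path], overwrite: bool = True) -> list[PKModelSpec]:
    """Load a YAML catalogue (one document per drug) and register its models."""
    loaded = []
    for doc in yaml.safe_load_all(Path(path).read_text()):
        if doc is None:
            continue
        model = model_from_dict(doc)
        register_model(model, overwrite=overwrite)
        loaded.append(model)
    return loaded
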