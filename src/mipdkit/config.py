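"""Per-drug clinical configuration: targets, safety limits, schedule defaults.

The shipped defaults encode ordinary adult ICU practice (standard doses,
conventional PK/PD targets, conservative toxicity ceilings) and are meant to
be overridden per site from a YAML file. The PK/PD target kind follows the
drug class: trough-anchored %T>MIC for the beta-lactams (meropenem,
ceftriaxone), AUC-based for vancomycin and ciprofloxacin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import yaml

from .advisor import DEFAULT_FRESHNESS_H, SafetyLimits
from .dosing import ExposureTarget, TargetKind
from .registry import get_model

__all__ = ["DrugConfig", "default_config", "default_configs", "load_config"]


@dataclass(frozen=True)
class DrugConfig:
    """Everything the advisor needs to know about one drug."""

    drug: str
    target: ExposureTarget
    limits: SafetyLimits
    baseline_interval_h: float
    infusion_duration_min: float = 60.0
    continuous_enabled: bool = True
    freshness_h: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRESHNESS_H)
    )

    def __post_init__(self) -> None:
        get_model(self.drug)  # must reference a registered model
        if self.baseline_interval_h <= 0 or self.infusion_duration_min <= 0:
            raise ValueError("intervals and infusion durations must be > 0")


def default_configs() -> dict[str, DrugConfig]:
    return {
        "vancomycin": DrugConfig(
            drug="vancomycin",
            target=ExposureTarget(
                kind=TargetKind.AUC_OVER_MIC,
                mic_mg_L=1.0,
                target_auc24_mg_h_L=500.0,
                acceptable_auc_range=(400.0, 600.0),
                acceptable_conc_range_mg_L=(10.0, 30.0),
            ),
            limits=SafetyLimits(
                max_dose_mg=2500.0,
                max_daily_dose_mg=6000.0,
                minimal_toxic_conc_mg_L=60.0,
                standard_daily_dose_mg=2000.0,
            ),
            baseline_interval_h=12.0,
        ),
        "meropenem": DrugConfig(
            drug="meropenem",
            target=ExposureTarget(kind=TargetKind.T_ABOVE_MIC, mic_mg_L=2.0),
            limits=SafetyLimits(
                max_dose_mg=2000.0,
                max_daily_dose_mg=6000.0,
                minimal_toxic_conc_mg_L=150.0,
                standard_daily_dose_mg=3000.0,
            ),
            baseline_interval_h=8.0,
            infusion_duration_min=30.0,
        ),
        "ciprofloxacin": DrugConfig(
            drug="ciprofloxacin",
            target=ExposureTarget(
                kind=TargetKind.AUC_OVER_MIC,
                mic_mg_L=0.5,
                target_auc24_mg_h_L=125.0 * 0.5,  # AUC24/MIC >= 125
            ),
            limits=SafetyLimits(
                max_dose_mg=800.0,
                max_daily_dose_mg=2400.0,
                minimal_toxic_conc_mg_L=20.0,
                standard_daily_dose_mg=1200.0,
            ),
            baseline_interval_h=12.0,
        ),
        "ceftriaxone": DrugConfig(
            drug="ceftriaxone",
            target=ExposureTarget(kind=TargetKind.T_ABOVE_MIC, mic_mg_L=1.0),
            limits=SafetyLimits(
                max_dose_mg=4000.0,
                max_daily_dose_mg=4000.0,
                minimal_toxic_conc_mg_L=400.0,
                standard_daily_dose_mg=2000.0,
            ),
            baseline_interval_h=24.0,
            infusion_duration_min=30.0,
        ),
    }


def default_config(drug: str) -> DrugConfig:
    try:
        return default_configs()[drug.strip().lower()]
    except KeyError:
        raise KeyError(
            f"no default configuration for {drug!r}; known: "
            f"{', '.join(sorted(default_configs()))}"
        ) from None


def load_config(path: Union[str, Path], drug: str) -> DrugConfig:
    """Load a YAML overlay on the defaults for one drug.

    The YAML maps drug name -> {target: {...}, limits: {...}, ...}; any field
    not present keeps its default.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    base = default_config(drug)
    entry = raw.get(drug.strip().lower())
    if not entry:
        return base
    target = base.target
    if "target" in entry:
        t = {**_target_dict(base.target), **entry["target"]}
        for key in ("acceptable_conc_range_mg_L", "acceptable_auc_range"):
            if t.get(key) is not None:
                t[key] = tuple(t[key])
        target = ExposureTarget(**t)
    limits = base.limits
    if "limits" in entry:
        limits = SafetyLimits(**{**base.limits.__dict__, **entry["limits"]})
    return replace(
        base,
        target=target,
        limits=limits,
        baseline_interval_h=entry.get("baseline_interval_h", base.baseline_interval_h),
        infusion_duration_min=entry.get("infusion_duration_min", base.infusion_duration_min),
        continuous_enabled=entry.get("continuous_enabled", base.continuous_enabled),
        freshness_h=entry.get("freshness_h", dict(base.freshness_h)),
    )


def _target_dict(t: ExposureTarget) -> dict:
    return {
        "kind": t.kind.value,
        "mic_mg_L": t.mic_mg_L,
        "target_cmin_mg_L": t.target_cmin_mg_L,
        "trough_multiplier": t.trough_multiplier,
        "target_auc24_mg_h_L": t.target_auc24_mg_h_L,
        "acceptable_conc_range_mg_L": t.acceptable_conc_range_mg_L,
        "acceptable_auc_range": t.acceptable_auc_range,
    }
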