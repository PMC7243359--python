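"""Maintenance and loading dose calculation from PK linearity.

Three principles drive the calculators:

* Dose-exposure proportionality (linear PK): scaling a dose scales every
  exposure metric by the same factor, so a target maintenance dose follows
  from a simulated test dose as MD_target = exposure_target/exposure_test *
  MD_test.
* The analytic AUC relation: at steady state the daily dose equals the daily
  AUC times clearance, MD_daily = AUC24_target * CL — no simulation needed.
* Superposition: the loading dose is sized so that the concentration at the
  end of its infusion reaches the steady-state peak of the maintenance
  regimen, after subtracting the residual concentration Ct_res still present
  from any prior doses (decomposing the PK process into residual decay plus
  the loading dose's own contribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from typing import Optional, Sequence

from .models import IndividualParameters, PKModelSpec
from .simulate import (
    EPOCH,
    DoseEvent,
    ExposureSummary,
    rk4_solve,
    steady_state_metrics,
)

__all__ = [
    "TargetKind",
    "ExposureTarget",
    "RegimenProposal",
    "scale_dose",
    "maintenance_dose_by_scaling",
    "maintenance_dose_by_auc",
    "loading_dose",
]


class TargetKind(str, Enum):
    T_ABOVE_MIC = "T_ABOVE_MIC"
    AUC_OVER_MIC = "AUC_OVER_MIC"


@dataclass(frozen=True)
class ExposureTarget:
    """PK/PD target for a drug.

    T_ABOVE_MIC targets are operationalized as a target steady-state trough of
    ``trough_multiplier`` x MIC (or an explicit ``target_cmin_mg_L``), which
    guarantees 100 %T>MIC at steady state. AUC_OVER_MIC targets state the
    desired AUC over 24 h directly.
    """

    kind: TargetKind
    mic_mg_L: float = 1.0
    target_cmin_mg_L: Optional[float] = None
    trough_multiplier: float = 1.0
    target_auc24_mg_h_L: Optional[float] = None
    acceptable_conc_range_mg_L: Optional[tuple[float, float]] = None
    acceptable_auc_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", TargetKind(self.kind))
        if self.mic_mg_L < 0:
            raise ValueError("mic_mg_L must be >= 0")
        if self.kind == TargetKind.AUC_OVER_MIC:
            if self.target_auc24_mg_h_L is None or self.target_auc24_mg_h_L < 0:
                raise ValueError("AUC_OVER_MIC target requires target_auc24_mg_h_L >= 0")
        else:
            if self.trough_target_mg_L <= 0:
                raise ValueError("T_ABOVE_MIC target requires a positive trough target")
        for rng in (self.acceptable_conc_range_mg_L, self.acceptable_auc_range):
            if rng is not None and not rng[0] < rng[1]:
                raise ValueError(f"range {rng} must satisfy low < high")

    @property
    def trough_target_mg_L(self) -> float:
        if self.target_cmin_mg_L is not None:
            return self.target_cmin_mg_L
        return self.trough_multiplier * self.mic_mg_L


@dataclass(frozen=True)
class RegimenProposal:
    """A concrete dosing regimen with its predicted steady-state exposure."""

    maintenance_dose_mg: float
    interval_h: float
    infusion_duration_min: float
    loading_dose_mg: Optional[float] = None
    predicted: Optional[ExposureSummary] = None
    residual_conc_at_start_mg_L: float = 0.0

    def __post_init__(self) -> None:
        if self.maintenance_dose_mg < 0:
            raise ValueError("maintenance_dose_mg must be >= 0")
        if self.loading_dose_mg is not None and self.loading_dose_mg < 0:
            raise ValueError("loading_dose_mg must be >= 0")

    @property
    def daily_dose_mg(self) -> float:
        return self.maintenance_dose_mg * 24.0 / self.interval_h


class NoSolutionError(RuntimeError):
    """No dose can produce the requested exposure (e.g. zero test exposure)."""


def scale_dose(md_test_mg: float, exposure_test: float, exposure_target: float) -> float:
    """Linear-PK dose scaling: MD_target = exposure_target/exposure_test * MD_test.

    E.g. a 400 mg/day test dose yielding a 10 mg/L trough scales to
    20/10 * 400 = 800 mg/day for a 20 mg/L trough target.
    """
    if exposure_test <= 0:
        raise NoSolutionError(
            f"test exposure is {exposure_test}; cannot scale a dose from zero exposure"
        )
    return md_test_mg * exposure_target / exposure_test


def maintenance_dose_by_scaling(
    model: PKModelSpec,
    params: IndividualParameters,
    interval_h: float,
    target: ExposureTarget,
    test_md_mg: float = 500.0,
    infusion_duration_min: float = 60.0,
    step_min: float = 1.0,
) -> float:
    """Maintenance dose per administration for a trough (%T>MIC) target.

    Simulates a test dose to steady state, reads the trough, and scales the
    dose by the trough ratio (exact under linear PK up to grid
    discretization). The result is independent of the test dose, which a test
    asserts.
    """
    if target.kind != TargetKind.T_ABOVE_MIC:
        raise ValueError("maintenance_dose_by_scaling expects a T_ABOVE_MIC target")
    ss = steady_state_metrics(
        params, test_md_mg, interval_h, infusion_duration_min, step_min=step_min
    )
    return scale_dose(test_md_mg, ss.cmin_mg_L, target.trough_target_mg_L)


def maintenance_dose_by_auc(cl_L_h: float, target_auc24_mg_h_L: float) -> float:
    """Daily maintenance dose (mg/24 h) from the analytic relation MD = AUC x CL."""
    if cl_L_h <= 0:
        raise ValueError(f"clearance must be > 0, got {cl_L_h}")
    if target_auc24_mg_h_L < 0:
        raise ValueError("target AUC must be >= 0")
    return target_auc24_mg_h_L * cl_L_h


def loading_dose(
    model: PKModelSpec,
    params: IndividualParameters,
    md_mg: float,
    interval_h: float,
    dose_history: Sequence[DoseEvent] = (),
    at_time: Optional[datetime] = None,
    infusion_duration_min: float = 60.0,
    test_ld_mg: Optional[float] = None,
    step_min: float = 1.0,
) -> float:
    """Loading dose reaching the maintenance regimen's steady-state peak at once.

    Procedure: (a) simulate the MD regimen to steady state to obtain the
    target Cmax; (b) simulate the residual decay of the prior-dose state until
    the end of the LD infusion, yielding Ct_res; (c) simulate a test LD from a
    drug-free state and read its end-of-infusion concentration; (d) scale the
    test LD by (Cmax - Ct_res) / Cmax_testLD. Returns 0 when the residual
    already meets or exceeds the target peak.
    """
    if md_mg <= 0:
        raise ValueError("md_mg must be > 0")
    ss = steady_state_metrics(params, md_mg, interval_h, infusion_duration_min, step_min=step_min)
    cmax_ss = ss.cmax_mg_L

    ct_res = _residual_concentration(
        params, dose_history, at_time or EPOCH, infusion_duration_min, step_min
    )
    if ct_res >= cmax_ss:
        return 0.0

    ld_test = test_ld_mg if test_ld_mg is not None else md_mg
    inf_h = infusion_duration_min / 60.0
    test_events = [
        DoseEvent(
            drug=model.drug_name,
            amount_mg=ld_test,
            start_time=EPOCH,
            infusion_duration_min=infusion_duration_min,
        )
    ]
    tc = rk4_solve(params, test_events, horizon_h=inf_h, start=EPOCH, step_min=step_min)
    cmax_test = tc.concentration_at(inf_h)
    return scale_dose(ld_test, cmax_test, cmax_ss - ct_res)


def _residual_concentration(
    params: IndividualParameters,
    dose_history: Sequence[DoseEvent],
    ld_start: datetime,
    ld_infusion_duration_min: float,
    step_min: float = 1.0,
) -> float:
    """Concentration from prior doses at the end of the LD infusion (Ct_res)."""
    past = [ev for ev in dose_history if ev.start_time < ld_start]
    if not past:
        return 0.0
    t0 = min(ev.start_time for ev in past)
    ld_end = ld_start + timedelta(minutes=ld_infusion_duration_min)
    horizon_h = (ld_end - t0).total_seconds() / 3600.0
    tc = rk4_solve(params, past, horizon_h=horizon_h, start=t0, step_min=step_min)
    return tc.concentration_at(ld_end)
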