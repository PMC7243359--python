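"""Clinical dosing-advice algorithm with safety constraints.

The advisor iterates over dosing frequencies from the drug's baseline up to
six administrations per day. For each frequency it computes a maintenance
dose (trough-scaling for %T>MIC targets, the analytic AUC relation for
AUC/MIC targets) and accepts the first frequency whose dose per
administration, daily total, and predicted steady-state peak all satisfy the
drug's safety limits. A loading dose is added when needed to reach steady
state immediately; otherwise the advisor reports the maintenance regimen and
an estimated ideal start time at which any residual concentration has decayed
to the regimen's steady-state trough. If no intermittent regimen is safe, a
continuous-infusion advice is produced (when enabled), and failing that the
advisor declines with a referral to the pharmacist.

Advice is always absolute — a dose, interval, and start time — never relative
to the current order, and textual warnings flag doses far from the standard
daily dose as well as stale covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Mapping, Optional, Sequence

from .dosing import (
    ExposureTarget,
    RegimenProposal,
    TargetKind,
    loading_dose,
    maintenance_dose_by_auc,
    maintenance_dose_by_scaling,
    _residual_concentration,
)
from .models import (
    CorrectionFactors,
    IndividualParameters,
    PKModelSpec,
    compute_individual_parameters,
)
from .records import PatientRecord
from .simulate import (
    DoseEvent,
    ExposureSummary,
    rk4_solve,
    steady_state_metrics,
    time_to_steady_state,
)

__all__ = [
    "SafetyLimits",
    "AdviceStatus",
    "AdviceWarning",
    "AdviceOptions",
    "DoseAdvice",
    "advise",
    "staleness_warnings",
    "render_advice_text",
]

#: Allowed administrations per day ("up to six times daily"; 5/day is
#: clinically unused and excluded).
FREQUENCY_LADDER = (1, 2, 3, 4, 6)

DEFAULT_FRESHNESS_H: Mapping[str, float] = {
    "serum_creatinine_mg_dL": 24.0,
    "weight_kg": 7 * 24.0,
}


class AdviceStatus(str, Enum):
    LOADING_PLUS_MAINTENANCE = "LOADING_PLUS_MAINTENANCE"
    MAINTENANCE_ONLY = "MAINTENANCE_ONLY"
    CONTINUOUS = "CONTINUOUS"
    NO_ADVICE = "NO_ADVICE"


@dataclass(frozen=True)
class SafetyLimits:
    """Hard upper limits on an acceptable regimen."""

    max_dose_mg: float
    max_daily_dose_mg: float
    minimal_toxic_conc_mg_L: float
    standard_daily_dose_mg: float

    def __post_init__(self) -> None:
        for name in ("max_dose_mg", "max_daily_dose_mg", "minimal_toxic_conc_mg_L",
                     "standard_daily_dose_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_dose_mg > self.max_daily_dose_mg:
            raise ValueError("max_dose_mg cannot exceed max_daily_dose_mg")


@dataclass(frozen=True)
class AdviceWarning:
    code: str
    text: str


@dataclass(frozen=True)
class AdviceOptions:
    """Tunable advisor behavior; defaults reflect ordinary ward practice."""

    now: Optional[datetime] = None
    continuous_enabled: bool = True
    infusion_duration_min: float = 60.0
    correction_factors: Optional[CorrectionFactors] = None
    freshness_h: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FRESHNESS_H))
    rounding_increment_mg: Optional[float] = None
    test_md_mg: float = 500.0
    step_min: float = 1.0


@dataclass(frozen=True)
class DoseAdvice:
    status: AdviceStatus
    drug: str
    regimen: Optional[RegimenProposal]
    recommended_start_time: Optional[datetime]
    warnings: tuple[AdviceWarning, ...]
    inputs_snapshot: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.status != AdviceStatus.NO_ADVICE and self.regimen is None:
            raise ValueError(f"status {self.status} requires a regimen")


def staleness_warnings(
    patient: PatientRecord,
    freshness_h: Mapping[str, float] = DEFAULT_FRESHNESS_H,
    now: Optional[datetime] = None,
) -> list[AdviceWarning]:
    """One warning per covariate older than its configured maximum age.

    Warnings are ordered deterministically by covariate name.
    """
    now = now or patient.covariates[-1].time
    out: list[AdviceWarning] = []
    for name in sorted(freshness_h):
        limit = freshness_h[name]
        stamped = [c.time for c in patient.covariates if getattr(c, name, None) is not None]
        newest = max(stamped, default=None)
        if newest is None:
            out.append(
                AdviceWarning("MISSING_COVARIATE", f"No recorded value for {name}.")
            )
            continue
        age_h = (now - newest).total_seconds() / 3600.0
        if age_h > limit:
            out.append(
                AdviceWarning(
                    "STALE_COVARIATE",
                    f"Most recent {name} is {age_h:.1f} h old "
                    f"(recommended at most every {limit:.0f} h); "
                    f"older than recommended data is being used.",
                )
            )
    return out


def _round_dose(dose_mg: float, increment: Optional[float], ceiling: float) -> float:
    """Round to the increment, never above the safety ceiling."""
    if increment is None or increment <= 0:
        return dose_mg
    rounded = round(dose_mg / increment) * increment
    while rounded > ceiling:
        rounded -= increment
    return max(rounded, 0.0)


def _dose_range_warnings(daily_mg: float, limits: SafetyLimits) -> list[AdviceWarning]:
    if daily_mg > 2.0 * limits.standard_daily_dose_mg:
        return [
            AdviceWarning(
                "DOSE_ABOVE_USUAL_RANGE",
                f"Advised total of {daily_mg:.0f} mg over 24 h exceeds twice the "
                f"standard daily dose of {limits.standard_daily_dose_mg:.0f} mg; "
                "review before ordering.",
            )
        ]
    if daily_mg < 0.5 * limits.standard_daily_dose_mg:
        return [
            AdviceWarning(
                "DOSE_BELOW_USUAL_RANGE",
                f"Advised total of {daily_mg:.0f} mg over 24 h is below half the "
                f"standard daily dose of {limits.standard_daily_dose_mg:.0f} mg; "
                "review before ordering.",
            )
        ]
    return []


def _maintenance_dose(
    model: PKModelSpec,
    params: IndividualParameters,
    interval_h: float,
    target: ExposureTarget,
    opts: AdviceOptions,
) -> float:
    if target.kind == TargetKind.AUC_OVER_MIC:
        daily = maintenance_dose_by_auc(params.cl_L_h, target.target_auc24_mg_h_L)
        return daily * interval_h / 24.0
    return maintenance_dose_by_scaling(
        model, params, interval_h, target,
        test_md_mg=opts.test_md_mg,
        infusion_duration_min=opts.infusion_duration_min,
        step_min=opts.step_min,
    )


def _is_safe(md_mg: float, freq: int, cmax_mg_L: float, limits: SafetyLimits) -> bool:
    return (
        md_mg <= limits.max_dose_mg
        and md_mg * freq <= limits.max_daily_dose_mg
        and cmax_mg_L < limits.minimal_toxic_conc_mg_L
    )


def _ideal_start_time(
    params: IndividualParameters,
    history: Sequence[DoseEvent],
    now: datetime,
    ss_trough_mg_L: float,
    step_min: float,
) -> datetime:
    """Earliest time at which the residual concentration has decayed to the
    regimen's steady-state trough (1-minute resolution)."""
    past = [ev for ev in history if ev.start_time < now]
    if not past:
        return now
    t0 = min(ev.start_time for ev in past)
    horizon_h = (now - t0).total_seconds() / 3600.0 + min(
        time_to_steady_state(params), 14 * 24.0
    )
    tc = rk4_solve(params, past, horizon_h=horizon_h, start=t0, step_min=step_min)
    now_h = (now - t0).total_seconds() / 3600.0
    mask = tc.times_h >= now_h
    below = mask & (tc.central_conc_mg_L <= ss_trough_mg_L * (1 + 1e-9))
    idx = below.nonzero()[0]
    if len(idx) == 0:
        return now + timedelta(hours=float(tc.times_h[-1] - now_h))
    return t0 + timedelta(hours=float(tc.times_h[idx[0]]))


def advise(
    model: PKModelSpec,
    patient: PatientRecord,
    target: ExposureTarget,
    limits: SafetyLimits,
    options: AdviceOptions = AdviceOptions(),
) -> DoseAdvice:
    """Produce a dosing advice for one patient (deterministic in its inputs)."""
    now = options.now or max(
        [patient.covariates[-1].time] + [d.start_time for d in patient.doses]
    )
    cov = patient.covariates_at(now)
    params = compute_individual_parameters(model, cov, options.correction_factors)
    history = patient.doses_for(model.drug_name)
    warnings = list(staleness_warnings(patient, options.freshness_h, now))
    snapshot = {
        "covariate_time": cov.time.isoformat() if cov.time else None,
        "weight_kg": cov.weight_kg,
        "serum_creatinine_mg_dL": cov.serum_creatinine_mg_dL,
        "age_years": cov.age_years,
        "sex": cov.sex.value,
        "cl_L_h": params.cl_L_h,
        "v1_L": params.v1_L,
        "correction_factors": (options.correction_factors or CorrectionFactors()).as_dict(),
    }

    base_freq = max(1, round(24.0 / model.baseline_interval_h))
    ladder = [f for f in FREQUENCY_LADDER if f >= base_freq]
    if not ladder:
        ladder = [FREQUENCY_LADDER[-1]]

    for freq in ladder:
        interval_h = 24.0 / freq
        try:
            md = _maintenance_dose(model, params, interval_h, target, options)
        except Exception:
            continue
        md = _round_dose(md, options.rounding_increment_mg, limits.max_dose_mg)
        if md <= 0:
            continue
        predicted = steady_state_metrics(
            params, md, interval_h, options.infusion_duration_min,
            mic_mg_L=target.mic_mg_L, step_min=options.step_min,
        )
        if not _is_safe(md, freq, predicted.cmax_mg_L, limits):
            continue

        ld = loading_dose(
            model, params, md, interval_h, history,
            at_time=now,
            infusion_duration_min=options.infusion_duration_min,
            step_min=options.step_min,
        )
        ld = _round_dose(ld, options.rounding_increment_mg, limits.max_dose_mg)
        if ld > limits.max_dose_mg:
            ld = limits.max_dose_mg
            warnings.append(
                AdviceWarning(
                    "LD_CAPPED",
                    f"Loading dose capped at the per-administration limit of "
                    f"{limits.max_dose_mg:.0f} mg; steady state will be reached "
                    "more slowly.",
                )
            )
        ct_res = _residual_concentration(
            params, history, now, options.infusion_duration_min, options.step_min
        )
        warnings.extend(_dose_range_warnings(md * freq, limits))

        regimen = RegimenProposal(
            maintenance_dose_mg=md,
            interval_h=interval_h,
            infusion_duration_min=options.infusion_duration_min,
            loading_dose_mg=ld if ld > 0 else None,
            predicted=predicted,
            residual_conc_at_start_mg_L=ct_res,
        )
        # independent re-check of the safety predicates
        assert _is_safe(regimen.maintenance_dose_mg, freq, predicted.cmax_mg_L, limits)
        if ld > 0:
            status = AdviceStatus.LOADING_PLUS_MAINTENANCE
            start = now
        else:
            status = AdviceStatus.MAINTENANCE_ONLY
            start = _ideal_start_time(
                params, history, now, predicted.cmin_mg_L, options.step_min
            )
        return DoseAdvice(
            status=status,
            drug=model.drug_name,
            regimen=regimen,
            recommended_start_time=start,
            warnings=tuple(warnings),
            inputs_snapshot=snapshot,
        )

    if options.continuous_enabled:
        advice = _continuous_advice(
            model, params, target, limits, history, now, warnings, snapshot, options
        )
        if advice is not None:
            return advice

    warnings.append(
        AdviceWarning(
            "NO_SAFE_REGIMEN",
            "No dosing regimen satisfies the safety limits; please contact the "
            "support team or the pharmacist.",
        )
    )
    return DoseAdvice(
        status=AdviceStatus.NO_ADVICE,
        drug=model.drug_name,
        regimen=None,
        recommended_start_time=None,
        warnings=tuple(warnings),
        inputs_snapshot=snapshot,
    )


def _continuous_advice(
    model: PKModelSpec,
    params: IndividualParameters,
    target: ExposureTarget,
    limits: SafetyLimits,
    history: Sequence[DoseEvent],
    now: datetime,
    warnings: list[AdviceWarning],
    snapshot: Mapping[str, object],
    options: AdviceOptions,
) -> Optional[DoseAdvice]:
    """Continuous-infusion fallback: a rate consistent with the target."""
    if target.kind == TargetKind.AUC_OVER_MIC:
        daily = maintenance_dose_by_auc(params.cl_L_h, target.target_auc24_mg_h_L)
    else:
        # steady-state concentration of a continuous infusion is rate/CL
        daily = target.trough_target_mg_L * params.cl_L_h * 24.0
    css = daily / 24.0 / params.cl_L_h
    if daily > limits.max_daily_dose_mg or css >= limits.minimal_toxic_conc_mg_L:
        return None
    warnings = list(warnings) + _dose_range_warnings(daily, limits)
    ld = loading_dose(
        model, params, daily, 24.0, history,
        at_time=now,
        infusion_duration_min=1440.0,
        step_min=options.step_min,
    )
    ld = min(ld, limits.max_dose_mg)
    predicted = ExposureSummary(
        auc_mg_h_L=css * 24.0,
        cmin_mg_L=css,
        cmax_mg_L=css,
        pct_time_above_mic=100.0 if css > target.mic_mg_L else 0.0,
        window_h=(0.0, 24.0),
    )
    regimen = RegimenProposal(
        maintenance_dose_mg=daily,
        interval_h=24.0,
        infusion_duration_min=1440.0,
        loading_dose_mg=ld if ld > 0 else None,
        predicted=predicted,
        residual_conc_at_start_mg_L=_residual_concentration(
            params, history, now, options.infusion_duration_min, options.step_min
        ),
    )
    return DoseAdvice(
        status=AdviceStatus.CONTINUOUS,
        drug=model.drug_name,
        regimen=regimen,
        recommended_start_time=now,
        warnings=tuple(warnings),
        inputs_snapshot=snapshot,
    )


def render_advice_text(advice: DoseAdvice) -> str:
    """Plain-text rendering: absolute doses only, never relative to prior orders."""
    lines = [f"Dosing advice for {advice.drug}:"]
    r = advice.regimen
    if advice.status == AdviceStatus.NO_ADVICE:
        lines.append("  No safe dosing advice could be generated.")
        lines.append("  Please contact the support team or the pharmacist.")
    elif advice.status == AdviceStatus.CONTINUOUS:
        rate = r.maintenance_dose_mg / 24.0
        if r.loading_dose_mg:
            lines.append(f"  Loading dose: {r.loading_dose_mg:.0f} mg.")
        lines.append(
            f"  Continuous infusion at {rate:.1f} mg/h "
            f"({r.maintenance_dose_mg:.0f} mg per 24 h)."
        )
        lines.append(f"  Start at {advice.recommended_start_time.isoformat()}.")
    else:
        if advice.status == AdviceStatus.LOADING_PLUS_MAINTENANCE:
            lines.append(f"  Loading dose: {r.loading_dose_mg:.0f} mg now.")
        lines.append(
            f"  Maintenance dose: {r.maintenance_dose_mg:.0f} mg every "
            f"{r.interval_h:g} h (infused over {r.infusion_duration_min:.0f} min)."
        )
        lines.append(
            f"  Recommended start time: {advice.recommended_start_time.isoformat()}."
        )
    if r is not None and r.predicted is not None:
        p = r.predicted
        lines.append(
            f"  Predicted steady state: AUC24 {p.auc_mg_h_L:.0f} mg*h/L, "
            f"Cmin {p.cmin_mg_L:.1f} mg/L, Cmax {p.cmax_mg_L:.1f} mg/L, "
            f"%T>MIC {p.pct_time_above_mic:.0f}%."
        )
    for w in advice.warnings:
        lines.append(f"  WARNING [{w.code}]: {w.text}")
    return "\n".join(lines)
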