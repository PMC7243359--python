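"""Generate a clinical dosing advice with safety constraints.

The advisor iterates dosing frequencies, sizes a maintenance dose to the
drug's PK/PD target (here: vancomycin AUC24 of 500 mg*h/L), adds a loading
dose to reach the steady-state peak immediately, and enforces per-dose,
daily, and peak-concentration safety limits. The advice is absolute — dose,
interval, start time — never relative to a prior order.
"""

import mipdkit as mk

patient = mk.PatientRecord(
    id="example",
    covariates=[mk.CovariateSet(weight_kg=70.0, serum_creatinine_mg_dL=1.0,
                                age_years=40.0, sex=mk.Sex.MALE,
                                clcr_ml_min=100.0, time=mk.EPOCH)],
)
cfg = mk.default_config("vancomycin")
advice = mk.advise(mk.get_model("vancomycin"), patient, cfg.target, cfg.limits,
                   mk.AdviceOptions(now=mk.EPOCH))
print(mk.render_advice_text(advice))

# An unreachable toxicity ceiling (with continuous dosing disabled) yields a
# NO_ADVICE referral instead of an unsafe regimen:
import dataclasses
tight = dataclasses.replace(cfg.limits, minimal_toxic_conc_mg_L=0.5)
refused = mk.advise(mk.get_model("vancomycin"), patient, cfg.target, tight,
                    mk.AdviceOptions(now=mk.EPOCH, continuous_enabled=False))
print()
print(mk.render_advice_text(refused))
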