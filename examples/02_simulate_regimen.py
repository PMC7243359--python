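"""Simulate a vancomycin regimen and summarize PK exposure.

Integrates 1000 mg q12h (60-min infusions) for 48 h on the 1-minute RK4 grid,
prints exposure metrics for the final day, and verifies the solver against
the closed-form one-compartment solution — the median absolute difference
should be at floating-point level.
"""

import numpy as np

import mipdkit as mk

cov = mk.CovariateSet(weight_kg=70.0, serum_creatinine_mg_dL=1.0, age_years=40.0,
                      sex=mk.Sex.MALE, clcr_ml_min=100.0)
params = mk.compute_individual_parameters(mk.get_model("vancomycin"), cov)
print(f"individual parameters: CL={params.cl_L_h} L/h, V1={params.v1_L:.1f} L")
print(f"terminal half-life: {mk.terminal_half_life(params):.1f} h; "
      f"steady state after ~{mk.time_to_steady_state(params):.0f} h\n")

events = mk.build_regimen("vancomycin", 1000.0, 12.0, 4, mk.EPOCH, 60.0)
tc = mk.rk4_solve(params, events, horizon_h=48.0)
s = mk.summarize_exposure(tc, window_h=(24.0, 48.0), mic_mg_L=1.0)
print(f"day 2 exposure: AUC={s.auc_mg_h_L:.0f} mg*h/L, Cmin={s.cmin_mg_L:.1f}, "
      f"Cmax={s.cmax_mg_L:.1f} mg/L, %T>MIC={s.pct_time_above_mic:.0f}%")

exact = mk.closed_form_one_compartment(params, events, tc.times_h)
print(f"median |RK4 - analytic| = "
      f"{np.median(np.abs(tc.central_conc_mg_L - exact)):.2e} mg/L")
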