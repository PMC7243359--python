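"""Bayesian MAP individualization from measured plasma levels.

A synthetic patient is simulated with known deviations from the population
(CL x1.5, V1 x0.8); noisy peak/trough samples are drawn; simulated annealing
then recovers multiplicative correction factors by balancing the lognormal
IIV prior against the residual-error likelihood. The printed factors should
land near the simulated truth.
"""

from datetime import timedelta

import mipdkit as mk

model = mk.get_model("vancomycin")
cov = mk.CovariateSet(weight_kg=70.0, serum_creatinine_mg_dL=1.0, age_years=40.0,
                      sex=mk.Sex.MALE, clcr_ml_min=100.0, time=mk.EPOCH)
patient = mk.PatientRecord(id="tdm", covariates=[cov])

truth = mk.CorrectionFactors(cl=1.5, v1=0.8)
doses = mk.build_regimen("vancomycin", 1000.0, 12.0, 6, mk.EPOCH, 60.0)
times = [mk.EPOCH + timedelta(hours=12 * k + o)
         for k in range(6) for o in (1.0, 4.0, 8.0, 11.9)]
obs = mk.simulate_observed_levels(model, patient, doses, times, seed=7, factors=truth)
print(f"simulated truth: CL x{truth.cl}, V1 x{truth.v1}; {len(obs)} noisy samples")

est, fitted = mk.map_estimate(model, cov, doses, obs, seed=11)
print(f"MAP estimate:    CL x{est.cl:.3f}, V1 x{est.v1:.3f}")
print(f"fitted trough at 72 h: {fitted.concentration_at(71.9):.1f} mg/L")
print("(factors within ~15% of truth; shrinkage toward 1 reflects the IIV prior)")
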