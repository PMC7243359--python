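# mipdkit

A model-informed precision dosing (MIPD) toolkit for intravenous antibiotics
in critically ill patients. Sepsis pharmacokinetics (PK) vary enormously
between ICU patients — renal function, body weight, and fluid status shift
clearance and distribution volume many-fold — so standard dosing frequently
misses the exposure that kills the pathogen. `mipdkit` implements the
computational core of a bedside dosing decision-support workflow: population
PK models evaluated from routine covariates, simulation of any dosing
schedule, maintenance- and loading-dose calculation, a safety-constrained
dosing-advice algorithm, and Bayesian individualization when measured plasma
levels are available. Everything is testable offline on synthetic patients;
there is no EHR connectivity.

It is a library first (`import mipdkit`), with narrative scripts under
`examples/` and a thin `mipd` command-line wrapper
(`advise` / `simulate` / `fit` / `synth` / `evaluate`).

## The model

Drug amounts follow a linear one- or two-compartment system,

    dA1/dt = R(t) − (CL/V1)·A1 − (Q/V1)·A1 + (Q/V2)·A2
    dA2/dt =        (Q/V1)·A1 − (Q/V2)·A2,          C = A1/V1,

with infusion rate R(t), clearance CL (L/h), central/peripheral volumes V1,
V2 (L), and inter-compartmental clearance Q (L/h). Four literature
population models ship in the registry (meropenem, ciprofloxacin,
ceftriaxone, vancomycin) with covariate equations on CL (renal function via
serum creatinine or Cockcroft–Gault CLcr) and, for vancomycin, weight-based
V1 = 1.53 L/kg. The system is integrated with a classical fourth-order
Runge–Kutta scheme on a 1-minute grid; a closed-form one-compartment
solution serves as an independent oracle.

Dosing rests on PK linearity:

* **Maintenance dose (trough target):** MD_target = (C_min,target /
  C_min,test) · MD_test, with the test trough read from a steady-state
  simulation (seven terminal half-lives).
* **Maintenance dose (AUC target):** MD_daily = AUC24_target × CL, no
  simulation required.
* **Loading dose:** by superposition, LD is sized so the concentration at
  the end of its infusion reaches the maintenance regimen's steady-state
  peak after subtracting the residual concentration from prior doses.

The advisor iterates frequencies (baseline up to six daily), accepts the
first regimen satisfying the per-dose, per-day, and peak-toxicity limits,
falls back to a continuous infusion, and otherwise declines with a referral.
Given measured levels, correction factors f on CL and V1 are estimated by
maximizing the posterior combining a lognormal IIV prior (mode at f = 1,
log-SD ω) with the model's residual-error likelihood, using seeded simulated
annealing (5,000 proposals).

## Worked example

```python
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
```

prints

```
Dosing advice for vancomycin:
  Loading dose: 2500 mg now.
  Maintenance dose: 1145 mg every 12 h (infused over 60 min).
  Recommended start time: 2024-01-01T00:00:00+00:00.
  Predicted steady state: AUC24 498 mg*h/L, Cmin 16.2 mg/L, Cmax 26.0 mg/L, %T>MIC 100%.
  WARNING [LD_CAPPED]: Loading dose capped at the per-administration limit of 2500 mg; ...
```

Reading: the patient's clearance (4.58 L/h at CLcr 100 mL/min) times the
AUC24 target of 500 mg·h/L gives 2290 mg/day, split as 1145 mg q12h; the
predicted steady-state AUC of 498 mg·h/L confirms the target; the loading
dose that would reach the steady-state peak at once (2842 mg) exceeds the
per-administration limit and is capped with a warning. The scripts in
`examples/` walk through each capability (covariate models, simulation, MAP
individualization, cohort evaluation) and print one-line interpretations.

## Layout

```
src/mipdkit/
  models.py     covariate models, Cockcroft-Gault, individual parameters
  registry.py   built-in model catalogue (+ YAML round-trip)
  simulate.py   RK4 engine, closed-form oracle, exposure metrics
  dosing.py     maintenance/loading dose calculators
  advisor.py    dosing-advice algorithm, safety limits, warnings
  mapfit.py     MAP estimation via simulated annealing
  cohort.py     synthetic ICU cohort + paired regimen evaluation
  config.py     per-drug targets/limits (YAML-overridable)
  io.py, cli.py file schemas and the `mipd` command
docs/methods.md the modeling and validation notes
```

Not in scope: EHR/laboratory connectivity, databases and GUIs, nonlinear
(saturable) elimination, antibiotic choice or treatment duration, and
closed-loop ordering — advice is always mediated by a clinician.
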