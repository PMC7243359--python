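# Methods

## Structural model and solver

All registered models are linear mammillary systems (one or two
compartments) with zero-order infusion input into the central compartment
and first-order elimination CL/V1 from it. Infusions are the only input
route (IV antibiotics); oral absorption is out of scope. Bolus doses are
represented as 1-minute infusions and dose times are snapped to the nearest
grid point, matching the solver's resolution.

The integrator is classical fourth-order Runge–Kutta with a fixed 1-minute
step (configurable via `step_min`). The infusion forcing is piecewise
constant per step — within each step the rate active at the step's start is
used — so a single RK4 step reduces exactly to the affine map
`y⁺ = M·y + N·u` with

    M = I + hA + (hA)²/2 + (hA)³/6 + (hA)⁴/24
    N = h·(I + hA/2 + (hA)²/6 + (hA)³/24)

(`A` the system matrix, `h` the step in hours, `u` the constant input-rate
vector). The engine propagates this map in closed form over runs of constant
rate: scalar geometric recurrences for one compartment, the eigenbasis of
`M` for two. This is algebraically the same trajectory a literal RK4 step
loop produces (a test asserts agreement to 1e-9) but runs in O(grid) numpy
work, which is what lets the advisor-safety and parameter-recovery studies
run at full size. A plain step loop remains as a fallback for
(near-)defective step matrices (repeated eigenvalues), which do not occur
for physiological parameter sets.

Accuracy: against the closed-form one-compartment solution the 1-minute RK4
grid agrees to ~5e-14 mg/L (median) on a 48-h vancomycin regimen — the
truncation error scale is (k·h)⁵ per step with k·h ≈ 7e-4. A convergence
test on a stiff decay (k = 2 h⁻¹) confirms fourth-order behavior (halving
the step cuts the max error ≈16×).

## Covariate models

* **Vancomycin** (one compartment): CL = 4.58 × (CLcr/100) L/h,
  V1 = 1.53 L/kg × body weight. CLcr in mL/min; a measured/derived
  `clcr_ml_min` takes precedence, otherwise Cockcroft–Gault
  (140 − age)·weight/(72·SCR), ×0.85 for women, floored at 0.
* **Meropenem** (one compartment): CL = 11.1 × (mSCR/0.7)⁻¹ with
  mSCR = max(SCR, 0.4 mg/dL); the clamp prevents clearance blow-up at very
  low creatinine. V1 = 33.6 L.
* **Ciprofloxacin** (two compartments): CL = 18 × (CLcr/91.7)^θ₂;
  the source's exponent is not carried in our structural summary, so
  θ₂ defaults to 1 and is configurable. At the 91.7 mL/min reference the
  ratio is 1 and CL = 18 L/h regardless. V1 = 38 L, Q = 60 L/h, V2 = 73 L.
* **Ceftriaxone** (two compartments): the source table's covariate equation
  is ambiguous; implemented as CL = 0.56 + 0.32 × (CLcr[L/h]/4.26), with
  CLcr converted to L/h (×0.06) because 4.26 L/h ≈ 71 mL/min is a plausible
  reference clearance, whereas reading 4.26 in mL/min yields CL ≈ 8 L/h at
  normal renal function — implausible for ceftriaxone. Any linear-in-CLcr
  reading returns the 0.56 L/h intercept at CLcr = 0. Flagged in the
  registry for verification against the cited publication (PMID 21545483).
* **Cefotaxime**: no model ships; the registry accepts a user-supplied
  one-compartment spec (a generic `linear_combination` covariate form covers
  albumin/SOFA/creatinine effects on CL).

Covariate equations are stored as named forms with coefficients so
catalogues round-trip through YAML. Correction factors act multiplicatively
on CL and V1 after covariate adjustment.

**Variability placeholders.** The IIV omegas (0.25–0.35) and residual sigmas
(additive 1 mg/L; proportional 15–20%) are documented placeholders in the
range typical for ICU antibiotic popPK models; the structural summaries the
registry was built from do not carry the sources' variability estimates.
They drive only the synthetic-data generator and the MAP prior, are
config-overridable, and every deterministic result (covariate clearances,
solver accuracy, dose calculations, safety gating) is independent of them.

## Dose calculation

Linearity is the premise: exposure is proportional to dose, and total
exposure over a day is invariant to how the daily dose is divided (tests
assert both to <1%).

* **Trough-targeted MD** (beta-lactams, %T>MIC): simulate a test dose at the
  chosen interval to steady state, read the trough, scale by the trough
  ratio. The result is test-dose independent (asserted). The trough target
  defaults to 1 × MIC (configurable multiplier), which pins the steady-state
  concentration at or above the MIC for the whole interval; with the trough
  exactly at the MIC the strict `>` comparison in %T>MIC reports ~99.8%
  rather than 100% (boundary grid points).
* **AUC-targeted MD** (vancomycin, ciprofloxacin): MD_daily = AUC24 × CL.
* **Loading dose:** target peak = steady-state C_max of the MD regimen;
  residual concentration Ct_res from prior doses is simulated to the end of
  the LD infusion and subtracted; a test LD from drug-free state is scaled
  by (C_max − Ct_res)/C_max,test. Never negative: if the residual already
  reaches the target peak, LD = 0. With accumulation the LD legitimately
  exceeds one MD.

**Steady state** is taken as reached after seven terminal half-lives
(2⁻⁷ ≈ 0.8% residual deficit). Regimens are simulated for
`ceil(7·t½/interval) + 1` intervals so that the *measured* final interval
starts beyond seven half-lives; this keeps the AUC-closure identity inside
1%. Simulated time toward steady state is capped at 14 days to bound
runtime for very low clearances; for such patients the "steady-state"
metrics are the 14-day profile.

## Dosing-advice algorithm

Frequencies iterate from the drug's baseline (config: meropenem q8h,
vancomycin and ciprofloxacin q12h, ceftriaxone q24h) upward through
{1, 2, 3, 4, 6}/day (5/day is clinically unused). The first frequency whose
MD satisfies (i) MD ≤ max single dose, (ii) daily total ≤ max daily dose,
and (iii) predicted steady-state C_max < minimal toxic concentration is
accepted — first-feasible, so advice is deterministic. MD safety gates
acceptance first; the LD is then computed and, if it exceeds the
per-administration limit, capped at that limit with an explicit warning
(steady state is then approached over a few intervals instead of one).

If a positive LD is needed the advice starts now (loading + maintenance);
otherwise the ideal start time is the first minute at which the residual
concentration has decayed to the regimen's steady-state trough. If no
intermittent regimen is safe and continuous dosing is enabled, the advice is
a rate consistent with the target (AUC: AUC24×CL/24 mg/h; trough target:
C_target×CL), checked against the daily limit and the toxic ceiling;
otherwise NO_ADVICE with a pharmacist referral. Warnings: daily dose more
than twice or less than half the standard daily dose, covariates older than
their freshness limit (creatinine 24 h, weight 7 d by default), and the LD
cap. Advice is always absolute, never "increase/decrease by X" relative to a
prior order.

The shipped per-drug targets and limits (e.g. vancomycin AUC24 500 mg·h/L,
toxic peak 60 mg/L, max 2500 mg/dose and 6 g/day; meropenem MIC 2 mg/L) are
ordinary adult ICU practice defaults, config-overridable, and are the
conditions under which the safety study runs.

## MAP individualization

Objective: Σ_j [(y_j − ŷ_j)²/(2σ_j²) + ½ln(2πσ_j²)] +
Σ_i (ln f_i)²/(2ω_i²), with σ_j² from the model's residual error kind
(additive σ_a²; proportional (σ_p·ŷ)², undefined at ŷ = 0; combined the
sum) and factors on CL and V1 only — Q and V2 stay at covariate-adjusted
typicals. Search: simulated annealing on log-factors bounded to ±ln 10
(factors 0.1–10×, wide enough for the up-to-500-fold concentration
variation reported in ICU cohorts while excluding degenerate excursions);
Gaussian proposals (SD 0.05), geometric cooling (T₀ = 1, α = 0.999), 5,000
iterations counted as proposals, best-seen state returned. All settings are
config-exposed; identical seeds give bit-identical results. The dose grid is
resolved once per fit and reused across the 5,000 objective evaluations.

**Validation design.** The recovery study simulates a patient with known
deviations (CL ×1.5, V1 ×0.8) and fits from noisy samples. Two facts shape
the design: trough-only sampling is nearly uninformative about V1, and with
sparse data the lognormal prior deliberately shrinks the MAP mode toward 1 —
that shrinkage is the estimator working as designed, verified directly
against a dense grid of the posterior (the annealer tracks the true mode to
~1%). To test the *estimator* rather than the information content of a
sparse design, the recovery study uses dense TDM sampling (4 samples per
12-h interval over 72 h); under that design ≥90% of 50 seeded replicates
recover both factors within 15%. Sparse-data behavior is covered by the
prior/likelihood-balance tests (σ→0 pulls the mode to the data-implied
factors; σ→∞ returns it to 1).

## Synthetic cohort

Per patient: weight ~ N(80, 18) kg, age ~ U(18, 90), sex 60/40 male/female,
creatinine lognormal around 0.9 mg/dL, albumin ~ N(28, 6) g/L, all clipped
to hard ranges (weight 40–150 kg, SCR 0.3–5 mg/dL); creatinine follows a
multiplicative random walk (log-SD 0.15/day) emulating day-to-day renal
drift. IIV factors are lognormal(0, ω); observations add residual noise per
the model's error kind and truncate at 0. The paired evaluation harness
simulates 24 h from an anchor per patient and strategy and scores percent
time in the 10–30 mg/L window and AUC24 against 400–600 mg·h/L. The
"low-noise" attainment condition scales the truth IIV by 0.3 (ω ≈ 0.1),
chosen once as the generator's low-noise setting.

What the generator does **not** emulate: EHR artifacts (missing or stale
labs beyond the drift model, unit errors, undocumented doses), assay limits
of quantification, non-adherent administration times, and nonlinear
(saturable) kinetics. Passing tests therefore demonstrate correctness of
the algorithms under the models' own assumptions, not bedside performance.

## Numerical choices and degenerate inputs

* Grid: 1-minute steps; windows and event times snapped to the grid; AUC by
  the trapezoidal rule on grid points; %T>MIC as the fraction of grid points
  strictly above the MIC.
* Problem sizes: the safety study uses 1,000 synthetic patients round-robin
  across the four drugs; the recovery study 50 replicates; the loading-dose
  contract 24 randomized scenarios — sizes chosen to exercise all branches
  while keeping the default suite fast.
* Zero test exposure (e.g. absurd clearance) raises `NoSolutionError`
  instead of dividing by zero; non-positive parameters, negative amounts,
  events outside the horizon, and empty windows are rejected with named
  errors; concentrations are clipped of negative float dust.
* `CorrectionFactors` defaults are exactly 1.0; an empty observation set
  returns them without search.

## Known limitations

Linear PK only (ceftriaxone's saturable protein binding is not modeled);
no stiff-solver alternative (unnecessary for linear systems at this step
size); no posterior uncertainty (MAP point estimates only); single-drug
advice with no interaction or duration logic; the 14-day steady-state cap
understates exposure for extremely low clearance.
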