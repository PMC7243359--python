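"""Evaluate population PK models for an individual ICU patient.

Builds a covariate set for a 70 kg, 40-year-old man and prints each drug's
individual clearance and volume. Clearance scales with renal function
(Cockcroft-Gault creatinine clearance or serum creatinine, depending on the
model); vancomycin's central volume scales with body weight.
"""

import mipdkit as mk

cov = mk.CovariateSet(
    weight_kg=70.0, serum_creatinine_mg_dL=1.0, age_years=40.0, sex=mk.Sex.MALE,
)
print(f"Cockcroft-Gault CLcr: {mk.cockcroft_gault(cov):.1f} mL/min\n")

for drug in mk.list_models():
    model = mk.get_model(drug)
    p = mk.compute_individual_parameters(model, cov)
    extra = f", Q={p.q_L_h} L/h, V2={p.v2_L} L" if p.n_compartments == 2 else ""
    print(f"{drug:>13}: CL={p.cl_L_h:6.2f} L/h, V1={p.v1_L:6.1f} L{extra}"
          f"   (source PMID {model.source_id})")

# A MAP correction factor acts multiplicatively on CL and V1:
adj = mk.compute_individual_parameters(
    mk.get_model("vancomycin"), cov, mk.CorrectionFactors(cl=1.5, v1=0.8)
)
print(f"\nvancomycin with CL x1.5, V1 x0.8: CL={adj.cl_L_h:.2f} L/h, V1={adj.v1_L:.1f} L")
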