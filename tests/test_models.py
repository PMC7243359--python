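"""Covariate models, Cockcroft-Gault, and registry behavior."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mipdkit as mk
from mipdkit.models import MissingCovariateError


def cov(weight=70.0, scr=1.0, age=40.0, sex=mk.Sex.MALE, clcr=None):
    return mk.CovariateSet(
        weight_kg=weight, serum_creatinine_mg_dL=scr, age_years=age, sex=sex,
        clcr_ml_min=clcr,
    )


class TestCockcroftGault:
    def test_hand_evaluated_male(self):
        # (140-40)*70 / (72*1.0) = 97.22 mL/min
        assert mk.cockcroft_gault(cov()) == pytest.approx(97.2222, abs=1e-3)

    def test_female_factor(self):
        male = mk.cockcroft_gault(cov())
        female = mk.cockcroft_gault(cov(sex=mk.Sex.FEMALE))
        assert female == pytest.approx(0.85 * male)
        assert female == pytest.approx(82.6389, abs=1e-3)

    def test_floored_at_zero_for_extreme_age(self):
        assert mk.cockcroft_gault(cov(age=140.0)) == 0.0
        assert mk.cockcroft_gault(cov(age=150.0)) == 0.0

    def test_measured_clcr_takes_precedence(self):
        m = mk.get_model("vancomycin")
        p_measured = mk.compute_individual_parameters(m, cov(clcr=50.0))
        p_derived = mk.compute_individual_parameters(m, cov())
        assert p_measured.cl_L_h == pytest.approx(4.58 * 0.5)
        assert p_derived.cl_L_h == pytest.approx(4.58 * 97.2222 / 100.0, abs=1e-3)


class TestCovariateModels:
    def test_vancomycin_reference(self):
        m = mk.get_model("vancomycin")
        p = mk.compute_individual_parameters(m, cov(clcr=100.0))
        assert p.cl_L_h == 4.58
        assert p.v1_L == pytest.approx(1.53 * 70.0)
        assert p.n_compartments == 1

    def test_meropenem_reference(self):
        m = mk.get_model("meropenem")
        p = mk.compute_individual_parameters(m, cov(scr=0.7))
        assert p.cl_L_h == 11.1
        assert p.v1_L == 33.6

    def test_meropenem_creatinine_clamp(self):
        m = mk.get_model("meropenem")
        at_02 = mk.compute_individual_parameters(m, cov(scr=0.2))
        at_04 = mk.compute_individual_parameters(m, cov(scr=0.4))
        assert at_02.cl_L_h == at_04.cl_L_h

    def test_ciprofloxacin_exponent_independent_at_reference(self):
        m = mk.get_model("ciprofloxacin")
        for exponent in (0.3, 1.0, 2.5):
            m2 = dataclasses.replace(
                m, covariate_model={"CL": {**m.covariate_model["CL"], "exponent": exponent}}
            )
            p = mk.compute_individual_parameters(m2, cov(clcr=91.7))
            assert p.cl_L_h == pytest.approx(18.0, abs=1e-12)

    def test_ciprofloxacin_is_two_compartment(self):
        p = mk.compute_individual_parameters(mk.get_model("ciprofloxacin"), cov(clcr=91.7))
        assert (p.q_L_h, p.v2_L) == (60.0, 73.0)

    def test_ceftriaxone_intercept_at_zero_clearance(self):
        m = mk.get_model("ceftriaxone")
        p = mk.compute_individual_parameters(m, cov(clcr=0.0))
        assert p.cl_L_h == pytest.approx(0.56)

    def test_vancomycin_monotone_in_clcr(self):
        m = mk.get_model("vancomycin")
        cls = [mk.compute_individual_parameters(m, cov(clcr=c)).cl_L_h
               for c in (20, 60, 100, 140)]
        assert cls == sorted(cls) and len(set(cls)) == 4

    def test_meropenem_monotone_decreasing_above_clamp(self):
        m = mk.get_model("meropenem")
        cls = [mk.compute_individual_parameters(m, cov(scr=s)).cl_L_h
               for s in (0.5, 1.0, 2.0, 4.0)]
        assert cls == sorted(cls, reverse=True)

    @settings(max_examples=25, deadline=None)
    @given(factor=st.floats(0.1, 10.0))
    def test_correction_factors_act_multiplicatively(self, factor):
        m = mk.get_model("vancomycin")
        base = mk.compute_individual_parameters(m, cov(clcr=80.0))
        adj = mk.compute_individual_parameters(
            m, cov(clcr=80.0), mk.CorrectionFactors(cl=factor, v1=factor)
        )
        assert adj.cl_L_h == pytest.approx(factor * base.cl_L_h, rel=1e-12)
        assert adj.v1_L == pytest.approx(factor * base.v1_L, rel=1e-12)

    def test_missing_covariate_named_in_error(self):
        m = mk.get_model("meropenem")
        bad = dataclasses.replace(
            m,
            covariate_model={
                "CL": {"form": "linear_combination", "theta0": 1.0,
                       "coefficients": {"albumin_g_L": 0.1}},
            },
        )
        with pytest.raises(MissingCovariateError, match="albumin_g_L"):
            mk.compute_individual_parameters(bad, cov())


class TestRegistry:
    def test_lookup_is_case_insensitive_with_source_ids(self):
        assert mk.get_model("Vancomycin").source_id == "21402850"
        assert mk.get_model("MEROPENEM").source_id == "21366653"

    def test_unknown_drug_lists_known_names(self):
        with pytest.raises(mk.UnknownDrugError) as exc:
            mk.get_model("penicillin")
        msg = str(exc.value)
        for name in ("ceftriaxone", "ciprofloxacin", "meropenem", "vancomycin"):
            assert name in msg

    def test_catalogue_round_trip(self, tmp_path):
        path = tmp_path / "catalogue.yaml"
        mk.dump_catalogue(path)
        originals = {name: mk.get_model(name) for name in mk.list_models()}
        loaded = mk.load_catalogue(path)
        assert {m.drug_name for m in loaded} == set(originals)
        for m in loaded:
            assert m == originals[m.drug_name]

    def test_user_supplied_one_compartment_model(self):
        # a cefotaxime-like spec: albumin/SOFA/creatinine on CL
        spec = mk.PKModelSpec(
            drug_name="cefotaxime-test",
            n_compartments=1,
            typical_params={"CL": 8.0, "V1": 30.0},
            covariate_model={
                "CL": {"form": "linear_combination", "theta0": 10.0,
                       "coefficients": {"albumin_g_L": 0.05,
                                        "serum_creatinine_mg_dL": -1.0,
                                        "sofa": -0.2}},
            },
            iiv={"CL": 0.3},
            residual_error=mk.ResidualError(kind="additive", sigma_add_mg_L=1.0),
        )
        mk.register_model(spec, overwrite=True)
        c = mk.CovariateSet(weight_kg=70, serum_creatinine_mg_dL=1.0, age_years=40,
                            sex=mk.Sex.MALE, albumin_g_L=30.0, sofa=5)
        p = mk.compute_individual_parameters(mk.get_model("cefotaxime-test"), c)
        assert p.cl_L_h == pytest.approx(10.0 + 1.5 - 1.0 - 1.0)

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            mk.PKModelSpec(
                drug_name="bad", n_compartments=1,
                typical_params={"CL": 1.0, "V1": 10.0, "Q": 2.0, "V2": 5.0},
                covariate_model={}, iiv={},
                residual_error=mk.ResidualError(kind="additive", sigma_add_mg_L=1.0),
            )
        with pytest.raises(ValueError):
            mk.PKModelSpec(
                drug_name="bad", n_compartments=1,
                typical_params={"CL": -1.0, "V1": 10.0},
                covariate_model={}, iiv={},
                residual_error=mk.ResidualError(kind="additive", sigma_add_mg_L=1.0),
            )
        with pytest.raises(ValueError, match="IIV"):
            mk.PKModelSpec(
                drug_name="bad", n_compartments=1,
                typical_params={"CL": 1.0, "V1": 10.0},
                covariate_model={}, iiv={"Q": 0.2},
                residual_error=mk.ResidualError(kind="additive", sigma_add_mg_L=1.0),
            )
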