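"""Renal-function estimators: hand-evaluated golden values, flags, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carbopk as ck
from carbopk.renal import METHODS, MissingCovariateError, evaluate_methods

from conftest import random_patient


class TestBMI:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [(99.0, 170.0, 34.26), (72.25, 170.0, 25.00), (68.0, 180.0, 20.99)],
    )
    def test_hand_values(self, weight, height, expected):
        assert ck.compute_bmi(weight, height) == pytest.approx(expected, abs=0.005)

    def test_boundary_bmi_25_is_overweight_stratum(self):
        # the AIBW switch and the stratum lower bound are both inclusive at 25.0
        assert ck.Stratum.classify(ck.compute_bmi(72.25, 170.0)) is ck.Stratum.OVERWEIGHT

    @given(h=st.floats(120, 220))
    @settings(derandomize=True, max_examples=50)
    def test_algebraic_identity(self, h):
        w = h * h / 1e4 * 25.0
        assert ck.compute_bmi(w, h) == pytest.approx(25.0, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ck.compute_bmi(0.0, 170.0)


class TestWeightDescriptors:
    def test_devine_ibw_male_180(self):
        # 50 kg + 2.3 kg per inch over 60 in: 50 + 2.3*(180-152.4)/2.54
        assert ck.ibw("M", 180.0) == pytest.approx(74.992125984, rel=1e-9)

    def test_devine_ibw_female_165(self):
        assert ck.ibw("F", 165.0) == pytest.approx(45.5 + 2.3 * (165 - 152.4) / 2.54)

    def test_aibw_composition(self):
        w_ideal = ck.ibw("M", 180.0)
        assert ck.aibw("M", 180.0, 100.0) == pytest.approx(
            w_ideal + 0.4 * (100.0 - w_ideal), rel=1e-12)

    @given(h=st.floats(150, 200), w=st.floats(40, 140))
    @settings(derandomize=True, max_examples=50)
    def test_aibw_fixed_point_and_ordering(self, h, w):
        w_ideal = ck.ibw("F", h)
        assert ck.aibw("F", h, w_ideal) == pytest.approx(w_ideal, rel=1e-12)
        if w >= w_ideal:
            assert w_ideal <= ck.aibw("F", h, w) <= w


class TestCockcroftGault:
    def test_hand_value(self):
        assert ck.cockcroft_gault(72.0, 40, "M", 80.0) == pytest.approx(110.7)

    def test_sex_factor_ratio(self):
        m = ck.cockcroft_gault(70.0, 55, "M", 90.0)
        f = ck.cockcroft_gault(70.0, 55, "F", 90.0)
        assert f / m == pytest.approx(1.04 / 1.23, rel=1e-12)

    def test_scr_homogeneity(self):
        assert ck.cockcroft_gault(70.0, 55, "M", 160.0) == pytest.approx(
            ck.cockcroft_gault(70.0, 55, "M", 80.0) / 2.0, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ck.cockcroft_gault(70.0, 55, "M", 0.0)
        with pytest.raises(ValueError):
            ck.cockcroft_gault(70.0, 141, "M", 80.0)


class TestAdjustedCG:
    def test_cap_fires_at_139_54(self, constants, coeffs):
        # construct raw CrCL = 139.54 exactly (lean patient, no other flags)
        age, scr = 40, 80.0
        weight = 139.54 * scr / ((140 - age) * 1.23)
        p = ck.Patient(id="C", sex="M", age=age, weight_kg=weight,
                       height_cm=196.0, scr_umol_l=scr, target_auc=6.0)
        assert p.bmi < 25
        est = ck.adjusted_cg(p, constants, coeffs)
        assert est.raw_crcl == pytest.approx(139.54, rel=1e-12)
        assert est.crcl == 125.0
        assert est.crcl_capped and not est.scr_floored

    def test_scr_floor_fires_below_60(self, constants, coeffs):
        p = ck.Patient(id="F", sex="M", age=70, weight_kg=68.0, height_cm=180.0,
                       scr_umol_l=49.0, target_auc=6.0)
        est = ck.adjusted_cg(p, constants, coeffs)
        assert est.scr_floored
        assert est.raw_crcl == pytest.approx(
            ck.cockcroft_gault(68.0, 70, "M", 60.0), rel=1e-12)

    def test_identity_branch_matches_conventional_abw(self, constants, coeffs):
        p = ck.Patient(id="I", sex="F", age=65, weight_kg=60.0, height_cm=168.0,
                       scr_umol_l=80.0, target_auc=5.0)
        a = ck.adjusted_cg(p, constants, coeffs)
        c = ck.conventional_cg(p, "ABW", False, constants, coeffs)
        assert a.crcl == c.crcl
        assert not (a.scr_floored or a.crcl_capped)

    def test_aibw_used_at_bmi_threshold(self, constants, coeffs):
        p = ck.Patient(id="T", sex="M", age=60, weight_kg=72.25, height_cm=170.0,
                       scr_umol_l=80.0, target_auc=6.0)
        assert ck.adjusted_cg(p, constants, coeffs).weight_descriptor == "AIBW"

    def test_acg_equals_abw_cg_on_unflagged_patients(self, constants, coeffs):
        """Exact identity on 1000 random patients with BMI<25, Scr>=60 and
        raw CrCL <= 125 — the aCG adjustments are strictly conditional."""
        rng = np.random.default_rng(2024)
        n = 0
        while n < 1000:
            p = random_patient(rng)
            if p.bmi >= 25 or p.scr_umol_l < 60:
                continue
            a = ck.adjusted_cg(p, constants, coeffs)
            if a.raw_crcl > 125:
                continue
            c = ck.conventional_cg(p, "ABW", False, constants, coeffs)
            assert a.crcl == c.crcl
            assert a.weight_used == p.weight_kg
            n += 1


class TestConventionalCG:
    def test_capped_applies_cap_and_floor(self, constants, coeffs):
        age, scr = 40, 80.0
        weight = 139.54 * scr / ((140 - age) * 1.23)
        p = ck.Patient(id="C2", sex="M", age=age, weight_kg=weight,
                       height_cm=196.0, scr_umol_l=scr, target_auc=6.0)
        est = ck.conventional_cg(p, "ABW", True, constants, coeffs)
        assert est.crcl == 125.0 and est.crcl_capped

    def test_aibw_le_abw_when_overweight(self, constants, coeffs):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = random_patient(rng)
            if p.weight_kg < ck.ibw(p.sex, p.height_cm, coeffs):
                continue
            ai = ck.conventional_cg(p, "AIBW", False, constants, coeffs)
            ab = ck.conventional_cg(p, "ABW", False, constants, coeffs)
            assert ai.crcl <= ab.crcl


class TestBenezet:
    def test_golden_value(self, golden_patient, constants, coeffs):
        est = ck.benezet_crcl(golden_patient, constants, coeffs)
        # hand evaluation: IBW(F,165)=56.9094 < 85 kg, Chatelut at IBW
        assert est.clearance(constants) == pytest.approx(76.9357995805, rel=1e-9)
        assert est.weight_descriptor == "IBW"
        assert est.direct_clearance

    def test_degenerates_to_abw_for_lean_patient(self, constants, coeffs):
        p = ck.Patient(id="L", sex="M", age=60, weight_kg=55.0, height_cm=180.0,
                       scr_umol_l=80.0, target_auc=6.0)
        assert p.weight_kg <= ck.ibw("M", 180.0, coeffs)
        est = ck.benezet_crcl(p, constants, coeffs)
        assert est.weight_descriptor == "ABW"
        assert est.weight_used == p.weight_kg

    def test_decreasing_in_scr(self, golden_patient, constants, coeffs):
        from dataclasses import replace
        lo = ck.benezet_crcl(golden_patient, constants, coeffs)
        hi = ck.benezet_crcl(replace(golden_patient, scr_umol_l=120.0), constants, coeffs)
        assert hi.crcl < lo.crcl


class TestSchmitt:
    def test_reference_covariates_give_typical_clearance(self, reference_patient,
                                                         constants, coeffs):
        est = ck.schmitt_clearance(reference_patient, constants, coeffs)
        assert est.clearance(constants) == pytest.approx(110.0, rel=1e-12)

    def test_golden_value(self, golden_patient, constants, coeffs):
        est = ck.schmitt_clearance(golden_patient, constants, coeffs)
        assert est.clearance(constants) == pytest.approx(86.72896041598, rel=1e-9)

    def test_decreasing_in_cystatin(self, golden_patient, constants, coeffs):
        from dataclasses import replace
        lo = ck.schmitt_clearance(golden_patient, constants, coeffs)
        hi = ck.schmitt_clearance(replace(golden_patient, cysc_mg_l=1.8),
                                  constants, coeffs)
        assert hi.crcl < lo.crcl

    def test_missing_cystatin_excludes(self, constants, coeffs):
        p = ck.Patient(id="M", sex="M", age=60, weight_kg=70.0, height_cm=175.0,
                       scr_umol_l=80.0, target_auc=6.0)
        with pytest.raises(MissingCovariateError):
            ck.schmitt_clearance(p, constants, coeffs)


class TestCKDEPI:
    def test_spline_knot_identity(self, coeffs):
        # female with Scr exactly at the knot κ=0.7 mg/dL: both spline terms = 1
        p = ck.Patient(id="K", sex="F", age=40, weight_kg=60.0, height_cm=165.0,
                       scr_umol_l=0.7 * 88.4, target_auc=6.0)
        est = ck.ckdepi(p, "creatinine", deindex=False, coefficients=coeffs)
        assert est.crcl == pytest.approx(142 * 0.9938**40 * 1.012, rel=1e-12)

    def test_golden_values_deindexed(self, golden_patient, coeffs):
        cr = ck.ckdepi(golden_patient, "creatinine", coefficients=coeffs)
        both = ck.ckdepi(golden_patient, "creatinine_cystatin", coefficients=coeffs)
        assert cr.crcl == pytest.approx(71.2010944344, rel=1e-9)
        assert both.crcl == pytest.approx(64.1951679351, rel=1e-9)

    def test_neutral_bsa_makes_deindex_a_noop(self, coeffs):
        height = 170.0
        c = coeffs["dubois_bsa"]
        weight = (1.73 / (c["coefficient"] * height ** c["height_exponent"])) ** (
            1.0 / c["weight_exponent"])
        p = ck.Patient(id="N", sex="F", age=50, weight_kg=weight, height_cm=height,
                       scr_umol_l=90.0, target_auc=6.0)
        on = ck.ckdepi(p, "creatinine", deindex=True, coefficients=coeffs)
        off = ck.ckdepi(p, "creatinine", deindex=False, coefficients=coeffs)
        assert on.crcl == pytest.approx(off.crcl, rel=1e-12)

    def test_combined_variant_requires_cystatin(self, coeffs):
        p = ck.Patient(id="M2", sex="M", age=60, weight_kg=70.0, height_cm=175.0,
                       scr_umol_l=80.0, target_auc=6.0)
        with pytest.raises(MissingCovariateError):
            ck.ckdepi(p, "creatinine_cystatin", coefficients=coeffs)


class TestCrCL24h:
    def test_hand_value(self):
        assert ck.crcl_24h(9.8, 69.0) == pytest.approx(98.63, abs=0.01)

    def test_ratio_homogeneity(self):
        assert ck.crcl_24h(19.6, 138.0) == pytest.approx(ck.crcl_24h(9.8, 69.0),
                                                         rel=1e-12)

    def test_algebraic_construction(self):
        # excretion chosen so the clearance is exactly 100 mL/min
        scr = 80.0
        ucr = 100.0 * scr * 1440.0 / 1e6
        assert ck.crcl_24h(ucr, scr) == pytest.approx(100.0, rel=1e-12)


class TestBSA:
    def test_dubois_hand_value(self):
        assert ck.bsa_dubois(72.0, 180.0) == pytest.approx(1.909, abs=0.002)

    def test_monotone(self):
        assert ck.bsa_dubois(80.0, 180.0) > ck.bsa_dubois(72.0, 180.0)
        assert ck.bsa_dubois(72.0, 190.0) > ck.bsa_dubois(72.0, 180.0)


class TestRegistry:
    def test_complete_patient_yields_all_ten_methods(self, constants, coeffs):
        from dataclasses import replace
        p = ck.Patient(id="G1", sex="F", age=62, weight_kg=85.0, height_cm=165.0,
                       scr_umol_l=88.0, cysc_mg_l=1.3, ucr_mmol_24h=10.0,
                       target_auc=5.0)
        estimates, exclusions = evaluate_methods(p, constants=constants,
                                                 coefficients=coeffs)
        assert not exclusions
        assert set(estimates) == {
            "aCG", "CG_ABW", "CG_ABW_capped", "CG_AIBW", "benezet",
            "crcl_24h", "schmitt", "ckdepi_cr", "ckdepi_cr_cys", "flat",
        }

    def test_exclusions_are_per_method(self, constants, coeffs):
        p = ck.Patient(id="X", sex="F", age=60, weight_kg=70.0, height_cm=165.0,
                       scr_umol_l=80.0, target_auc=6.0)  # no cysC, no urine
        estimates, exclusions = evaluate_methods(p, constants=constants,
                                                 coefficients=coeffs)
        assert set(exclusions) == {"schmitt", "ckdepi_cr_cys", "crcl_24h"}
        assert len(estimates) == len(METHODS) - 3

    def test_cap_dominance(self, constants, coeffs):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = random_patient(rng)
            for name in ("aCG", "CG_ABW_capped"):
                est = METHODS[name](p, constants, coeffs)
                assert est.crcl <= constants.crcl_cap

    def test_flat_reconstructs_population_clearance(self, golden_patient,
                                                    constants, coeffs):
        est = METHODS["flat"](golden_patient, constants, coeffs)
        assert est.clearance(constants) == pytest.approx(112.4, rel=1e-12)


def test_coefficient_loading_fails_loudly(tmp_path):
    bad = tmp_path / "c.toml"
    bad.write_text("[cockcroft_gault]\nf_male = 1.23\n")
    with pytest.raises(ValueError):
        ck.load_coefficients(bad)
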