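import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import euplokit as ek
from euplokit.calculator import effect_codes
from euplokit.errors import CoefficientError, DomainError, ProfileError

from .conftest import brute_force_mii


class TestLinearPredictor:
    def test_reference_profile_ejaculate_androfert(self, coefs):
        profile = ek.PatientProfile(39.414, ek.SpermSource.EJACULATE, ek.Center.ANDROFERT)
        y = ek.linear_predictor(profile, coefs)
        assert y == pytest.approx(-2.728414 + 0.4928267 - 0.0807783, abs=1e-12)

    def test_reference_profile_noa_androfert(self, coefs):
        profile = ek.PatientProfile(39.414, ek.SpermSource.TESTICULAR_NOA, ek.Center.ANDROFERT)
        y = ek.linear_predictor(profile, coefs)
        assert y == pytest.approx(-2.728414 - 0.4928267 - 0.0807783, abs=1e-12)

    @pytest.mark.parametrize("sperm", list(ek.SpermSource))
    @pytest.mark.parametrize("center", list(ek.Center))
    def test_age_interaction_vanishes_at_centering_age(self, coefs, sperm, center):
        at_center = ek.PatientProfile(coefs.age_center, sperm, center)
        # remove the age terms by hand and compare
        d1, d2, e1, e2 = effect_codes(sperm, center)
        expected = (
            coefs.intercept
            + coefs.s_ej_noa * d1
            + coefs.g_anat_andro * e1
            + coefs.g_gen_anat * e2
        )
        assert ek.linear_predictor(at_center, coefs) == pytest.approx(expected, abs=1e-12)

    def test_unspecified_center_contributes_nothing(self, coefs):
        base = ek.PatientProfile(35.0, ek.SpermSource.EJACULATE, ek.Center.UNSPECIFIED)
        y = ek.linear_predictor(base, coefs)
        stripped = ek.CoefficientSet(
            intercept=coefs.intercept,
            age_center=coefs.age_center,
            b_ej_noa_age=coefs.b_ej_noa_age,
            b_surg_noa_age=coefs.b_surg_noa_age,
            s_ej_noa=coefs.s_ej_noa,
        )
        assert y == ek.linear_predictor(base, stripped)

    def test_full_grid_matches_independent_evaluator(self, coefs):
        # independent hand-coded evaluation of the contrast equation
        def oracle(age, sperm, center):
            i_ej = 1.0 if sperm == "ej" else 0.0
            i_surg = 1.0 if sperm == "surg" else 0.0
            i_noa = 1.0 if sperm == "noa" else 0.0
            i_anat = 1.0 if center == "anat" else 0.0
            i_andro = 1.0 if center == "andro" else 0.0
            i_gen = 1.0 if center == "gen" else 0.0
            y = (
                -2.728414
                + (-0.138868) * (i_ej - i_noa) * (age - 39.414)
                + (-0.13032) * (i_surg - i_noa) * (age - 39.414)
                + 0.4928267 * (i_ej - i_noa)
                + 0.0807783 * (i_anat - i_andro)
                + 0.3765617 * (i_gen - i_anat)
            )
            return 1.0 / (1.0 + math.exp(-y))

        sperm_map = {
            "ej": ek.SpermSource.EJACULATE,
            "surg": ek.SpermSource.SURGICAL_NON_NOA,
            "noa": ek.SpermSource.TESTICULAR_NOA,
        }
        center_map = {
            "anat": ek.Center.ANATOLIA,
            "andro": ek.Center.ANDROFERT,
            "gen": ek.Center.GENERA,
        }
        for age in range(25, 46):
            for s_key, sperm in sperm_map.items():
                for c_key, center in center_map.items():
                    profile = ek.PatientProfile(float(age), sperm, center)
                    p = ek.euploidy_probability(ek.linear_predictor(profile, coefs))
                    assert p == pytest.approx(oracle(age, s_key, c_key), abs=1e-12)

    @pytest.mark.parametrize("age", [17.9, 50.1, -3.0, float("nan")])
    def test_age_out_of_range_rejected(self, age):
        with pytest.raises(ProfileError):
            ek.PatientProfile(age)


class TestEuploidyProbability:
    def test_logit_symmetry(self):
        assert ek.euploidy_probability(0.0) == 0.5

    def test_reference_value(self):
        assert ek.euploidy_probability(-2.3163656) == pytest.approx(0.0898, abs=5e-5)

    def test_saturation(self):
        assert ek.euploidy_probability(-20.0) < 1e-8
        assert ek.euploidy_probability(20.0) > 1 - 1e-8

    def test_strictly_increasing(self):
        ys = np.linspace(-10, 10, 201)
        ps = [ek.euploidy_probability(y) for y in ys]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            ek.euploidy_probability(float("inf"))


class TestMiiMin:
    def test_one_fair_trial(self):
        assert ek.mii_min(0.5, 0.5).mii_min == 1

    @pytest.mark.parametrize("pi,expected", [(0.7, 5), (0.8, 7), (0.9, 10)])
    def test_published_triple_at_p022(self, pi, expected):
        # confirm with the independent iteration oracle first
        assert brute_force_mii(0.22, pi) == expected
        assert ek.mii_min(0.22, pi).mii_min == expected

    def test_low_probability_case(self):
        assert brute_force_mii(0.0898, 0.7) == 13
        assert ek.mii_min(0.0898, 0.7).mii_min == 13

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_p_rejected(self, p):
        with pytest.raises(DomainError):
            ek.mii_min(p, 0.7)

    @pytest.mark.parametrize("pi", [0.0, 1.0, -0.2, 2.0])
    def test_degenerate_pi_rejected(self, pi):
        with pytest.raises(DomainError):
            ek.mii_min(0.2, pi)

    def test_unreachable_target_reported(self):
        with pytest.raises(DomainError, match="unreachable"):
            ek.mii_min(1e-12, 0.999999)

    def test_grid_equals_brute_force(self):
        for p in np.arange(0.01, 1.0, 0.02):
            for pi in np.arange(0.05, 0.96, 0.05):
                est = ek.mii_min(float(p), float(pi))
                assert est.mii_min == brute_force_mii(float(p), float(pi)), (p, pi)
                assert est.achieved_success >= pi * (1 - 1e-9)
                if est.mii_min > 0:
                    assert 1 - (1 - p) ** (est.mii_min - 1) < pi

    def test_monotone_in_p_and_pi(self):
        pis = np.arange(0.05, 0.96, 0.05)
        ps = np.arange(0.01, 1.0, 0.02)
        for pi in pis:
            counts = [ek.mii_min(float(p), float(pi)).mii_min for p in ps]
            assert all(b <= a for a, b in zip(counts, counts[1:]))
        for p in ps:
            counts = [ek.mii_min(float(p), float(pi)).mii_min for pi in pis]
            assert all(b >= a for a, b in zip(counts, counts[1:]))

    @given(
        p=st.floats(min_value=0.001, max_value=0.999),
        pi=st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(max_examples=300, deadline=None)
    def test_postconditions_hold_everywhere(self, p, pi):
        est = ek.mii_min(p, pi)
        assert est.achieved_success >= pi * (1 - 1e-9)
        assert est.risk == pytest.approx(1 - pi)
        if est.mii_min > 0:
            below = -math.expm1((est.mii_min - 1) * math.log1p(-p))
            assert below < pi * (1 + 1e-9)


class TestPredict:
    def test_mii_min_nondecreasing_in_pi(self, coefs):
        profile = ek.PatientProfile(38.0, ek.SpermSource.EJACULATE, ek.Center.GENERA)
        low = ek.predict(profile, 0.5, coefs)
        high = ek.predict(profile, 0.9, coefs)
        assert high.mii_min >= low.mii_min

    def test_age_gradient_for_ejaculate(self, coefs):
        p35 = ek.predict(ek.PatientProfile(35.0), 0.7, coefs).p
        p43 = ek.predict(ek.PatientProfile(43.0), 0.7, coefs).p
        assert p35 > p43

    def test_composition_identity(self, coefs):
        profile = ek.PatientProfile(41.0, ek.SpermSource.SURGICAL_NON_NOA, ek.Center.ANATOLIA)
        direct = ek.predict(profile, 0.8, coefs)
        manual = ek.mii_min(
            ek.euploidy_probability(ek.linear_predictor(profile, coefs)), 0.8
        )
        assert direct == manual

    def test_age_monotonicity_follows_contrast_signs(self, coefs):
        # ejaculate: slope is b_ej_noa_age * d1 = negative -> p decreasing
        ages = np.linspace(25, 45, 21)
        p_ej = [ek.predict(ek.PatientProfile(a), 0.7, coefs).p for a in ages]
        assert all(b < a for a, b in zip(p_ej, p_ej[1:]))
        # testicular NOA: slope is -b_ej_noa_age = positive -> p increasing
        p_noa = [
            ek.euploidy_probability(
                ek.linear_predictor(
                    ek.PatientProfile(a, ek.SpermSource.TESTICULAR_NOA), coefs
                )
            )
            for a in ages
        ]
        assert all(b > a for a, b in zip(p_noa, p_noa[1:]))

    def test_genera_above_anatolia(self, coefs):
        assert coefs.g_gen_anat > 0
        for age in (30.0, 38.0, 44.0):
            p_gen = ek.euploidy_probability(
                ek.linear_predictor(ek.PatientProfile(age, center=ek.Center.GENERA), coefs)
            )
            p_anat = ek.euploidy_probability(
                ek.linear_predictor(ek.PatientProfile(age, center=ek.Center.ANATOLIA), coefs)
            )
            assert p_gen > p_anat


class TestCoefficientSet:
    def test_default_matches_packaged_file(self, coefs):
        assert coefs.intercept == -2.728414
        assert coefs.age_center == 39.414
        assert coefs.b_ej_noa_age == -0.138868
        assert coefs.b_surg_noa_age == -0.13032
        assert coefs.s_ej_noa == 0.4928267
        assert coefs.g_anat_andro == 0.0807783
        assert coefs.g_gen_anat == 0.3765617

    def test_json_round_trip(self, coefs, tmp_path):
        path = tmp_path / "coefs.json"
        coefs.to_json(str(path))
        again = ek.CoefficientSet.from_json(str(path))
        assert again == coefs

    def test_center_free_set_is_valid(self):
        cs = ek.CoefficientSet(
            intercept=-2.0, age_center=39.0, b_ej_noa_age=-0.1,
            b_surg_noa_age=-0.1, s_ej_noa=0.5,
        )
        assert cs.center_free

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(CoefficientError):
            ek.CoefficientSet(
                intercept=float("nan"), age_center=39.0, b_ej_noa_age=0.0,
                b_surg_noa_age=0.0, s_ej_noa=0.0,
            )

    def test_age_center_bounds(self):
        with pytest.raises(CoefficientError):
            ek.CoefficientSet(
                intercept=0.0, age_center=55.0, b_ej_noa_age=0.0,
                b_surg_noa_age=0.0, s_ej_noa=0.0,
            )

    def test_missing_required_field_rejected(self):
        with pytest.raises(CoefficientError):
            ek.CoefficientSet.from_dict({"intercept": -2.0})


class TestProbabilityInterval:
    def test_contains_point_estimate(self, coefs):
        profile = ek.PatientProfile(36.0, ek.SpermSource.EJACULATE, ek.Center.GENERA)
        lo, hi = ek.probability_interval(profile, coefs)
        p = ek.euploidy_probability(ek.linear_predictor(profile, coefs))
        assert lo < p < hi

    def test_requires_standard_errors(self):
        bare = ek.CoefficientSet(
            intercept=-2.0, age_center=39.0, b_ej_noa_age=-0.1,
            b_surg_noa_age=-0.1, s_ej_noa=0.5,
        )
        with pytest.raises(CoefficientError):
            ek.probability_interval(ek.PatientProfile(35.0), bare)

    def test_wider_at_higher_level(self, coefs):
        profile = ek.PatientProfile(36.0)
        lo90, hi90 = ek.probability_interval(profile, coefs, level=0.90)
        lo99, hi99 = ek.probability_interval(profile, coefs, level=0.99)
        assert lo99 < lo90 and hi99 > hi90
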