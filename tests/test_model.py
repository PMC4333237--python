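"""Covariate models, allometry, induction multiplier and ratio algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmopk import (
    InvalidInputError,
    PopulationParameters,
    SubjectCovariates,
    allometric_typical_values,
    compute_ffm,
    compute_nfm,
    enzyme_production_multiplier,
    enzyme_time_to_steady_state_days,
    equilibration_half_life_minutes,
    unbound_ratio,
)
from pulmopk.errors import ConfigurationError
from pulmopk.model import size_descriptors


class TestFatFreeMass:
    def test_reference_male(self):
        # frozen value: direct evaluation of the sigmoid body-composition
        # formula with the male constants (42.92, 30.93) at 70 kg / 1.75 m
        assert compute_ffm("male", 70.0, 1.75) == pytest.approx(55.86, abs=0.005)

    def test_female_below_male_at_same_size(self):
        assert compute_ffm("female", 70.0, 1.75) < compute_ffm("male", 70.0, 1.75)

    def test_saturates_at_maximal_weight_height_squared(self):
        # at fixed height, infinite weight approaches WHS_max * HT^2 from below
        ht = 1.75
        cap = 42.92 * ht ** 2
        heavy = compute_ffm("male", 1e7, ht)
        heavier = compute_ffm("male", 1e9, ht)
        assert heavy < heavier < cap
        assert heavier == pytest.approx(cap, rel=1e-6)

    @pytest.mark.parametrize("weight,height", [(-1, 1.7), (0, 1.7), (70, 0), (70, -2)])
    def test_nonpositive_inputs_rejected(self, weight, height):
        with pytest.raises(InvalidInputError):
            compute_ffm("male", weight, height)

    @given(sex=st.sampled_from(["male", "female"]),
           height=st.floats(1.40, 2.05),
           bmi=st.floats(16.0, 45.0))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_bodyweight(self, sex, height, bmi):
        weight = bmi * height ** 2
        ffm = compute_ffm(sex, weight, height)
        assert 0.0 < ffm < weight


class TestNormalFatMass:
    @pytest.mark.parametrize("ffat,expected", [(0.0, 55.0), (1.0, 70.0), (0.5, 62.5)])
    def test_interpolates_between_ffm_and_weight(self, ffat, expected):
        assert compute_nfm(55.0, 70.0, ffat) == expected

    def test_ffm_above_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_nfm(80.0, 70.0, 0.5)

    def test_size_descriptors_ordering(self, ref_params):
        cov = SubjectCovariates(1, "female", 82.0, 1.60)
        d = size_descriptors(cov, ref_params.replace(ffat_cl=0.3, ffat_v=0.9))
        assert 0 < d.ffm <= d.bodyweight
        assert d.ffm <= d.nfm_cl <= d.bodyweight
        assert d.ffm <= d.nfm_v <= d.bodyweight


class TestAllometry:
    def test_identity_at_standard_mass(self, ref_params):
        # a subject whose FFM equals 70 kg gets the standardised values
        cov = SubjectCovariates(1, "male", 88.33, 1.95)
        ffm = compute_ffm("male", cov.weight, cov.height)
        assert ffm == pytest.approx(70.0, abs=0.15)
        cl, vc = allometric_typical_values(ref_params, cov)
        assert cl == pytest.approx(ref_params.cl_std, rel=2e-3)
        assert vc == pytest.approx(ref_params.vc_std, rel=2e-3)

    def test_no_scaling_returns_standard_values(self, ref_params):
        p = ref_params.replace(scaling_mode="none")
        cov = SubjectCovariates(1, "female", 50.0, 1.50)
        assert allometric_typical_values(p, cov) == (p.cl_std, p.vc_std)

    def test_half_mass_power_laws(self, ref_params):
        p = ref_params.replace(scaling_mode="bodyweight")
        cov = SubjectCovariates(1, "male", 35.0, 1.75)
        cl, vc = allometric_typical_values(p, cov)
        assert cl == pytest.approx(p.cl_std * 0.5 ** 0.75, rel=1e-12)
        assert vc == pytest.approx(p.vc_std * 0.5, rel=1e-12)

    def test_published_standard_clearance(self, ref_params):
        assert ref_params.cl_std == 3.85  # L/h at 70 kg, pre-induced

    def test_modes_agree_at_70kg_descriptor(self, ref_params):
        # bodyweight mode at WT=70 equals none; ffm mode at FFM=70 likewise
        cov_bw = SubjectCovariates(1, "male", 70.0, 1.75)
        cl_bw, vc_bw = allometric_typical_values(
            ref_params.replace(scaling_mode="bodyweight"), cov_bw)
        assert (cl_bw, vc_bw) == (ref_params.cl_std, ref_params.vc_std)

    def test_unknown_mode_rejected(self, ref_params):
        with pytest.raises(ConfigurationError):
            ref_params.replace(scaling_mode="bsa")


class TestInductionMultiplier:
    def test_no_drug_no_induction(self):
        assert enzyme_production_multiplier(0.0, 1.04, 0.0705) == 1.0

    def test_half_maximal_at_ec50(self):
        assert enzyme_production_multiplier(0.0705, 1.04, 0.0705) \
            == pytest.approx(1.0 + 1.04 / 2)

    def test_asymptote_one_plus_emax(self):
        # frozen limit: cp -> inf gives 1 + Emax = 2.04 with the published Emax
        assert enzyme_production_multiplier(1e12, 1.04, 0.0705) \
            == pytest.approx(2.04, rel=1e-9)

    @given(st.floats(0.0, 100.0), st.floats(0.001, 99.0))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing_and_bounded(self, cp, dcp):
        lo = enzyme_production_multiplier(cp, 1.04, 0.0705)
        hi = enzyme_production_multiplier(cp + dcp, 1.04, 0.0705)
        assert lo < hi < 1.0 + 1.04


class TestUnboundRatio:
    def test_published_ac_ratio(self):
        # 1.1 / 0.2 = 5.5, the post-estimation derivation of the unbound ratio
        assert unbound_ratio(1.1, 0.2) == pytest.approx(5.5)

    def test_formula_value_for_elf(self):
        # 0.26 / 0.2 is exactly 1.30 by the formula (the reference analysis
        # prints 1.28 from its unrounded estimate)
        assert unbound_ratio(0.26, 0.2) == pytest.approx(1.30)

    def test_fully_unbound_identity(self):
        assert unbound_ratio(0.7, 1.0) == 0.7

    @pytest.mark.parametrize("fu", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fu):
        with pytest.raises(InvalidInputError):
            unbound_ratio(1.0, fu)


class TestFixedRateConstants:
    def test_effect_compartment_halflife_about_one_minute(self):
        assert equilibration_half_life_minutes(41.58) == pytest.approx(1.0, abs=0.01)

    def test_enzyme_steady_state_about_forty_days(self):
        assert enzyme_time_to_steady_state_days(0.0036) == pytest.approx(40.0, abs=0.5)


class TestParameterValidation:
    def test_ka_is_required(self):
        with pytest.raises(TypeError):
            PopulationParameters()  # no silent default for ka

    @pytest.mark.parametrize("field,value", [
        ("cl_std", -1.0), ("vc_std", 0.0), ("ec50", 0.0), ("fu_plasma", 0.0),
        ("fu_plasma", 1.2), ("n_transit", -1), ("sigma_plasma", -0.1),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(InvalidInputError):
            PopulationParameters(ka=2.0, **{field: value})

    def test_fixed_mask_reflects_estimated_set(self, ref_params):
        mask = ref_params.fixed_mask
        assert not mask["cl_std"] and not mask["omega_cl"]
        assert mask["mtt"] and mask["k_elf"] and mask["ka"]

    def test_iiv_conventions(self, ref_params):
        assert ref_params.iiv_percent("sd") == pytest.approx(88.8)
        assert ref_params.iiv_percent("cv") == pytest.approx(
            100 * np.sqrt(np.expm1(0.888 ** 2)))
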