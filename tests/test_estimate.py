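"""Likelihood machinery: joint/marginal -2LL, the quadrature oracle, the
likelihood-ratio test, standard errors and small self-consistency fits."""

import numpy as np
import pandas as pd
import pytest

from pulmopk import (
    ConfigurationError,
    InvalidInputError,
    fit,
    individual_laplace_neg2ll,
    individual_neg2ll,
    lrt,
    lrt_threshold,
    marginal_neg2ll_quadrature,
    pack_dataset,
    predict_observations,
)
from pulmopk.design import CovariateModel, StudyDesignSpec, generate_study
from pulmopk.estimate import compare_scaling, foce_objective, numeric_hessian
from pulmopk.recovery import neutral_start, recovery_design


def _one_subject_table(times_matrices, dvs, dose_times=(0.0,), dose=600.0):
    rows = [dict(id=1, time=t, evid=1, amt=dose, dv=np.nan, matrix=np.nan,
                 mdv=1, sex="male", weight=70.0, height=1.75)
            for t in dose_times]
    rows += [dict(id=1, time=t, evid=0, amt=np.nan, dv=dv, matrix=m,
                  mdv=0, sex="male", weight=70.0, height=1.75)
             for (t, m), dv in zip(times_matrices, dvs)]
    return pd.DataFrame(rows).sort_values(["time", "evid"], ignore_index=True)


@pytest.fixture(scope="module")
def toy_params(ref_params):
    # standard-subject scaling so predictions have a closed relation to
    # the standardised parameters
    return ref_params.replace(scaling_mode="none")


class TestJointNeg2LL:
    def test_matches_formula_written_out_in_numpy(self, toy_params):
        table = _one_subject_table([(2.0, "plasma"), (6.0, "elf")], [4.0, 1.1])
        packed = pack_dataset(table)
        eta = 0.3
        f = predict_observations(packed, toy_params, np.array([eta]))
        sig = np.array([toy_params.sigma_plasma, toy_params.sigma_elf])
        v = f ** 2 * sig ** 2
        y = packed.obs_y
        expected = (np.log(2 * np.pi * v) + (y - f) ** 2 / v).sum() \
            + eta ** 2 / toy_params.omega_cl ** 2 \
            + np.log(2 * np.pi * toy_params.omega_cl ** 2)
        assert individual_neg2ll(packed, toy_params, eta) \
            == pytest.approx(expected, rel=1e-10)

    def test_doubling_sigma_shifts_by_analytic_amount(self, toy_params):
        # v -> 4v: each term changes by log(4) - 0.75 (y-f)^2/v
        table = _one_subject_table([(2.0, "plasma"), (4.0, "plasma")], [5.0, 4.0])
        packed = pack_dataset(table)
        f = predict_observations(packed, toy_params, np.array([0.1]))
        v = f ** 2 * toy_params.sigma_plasma ** 2
        resid = (packed.obs_y - f) ** 2
        expected_shift = (2 * np.log(4.0) - 0.75 * (resid / v).sum())
        wide = toy_params.replace(sigma_plasma=2 * toy_params.sigma_plasma)
        shift = individual_neg2ll(packed, wide, 0.1) \
            - individual_neg2ll(packed, toy_params, 0.1)
        assert shift == pytest.approx(expected_shift, rel=1e-9)

    def test_exact_fit_leaves_only_normalising_terms(self, toy_params):
        # y == f and eta == 0: only the log(2 pi v) and prior constants stay
        table = _one_subject_table([(4.0, "plasma")], [1.0])
        packed = pack_dataset(table)
        f = predict_observations(packed, toy_params, np.zeros(1))
        packed.obs_y[:] = f
        v = f[0] ** 2 * toy_params.sigma_plasma ** 2
        expected = np.log(2 * np.pi * v) \
            + np.log(2 * np.pi * toy_params.omega_cl ** 2)
        assert individual_neg2ll(packed, toy_params, 0.0) \
            == pytest.approx(expected, rel=1e-10)


def _model_consistent_toy(params, times_matrices, multipliers):
    """One-subject data built from the model's own typical predictions,
    perturbed by fixed multiplicative residuals — the well-behaved regime
    the Laplace approximation is meant for."""
    probe = _one_subject_table(times_matrices, [1.0] * len(times_matrices))
    f = predict_observations(pack_dataset(probe), params)
    return _one_subject_table(times_matrices, list(f * np.asarray(multipliers)))


class TestLaplaceAgainstQuadrature:
    def test_two_observation_toy_within_tenth_of_a_point(self, toy_params):
        # typical data (conditional mode near zero, sharp curvature)
        table = _model_consistent_toy(
            toy_params, [(2.0, "plasma"), (6.0, "plasma")], [1.0, 1.0])
        lap = individual_laplace_neg2ll(table, toy_params)
        quad = marginal_neg2ll_quadrature(table, toy_params)
        assert lap == pytest.approx(quad, abs=0.1)

    @pytest.mark.parametrize("tm,mult", [
        ([(2.0, "plasma"), (6.0, "plasma")], [1.2, 0.85]),
        ([(2.0, "plasma"), (4.0, "plasma"), (4.0, "elf"), (4.0, "ac")],
         [1.1, 0.9, 1.15, 0.8]),
        ([(1.0, "plasma"), (8.0, "ac")], [0.9, 1.25]),
        ([(4.0, "elf")], [1.05]),
    ])
    def test_small_instances_within_half_point(self, toy_params, tm, mult):
        table = _model_consistent_toy(toy_params, tm, mult)
        lap = individual_laplace_neg2ll(table, toy_params)
        quad = marginal_neg2ll_quadrature(table, toy_params)
        assert lap == pytest.approx(quad, abs=0.5)

    def test_tight_prior_closes_the_gap(self, toy_params):
        # with an informative prior the posterior is near-Gaussian and the
        # approximation error collapses by an order of magnitude
        table = _model_consistent_toy(
            toy_params, [(2.0, "plasma"), (6.0, "plasma")], [1.3, 0.75])
        p = toy_params.replace(omega_cl=0.2)
        lap = individual_laplace_neg2ll(table, p)
        quad = marginal_neg2ll_quadrature(table, p)
        assert lap == pytest.approx(quad, abs=0.01)


class TestLikelihoodRatioTest:
    def test_threshold_is_3_84_for_one_parameter(self):
        assert round(lrt_threshold(1), 2) == 3.84

    @pytest.mark.parametrize("ofv_reduced,significant", [(103.9, True),
                                                         (103.8, False)])
    def test_one_parameter_decision(self, ofv_reduced, significant):
        delta, sig = lrt(100.0, ofv_reduced, 1)
        assert delta == pytest.approx(ofv_reduced - 100.0)
        assert sig is significant

    def test_degrees_of_freedom_validated(self):
        with pytest.raises(InvalidInputError):
            lrt(100.0, 104.0, 0)


class TestNumericCurvature:
    def test_hessian_of_quadratic_is_exact(self):
        h_true = np.array([[4.0, 1.0], [1.0, 3.0]])

        def f(x):
            return 0.5 * x @ h_true @ x + 2.0

        h = numeric_hessian(f, np.array([0.3, -0.2]))
        np.testing.assert_allclose(h, h_true, rtol=1e-5)

    def test_rse_arithmetic(self):
        # SE 0.0112 on an estimate of 0.26 is a 4.3 % relative standard error
        assert 100 * 0.0112 / 0.26 == pytest.approx(4.3, abs=0.05)


@pytest.fixture(scope="module")
def noise_free_fit(ref_params):
    """Self-consistency: refit a noise-free study from perturbed starts."""
    spec = StudyDesignSpec(
        n_subjects=6, groups=(("male", "", 3), ("female", "", 3)),
        plasma_times=(2.0, 4.0), bal_times=(1.0, 4.0, 8.0),
        time_jitter=0.0, target_counts=None,
        covariates={"male": CovariateModel(75.0, 6.0, 1.75, 0.05),
                    "female": CovariateModel(62.0, 6.0, 1.62, 0.05)},
        seed=5,
    )
    truth = ref_params.replace(omega_cl=0.0, sigma_plasma=0.0,
                               sigma_elf=0.0, sigma_ac=0.0)
    table, _ = generate_study(spec, truth)
    # sigma fixed small: the ML optimum under a proportional error model
    # sits O(sigma^2) away from the perfect-fit point (the 2*sum(log f)
    # variance term rewards smaller predictions), so the noise-free limit
    # needs a small residual SD for sub-0.1 % recovery
    start = ref_params.replace(
        cl_std=5.5, vc_std=55.0, r_elf_plasma=0.5, r_ac_plasma=0.6,
        omega_cl=1e-3, sigma_plasma=0.01, sigma_elf=0.01, sigma_ac=0.01)
    free = ("cl_std", "vc_std", "r_elf_plasma", "r_ac_plasma")
    # fine kernel step and tight outer tolerances: this test checks the
    # estimator's exactness in the noise-free limit, so the integration
    # mismatch against the generating solver must sit well below 0.1 %
    result = fit(table, start, free=free, h_max=0.01,
                 optimizer_options={"ftol": 1e-12, "gtol": 1e-6})
    return table, start, free, result


class TestFit:
    def test_noise_free_recovery_to_a_tenth_percent(self, ref_params,
                                                    noise_free_fit):
        _, _, free, result = noise_free_fit
        for name in free:
            assert getattr(result.estimates, name) \
                == pytest.approx(getattr(ref_params, name), rel=1e-3), name

    def test_fit_never_worse_than_start(self, noise_free_fit):
        table, start, free, result = noise_free_fit
        packed = pack_dataset(table)
        ofv_start, _, _ = foce_objective(start, packed)
        assert result.ofv <= ofv_start

    def test_fixed_parameters_get_no_standard_error(self, noise_free_fit):
        _, _, free, result = noise_free_fit
        assert result.se is not None
        assert set(result.se) == set(free)
        assert "mtt" not in result.se and "k_elf" not in result.se

    def test_empirical_bayes_etas_near_zero_without_noise(self, noise_free_fit):
        _, _, _, result = noise_free_fit
        assert max(abs(e) for e in result.etas.values()) < 1e-3

    def test_subject_order_does_not_change_ofv(self, ref_params):
        table, _ = generate_study(recovery_design(5, seed=31), ref_params)
        packed = pack_dataset(table)
        shuffled = pd.concat(
            [sub for _, sub in sorted(table.groupby("id"),
                                      key=lambda kv: -kv[0])],
            ignore_index=True)
        packed_shuffled = pack_dataset(shuffled)
        o1, _, _ = foce_objective(ref_params, packed)
        o2, _, _ = foce_objective(ref_params, packed_shuffled)
        assert o1 == pytest.approx(o2, abs=1e-8)

    def test_freeing_distribution_rate_refused_on_single_bal_design(
            self, ref_params):
        table, _ = generate_study(StudyDesignSpec(seed=2), ref_params)
        start = neutral_start()
        with pytest.raises(ConfigurationError, match="k_elf"):
            fit(table, start, free=start.estimated + ("k_elf",))

    def test_unknown_parameter_refused(self, ref_params):
        table, _ = generate_study(recovery_design(4, seed=1), ref_params)
        with pytest.raises(ConfigurationError):
            fit(table, neutral_start(), free=("n_transit",))


class TestCompareScaling:
    def test_ranking_and_selection_rule(self, ref_params):
        table, _ = generate_study(recovery_design(8, seed=13), ref_params)
        start = neutral_start()
        ranking, selected, results = compare_scaling(
            table, start, compute_se=False,
            optimizer_options={"maxfun": 400})
        assert set(ranking["scaling_mode"]) == {"none", "bodyweight", "ffm", "nfm"}
        assert (ranking["ofv"].diff().dropna() >= 0).all()  # sorted by OFV
        # the nfm fit frees two extra fat-mass fractions
        n_free = dict(zip(ranking["scaling_mode"], ranking["n_free"]))
        assert n_free["nfm"] == n_free["ffm"] + 2
        # selection: fewest parameters among models within 3.84 of the best
        cands = ranking[ranking["ofv"] <= ranking["ofv"].min() + 3.84]
        expected = cands.sort_values(["n_free", "ofv"]).iloc[0]["scaling_mode"]
        assert selected == expected
        assert ranking.loc[ranking["scaling_mode"] == selected,
                           "selected"].all()
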