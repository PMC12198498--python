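"""Penalized likelihood, samples mode and the multi-start fit."""

import numpy as np
import pytest

import diffgek as dg
from diffgek import (
    MODELS,
    SINGLE_CONDITION,
    ParamVector,
    fit_gene,
    penalized_loglik,
    penalized_loglik_samples,
)
from diffgek.fitting import _wobbliness

from conftest import make_flat_course

LOG2PI = np.log(2 * np.pi)


def flat_params(sigma=0.05, alpha=2.0, beta=1.0, gamma=0.5, u0=0.4, s0=0.3):
    kin = dg.KineticParams(
        dg.RateSpline.constant(alpha),
        dg.RateSpline.constant(beta),
        dg.RateSpline.constant(gamma),
        u0,
        s0,
    )
    return ParamVector(
        SINGLE_CONDITION, {"c0": kin}, {"c0": sigma}, {"c0": sigma}
    )


class TestPenalizedLoglik:
    def test_flat_splines_pay_no_penalty(self, flat_course):
        params = flat_params()
        data = {"c0": flat_course}
        assert penalized_loglik(params, data, rho=10.0) == pytest.approx(
            penalized_loglik(params, data, rho=0.0)
        )

    def test_rho_zero_is_pure_gaussian_loglik(self, flat_course):
        # wobbly splines: penalty must vanish exactly when rho = 0
        nt = dg.default_node_times()
        vals = np.array([1.0, 3.0, 0.5, 4.0, 2.0, 5.0, 1.5, 3.5])
        kin = dg.KineticParams(
            dg.RateSpline(nt, vals), dg.RateSpline(nt, vals), dg.RateSpline(nt, vals),
            0.4, 0.3,
        )
        params = ParamVector(SINGLE_CONDITION, {"c0": kin}, {"c0": 0.05}, {"c0": 0.05})
        data = {"c0": flat_course}
        pen = 3 * float(np.sum(np.diff(vals) ** 2))
        L0 = penalized_loglik(params, data, rho=0.0)
        L10 = penalized_loglik(params, data, rho=10.0)
        assert L10 == pytest.approx(L0 - 10.0 * pen)

    def test_zero_residuals_hand_computed_value(self, flat_course):
        # the course was generated from exactly these parameters, so the
        # data-fit residuals vanish and only the log-normalisation remains
        params = flat_params(sigma=0.05)
        L = penalized_loglik(params, {"c0": flat_course}, rho=10.0)
        expected = -0.5 * 20 * (np.log(2 * np.pi * 0.05) + np.log(2 * np.pi * 0.05))
        assert L == pytest.approx(expected, abs=1e-6)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            flat_params(sigma=0.0)

    def test_rejects_negative_rho(self, flat_course):
        with pytest.raises(ValueError):
            penalized_loglik(flat_params(), {"c0": flat_course}, rho=-1.0)


class TestSamplesMode:
    def test_single_replicate_equals_plain_likelihood(self, flat_course):
        params = flat_params()
        plain = penalized_loglik(params, {"c0": flat_course}, rho=10.0)
        reps = penalized_loglik_samples(params, {"c0": [flat_course]}, rho=10.0)
        assert reps == pytest.approx(plain)

    def test_two_identical_replicates_double_data_term_only(self, flat_course):
        nt = dg.default_node_times()
        vals = np.linspace(0.5, 4.0, 8)
        kin = dg.KineticParams(
            dg.RateSpline(nt, vals), dg.RateSpline.constant(1.0),
            dg.RateSpline.constant(0.5), 0.4, 0.3,
        )
        params = ParamVector(SINGLE_CONDITION, {"c0": kin}, {"c0": 0.04}, {"c0": 0.04})
        rho = 7.0
        pen = rho * _wobbliness(params)
        L1 = penalized_loglik(params, {"c0": flat_course}, rho=rho)
        L2 = penalized_loglik_samples(params, {"c0": [flat_course, flat_course]}, rho=rho)
        # data term doubles, penalty enters once: L2 = 2*(L1 + pen) - pen
        assert L2 == pytest.approx(2.0 * L1 + pen)

    def test_opposite_residual_replicates_sum_independently(self):
        params = flat_params(sigma=0.05)
        course, kin = make_flat_course()
        traj = dg.integrate_kinetics(kin, course.pooled_times)
        delta = 0.1
        rep_plus = dg.GeneTimeCourse(
            course.pooled_times, traj.u + delta, traj.s + delta, condition="c0"
        )
        rep_minus = dg.GeneTimeCourse(
            course.pooled_times, traj.u - delta, traj.s - delta, condition="c0"
        )
        L = penalized_loglik_samples(params, {"c0": [rep_plus, rep_minus]}, rho=0.0)
        La = penalized_loglik(params, {"c0": rep_plus}, rho=0.0)
        Lb = penalized_loglik(params, {"c0": rep_minus}, rho=0.0)
        assert L == pytest.approx(La + Lb)

    def test_unequal_replicate_lengths_raise(self, flat_course):
        short = dg.GeneTimeCourse(
            flat_course.pooled_times[:10],
            flat_course.u_obs[:10],
            flat_course.s_obs[:10],
            condition="c0",
        )
        with pytest.raises(ValueError, match="unequal length"):
            penalized_loglik_samples(
                flat_params(), {"c0": [flat_course, short]}, rho=1.0
            )


class TestFitGene:
    def test_recovers_flat_rates_within_ten_percent(self, flat_course, small_fit_config):
        fit = fit_gene(
            {"c0": flat_course}, SINGLE_CONDITION, rho=10.0, seed=7,
            config=small_fit_config,
        )
        assert fit.success
        kin = fit.best_params.kinetics["c0"]
        t = flat_course.pooled_times
        for rate, truth in (("alpha", 2.0), ("beta", 1.0), ("gamma", 0.5)):
            est = getattr(kin, rate)(t)
            assert np.max(np.abs(est - truth) / truth) < 0.10, rate

    def test_best_params_respect_all_bounds(self, flat_course, small_fit_config):
        fit = fit_gene(
            {"c0": flat_course}, SINGLE_CONDITION, rho=10.0, seed=3,
            config=small_fit_config,
        )
        kin = fit.best_params.kinetics["c0"]
        for rate in ("alpha", "beta", "gamma"):
            vals = getattr(kin, rate).node_values
            assert np.all(vals >= 0.0) and np.all(vals <= dg.RATE_MAX + 1e-12)
        ref_u, ref_s = flat_course.u_obs[0], flat_course.s_obs[0]
        assert 0.1 * ref_u - 1e-9 <= kin.u0 <= 3.0 * ref_u + 1e-9
        assert 0.1 * ref_s - 1e-9 <= kin.s0 <= 3.0 * ref_s + 1e-9
        sd_u = fit.best_params.sd_u("c0")
        assert 0.01 * flat_course.u_obs.max() - 1e-12 <= sd_u
        assert sd_u <= 0.10 * flat_course.u_obs.max() + 1e-12

    def test_identical_seed_gives_identical_fit(self, flat_course, small_fit_config):
        f1 = fit_gene({"c0": flat_course}, SINGLE_CONDITION, seed=11, config=small_fit_config)
        f2 = fit_gene({"c0": flat_course}, SINGLE_CONDITION, seed=11, config=small_fit_config)
        assert np.array_equal(f1.x, f2.x)
        assert f1.penalized_loglik == f2.penalized_loglik

    def test_samples_mode_single_replicate_matches_plain(self, flat_course, small_fit_config):
        plain = fit_gene({"c0": flat_course}, SINGLE_CONDITION, seed=5, config=small_fit_config)
        reps = fit_gene({"c0": [flat_course]}, SINGLE_CONDITION, seed=5, config=small_fit_config)
        assert np.array_equal(plain.x, reps.x)

    def test_nesting_of_data_likelihood_at_rho_zero(self, small_fit_config):
        # identical conditions: the relaxed model M8 can only do at least as
        # well as M1 once the (model-size dependent) penalty is switched off
        course, _ = make_flat_course()
        data = {"wt": course, "mut": course}
        f1 = fit_gene(data, MODELS["M1"], rho=0.0, seed=2, config=small_fit_config)
        f8 = fit_gene(data, MODELS["M8"], rho=0.0, seed=2, config=small_fit_config)
        assert f8.penalized_loglik >= f1.penalized_loglik - 0.5

    def test_stronger_penalty_gives_flatter_splines(self, small_fit_config):
        total = {1.0: 0.0, 100.0: 0.0}
        for i in range(3):
            gene = dg.simulate_gene(MODELS["M1"], 1000 + i)
            course = gene.courses["c0"]
            for rho in (1.0, 100.0):
                fit = fit_gene(
                    {"c0": course}, SINGLE_CONDITION, rho=rho, seed=i,
                    config=small_fit_config,
                )
                total[rho] += _wobbliness(fit.best_params)
        assert total[100.0] <= total[1.0] + 1e-6

    def test_rejects_bad_arguments(self, flat_course):
        with pytest.raises(ValueError):
            fit_gene({"c0": flat_course}, SINGLE_CONDITION, rho=-1.0)
        with pytest.raises(ValueError):
            fit_gene({"c0": flat_course}, SINGLE_CONDITION, n_starts=0)
        with pytest.raises(ValueError):
            fit_gene({"c0": flat_course}, MODELS["M1"])  # needs 2 conditions
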