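"""Residual diagnostics, VPC calibration, bootstrap and external validation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vancopk import (
    CohortConfig,
    PopPKModel,
    PopulationParameters,
    load_model_spec,
    simulate_dataset,
)
from vancopk.covariates import ResidualErrorSpec, typical_parameters
from vancopk.diagnostics import (
    bootstrap,
    compare_models_paired,
    external_validation,
    gof_residuals,
    prediction_metrics,
    vpc,
)
from vancopk.estimation import map_eta
from vancopk.pk import concentration_at

from conftest import make_toy_subject


class TestPredictionMetrics:
    def test_hand_computed_toy_values(self):
        rep = prediction_metrics([10.0, 20.0], [8.0, 25.0])
        assert rep.mpe == pytest.approx(-1.5)
        assert rep.mae == pytest.approx(3.5)
        assert rep.mpe_pct == pytest.approx(2.5)
        assert rep.mae_pct == pytest.approx(22.5)
        assert rep.rmse == pytest.approx(np.sqrt(14.5), rel=1e-12)
        assert rep.rmse == pytest.approx(3.808, abs=1e-3)

    def test_perfect_prediction_zeroes_every_metric(self):
        rep = prediction_metrics([5.0, 7.0, 9.0], [5.0, 7.0, 9.0])
        assert (rep.mpe, rep.mae, rep.mpe_pct, rep.mae_pct, rep.rmse) == (0, 0, 0, 0, 0)

    def test_zero_observation_excluded_and_counted(self):
        rep = prediction_metrics([10.0, 5.0], [0.0, 4.0])
        assert rep.n_excluded == 1
        assert rep.mae_pct == pytest.approx(25.0)
        assert rep.n == 2

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_metric_inequalities_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        obs = rng.uniform(1.0, 30.0, n)
        ipred = obs * rng.lognormal(0, 0.4, n)
        rep = prediction_metrics(ipred, obs)
        assert rep.rmse >= rep.mae - 1e-12
        assert rep.mae >= abs(rep.mpe) - 1e-12
        assert rep.mae_pct >= abs(rep.mpe_pct) - 1e-9

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(8)
        obs = rng.uniform(2, 30, 25)
        ipred = obs * rng.lognormal(0, 0.3, 25)
        a = prediction_metrics(ipred, obs)
        perm = rng.permutation(25)
        b = prediction_metrics(ipred[perm], obs[perm])
        assert a.as_dict() == pytest.approx(b.as_dict())


class TestWilcoxonComparison:
    def test_identical_errors_degenerate(self):
        rep = compare_models_paired(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert rep.pvalue == 1.0
        assert "identical" in rep.note
        assert not rep.significant

    def test_exact_pvalue_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(4):
            n = 8
            d = rng.uniform(0.1, 3.0, n) * rng.choice([-1, 1], n)
            a = np.abs(rng.uniform(1, 5, n))
            b = a - d  # paired errors with differences d, no zeros/ties
            stat, p = stats.wilcoxon(a, b, mode="exact")
            ranks = stats.rankdata(np.abs(d))
            # enumerate all 2^n sign assignments of the ranks
            w_plus = []
            for signs in itertools.product([0, 1], repeat=n):
                w_plus.append(sum(r for s, r in zip(signs, ranks) if s))
            w_plus = np.array(w_plus)
            w_obs = float(np.sum(ranks[d > 0]))
            w_min = min(w_obs, n * (n + 1) / 2 - w_obs)
            p_enum = np.mean(np.minimum(w_plus, n * (n + 1) / 2 - w_plus) <= w_min)
            assert stat == pytest.approx(w_min)
            assert p == pytest.approx(p_enum, rel=1e-9)

    def test_shifted_errors_detected(self):
        rng = np.random.default_rng(19)
        a = rng.uniform(1, 3, 40)
        rep = compare_models_paired(a + 1.0, a)
        assert rep.pvalue < 0.001
        assert rep.significant


class TestGofResiduals:
    def test_cwres_calibration_at_scale(self, model2_spec, model2_params):
        cfg = CohortConfig(n_subjects=500, group="augmented", seed=71)
        cohort = simulate_dataset(cfg, model2_params, model2_spec)
        res = PopPKModel(cohort, model2_spec).evaluate(model2_params)
        gof = gof_residuals(res)
        assert len(gof) == sum(len(s.observations) for s in cohort)
        assert abs(gof["CWRES"].mean()) < 0.1
        assert 0.85 < gof["CWRES"].std(ddof=1) < 1.15
        assert np.isfinite(gof["CWRES"]).all()

    def test_noise_free_data_gives_zero_residuals(self, model2_spec):
        clean = PopulationParameters(
            theta=tuple(model2_spec.theta), omega_cl=0.0,
            sigma=ResidualErrorSpec("proportional", 0.0), spec=model2_spec)
        cohort = simulate_dataset(
            CohortConfig(n_subjects=10, group="augmented", seed=73), clean, model2_spec)
        eval_params = PopulationParameters(
            theta=tuple(model2_spec.theta), omega_cl=0.3,
            sigma=ResidualErrorSpec("proportional", 0.2), spec=model2_spec)
        gof = gof_residuals(PopPKModel(cohort, model2_spec).evaluate(eval_params))
        # CWRES vanishes to the inner mode-search tolerance
        assert np.max(np.abs(gof["CWRES"])) < 5e-3
        assert np.max(np.abs(gof["DV"] - gof["PRED"])) < 1e-8

    def test_single_observation_matches_hand_linearisation(self, model2_spec):
        subject = make_toy_subject(cl=0.9, v=5.2, times=(31.5,))
        params = PopulationParameters(
            theta=tuple(model2_spec.theta), omega_cl=0.3,
            sigma=ResidualErrorSpec("proportional", 0.25), spec=model2_spec)
        res = PopPKModel([subject], model2_spec).evaluate(params)
        gof = gof_residuals(res)
        eta_hat, _ = map_eta(subject, params)
        typ = typical_parameters(model2_spec, subject.covariates)
        d = 1e-4
        f = lambda e: float(concentration_at(
            31.5, subject.doses, type(typ)(typ.cl * np.exp(e), typ.v)))
        g = (f(eta_hat[0] + d) - f(eta_hat[0] - d)) / (2 * d)
        f_hat = f(eta_hat[0])
        mean = f_hat - g * eta_hat[0]
        sd = np.sqrt(g**2 * 0.3**2 + (0.25 * f_hat) ** 2)
        expected = (subject.observations[0].dv - mean) / sd
        assert gof["CWRES"].iloc[0] == pytest.approx(expected, rel=1e-6)


class TestVpc:
    def test_self_simulated_coverage_near_ninety_percent(
            self, model2_spec, model2_params):
        cohort = simulate_dataset(
            CohortConfig(n_subjects=200, group="augmented", seed=79),
            model2_params, model2_spec)
        res = PopPKModel(cohort, model2_spec).evaluate(model2_params)
        out = vpc(res, n_sim=300, seed=1)
        assert out.percentile_ordering_ok()
        # binomial tolerance at 400 observations around 0.90
        assert 0.85 <= out.coverage <= 0.95

    def test_grossly_inflated_volume_detected(self, model2_spec, model2_params):
        cohort = simulate_dataset(
            CohortConfig(n_subjects=200, group="augmented", seed=83),
            model2_params, model2_spec)
        theta = list(model2_params.theta)
        theta[1] *= 3.0  # V inflated x3
        bad = PopulationParameters(theta=tuple(theta),
                                   omega_cl=model2_params.omega_cl,
                                   sigma=model2_params.sigma, spec=model2_spec)
        res = PopPKModel(cohort, model2_spec).evaluate(bad)
        out = vpc(res, n_sim=200, seed=2)
        assert out.coverage < 0.85

    def test_replicate_count_stability(self, model2_spec, model2_params):
        cohort = simulate_dataset(
            CohortConfig(n_subjects=60, group="augmented", seed=89),
            model2_params, model2_spec)
        res = PopPKModel(cohort, model2_spec).evaluate(model2_params)
        small = vpc(res, n_sim=100, seed=3)
        large = vpc(res, n_sim=800, seed=3)
        for col in ("sim_p5", "sim_p50", "sim_p95"):
            np.testing.assert_allclose(small.table[col], large.table[col], rtol=0.10)

    def test_time_binning_available(self, model2_spec, model2_params):
        cohort = simulate_dataset(
            CohortConfig(n_subjects=40, group="augmented", seed=97),
            model2_params, model2_spec)
        res = PopPKModel(cohort, model2_spec).evaluate(model2_params)
        out = vpc(res, n_sim=100, bins="time", n_time_bins=2, seed=4)
        assert len(out.table) == 2

    def test_too_few_replicates_rejected(self, model2_spec, model2_params,
                                         arc_cohort):
        res = PopPKModel(arc_cohort, model2_spec).evaluate(model2_params)
        with pytest.raises(ValueError):
            vpc(res, n_sim=50)


class TestBootstrap:
    def test_single_subject_degenerates_to_point(self, model2_spec, toy_params):
        subject = make_toy_subject(cl=0.8, v=4.5)
        res = PopPKModel([subject], model2_spec).fit(init=toy_params)
        boot = bootstrap(res, n_reps=50, seed=5)
        assert boot.success_rate == 100.0
        assert np.allclose(boot.table["p97.5"] - boot.table["p2.5"], 0.0, atol=1e-9)
        assert np.allclose(boot.table["bias_pct"].abs(), 0.0, atol=1e-6)

    def test_rep_floor_enforced(self, model2_spec, toy_params):
        subject = make_toy_subject()
        res = PopPKModel([subject], model2_spec).fit(init=toy_params)
        with pytest.raises(ValueError):
            bootstrap(res, n_reps=10)


class TestExternalValidation:
    def test_stratified_vs_pooled_no_significant_difference(self, model1_spec):
        # replicate the study layout: stratified truths generate a mixed
        # modeling cohort; the stratified and pooled forms are fitted to
        # their respective cohorts and compared on held-out normal-group
        # subjects by paired absolute prediction errors
        p1 = PopulationParameters.published("model1")
        p2 = PopulationParameters.published("model2")
        p3 = PopulationParameters.published("model3")
        m2 = load_model_spec("model2")
        m3 = load_model_spec("model3")
        normal = simulate_dataset(
            CohortConfig(n_subjects=61, group="normal", seed=201), p1, model1_spec)
        arc = simulate_dataset(
            CohortConfig(n_subjects=54, group="augmented", seed=1201), p2, m2)
        fit1 = PopPKModel(normal, model1_spec).fit(init=p1)
        fit3 = PopPKModel(normal + arc, m3).fit(init=p3)
        external = simulate_dataset(
            CohortConfig(n_subjects=21, group="normal", seed=2201), p1, model1_spec)
        rep1 = external_validation(fit1.params, fit1.params.spec, external)
        rep3 = external_validation(fit3.params, fit3.params.spec, external)
        cmpres = compare_models_paired(rep1, rep3)
        assert cmpres.pvalue > 0.05
        assert rep1.rmse >= rep1.mae >= abs(rep1.mpe)

    def test_map_forecasting_tracks_observations(self, model2_spec, model2_params):
        external = simulate_dataset(
            CohortConfig(n_subjects=30, group="augmented", seed=103),
            model2_params, model2_spec)
        rep = external_validation(model2_params, model2_spec, external)
        # conditioning on the subject's own observations keeps relative
        # errors well below the residual-error scale
        assert rep.mae_pct < 100 * model2_params.sigma.sigma1
        assert rep.n == 60
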