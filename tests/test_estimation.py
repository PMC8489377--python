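"""FOCE engine: conditional modes, OFV vs quadrature, population fits."""

import numpy as np
import pytest

from vancopk import (
    CohortConfig,
    PopPKModel,
    PopulationParameters,
    load_model_spec,
    ofv_foce,
    ofv_quadrature_oracle,
    simulate_dataset,
)
from vancopk.covariates import CovariateTerm, ResidualErrorSpec, typical_parameters
from vancopk.estimation import (
    individual_minus2ll,
    jittered_init,
    map_eta,
    mc_oracle_minus2ll,
)
from vancopk.pk import IndividualParameters, concentration_at

from conftest import make_toy_subject


def params_for(spec, omega=0.3, sigma=0.2, form="proportional"):
    return PopulationParameters(
        theta=tuple(spec.theta), omega_cl=omega,
        sigma=ResidualErrorSpec(form, sigma), spec=spec,
    )


class TestIndividualMinus2LL:
    def test_perfect_fit_additive_unit_sigma(self, model2_spec):
        # Y = F exactly, additive sigma=1: -2ll = log(2*pi) per observation
        typ = typical_parameters(model2_spec, make_toy_subject().covariates)
        subject = make_toy_subject(cl=typ.cl, v=typ.v, times=(31.5,))
        params = params_for(model2_spec, sigma=1.0, form="additive")
        got = individual_minus2ll(subject, params, [0.0])
        assert got == pytest.approx(np.log(2 * np.pi), rel=1e-10)

    def test_two_observation_hand_density(self, model2_spec):
        subject = make_toy_subject(times=(31.5, 33.5))
        params = params_for(model2_spec, sigma=0.25)
        eta = 0.17
        typ = typical_parameters(model2_spec, subject.covariates)
        ip = IndividualParameters(typ.cl * np.exp(eta), typ.v)
        expected = 0.0
        for ob in subject.observations:
            f = float(concentration_at(ob.time, subject.doses, ip))
            var = (0.25 * f) ** 2
            expected += np.log(2 * np.pi * var) + (ob.dv - f) ** 2 / var
        got = individual_minus2ll(subject, params, [eta])
        assert got == pytest.approx(expected, rel=1e-10)

    def test_strictly_increasing_in_misfit(self, model2_spec):
        params = params_for(model2_spec, form="additive", sigma=1.0)
        typ = typical_parameters(model2_spec, make_toy_subject().covariates)
        base = make_toy_subject(cl=typ.cl, v=typ.v, times=(31.5,))
        f = base.observations[0].dv
        vals = [
            individual_minus2ll(
                make_toy_subject(cl=typ.cl, v=typ.v, times=(31.5,), dv=[f + off]),
                params, [0.0])
            for off in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(vals) > 0)


class TestMapEta:
    def test_strong_prior_pulls_eta_to_zero(self, model2_spec):
        subject = make_toy_subject(cl=1.4, v=4.89)  # data from eta != 0
        params = params_for(model2_spec, omega=1e-4, sigma=0.2)
        eta_hat, _ = map_eta(subject, params)
        assert abs(eta_hat[0]) < 1e-2

    def test_noise_free_recovery_of_known_eta(self, model2_spec):
        eta_true = 0.3
        typ = typical_parameters(model2_spec, make_toy_subject().covariates)
        subject = make_toy_subject(cl=typ.cl * np.exp(eta_true), v=typ.v)
        params = params_for(model2_spec, omega=0.5, sigma=0.05)
        eta_hat, curv = map_eta(subject, params)
        assert eta_hat[0] == pytest.approx(eta_true, abs=0.01)
        assert curv[0, 0] > 0

    def test_matches_dense_grid_search(self, model2_spec):
        subject = make_toy_subject(cl=0.9, v=5.5)
        params = params_for(model2_spec, omega=0.4, sigma=0.3)
        grid = np.linspace(-2, 2, 4001)
        omega2 = params.omega_cl**2
        h = np.array([
            individual_minus2ll(subject, params, [e])
            + e**2 / omega2 + np.log(2 * np.pi * omega2)
            for e in grid
        ])
        eta_grid = grid[np.argmin(h)]
        eta_hat, _ = map_eta(subject, params)
        assert eta_hat[0] == pytest.approx(eta_grid, abs=2e-3)


class TestOfv:
    def test_degenerate_omega_equals_fixed_effect_m2ll(self, model2_spec):
        subjects = [make_toy_subject(f"S{i}", cl=0.6 + 0.1 * i, v=4.0 + i)
                    for i in range(3)]
        params = params_for(model2_spec, omega=0.0, sigma=0.25)
        expected = 0.0
        for s in subjects:
            typ = typical_parameters(model2_spec, s.covariates)
            for ob in s.observations:
                f = float(concentration_at(ob.time, s.doses, typ))
                var = (0.25 * f) ** 2
                expected += np.log(2 * np.pi * var) + (ob.dv - f) ** 2 / var
        got = ofv_foce(subjects, model2_spec, params)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_three_subject_toy_close_to_quadrature(self, model2_spec):
        subjects = [make_toy_subject(f"S{i}", cl=0.5 + 0.2 * i, v=3.5 + 0.8 * i)
                    for i in range(3)]
        params = params_for(model2_spec, omega=0.35, sigma=0.25)
        foce = ofv_foce(subjects, model2_spec, params)
        quad = ofv_quadrature_oracle(subjects, model2_spec, params)
        assert foce == pytest.approx(quad, abs=0.5)

    def test_randomized_toys_within_one_unit_of_quadrature(self, model2_spec):
        rng = np.random.default_rng(23)
        for rep in range(8):
            n_sub = int(rng.integers(1, 6))
            subjects = []
            for i in range(n_sub):
                n_obs = int(rng.integers(1, 5))
                times = tuple(np.sort(rng.uniform(2.0, 40.0, n_obs)))
                subjects.append(make_toy_subject(
                    f"R{rep}_{i}", cl=float(rng.uniform(0.2, 2.0)),
                    v=float(rng.uniform(2.0, 8.0)), times=times))
            params = params_for(model2_spec, omega=float(rng.uniform(0.15, 0.5)),
                                sigma=float(rng.uniform(0.1, 0.35)))
            foce = ofv_foce(subjects, model2_spec, params)
            quad = ofv_quadrature_oracle(subjects, model2_spec, params)
            assert abs(foce - quad) < 1.0

    def test_subject_order_invariance(self, model2_spec):
        subjects = [make_toy_subject(f"S{i}", cl=0.5 + 0.15 * i, v=3.0 + 0.5 * i)
                    for i in range(5)]
        params = params_for(model2_spec)
        a = ofv_foce(subjects, model2_spec, params)
        b = ofv_foce(subjects[::-1], model2_spec, params)
        assert a == pytest.approx(b, abs=1e-9)


class TestQuadratureOracle:
    def test_degenerate_matches_closed_form(self, model2_spec):
        subjects = [make_toy_subject()]
        params = params_for(model2_spec, omega=0.0, sigma=0.25)
        assert ofv_quadrature_oracle(subjects, model2_spec, params) == pytest.approx(
            ofv_foce(subjects, model2_spec, params), rel=1e-12
        )

    def test_node_count_convergence(self, model2_spec):
        subjects = [make_toy_subject(cl=0.9, v=5.0)]
        params = params_for(model2_spec, omega=0.4, sigma=0.3)
        a = ofv_quadrature_oracle(subjects, model2_spec, params, n_nodes=32)
        b = ofv_quadrature_oracle(subjects, model2_spec, params, n_nodes=64)
        assert abs(a - b) < 1e-6

    def test_monte_carlo_agreement(self, model2_spec):
        subject = make_toy_subject(cl=0.85, v=4.2)
        params = params_for(model2_spec, omega=0.35, sigma=0.25)
        quad = ofv_quadrature_oracle([subject], model2_spec, params)
        mc, se = mc_oracle_minus2ll(subject, params, n_draws=200_000, seed=31)
        assert abs(quad - mc) < 3 * max(se, 1e-3)


class TestPopulationFit:
    def test_near_noise_free_theta_recovery(self, model2_spec):
        truth = PopulationParameters(
            theta=tuple(model2_spec.theta), omega_cl=0.0,
            sigma=ResidualErrorSpec("proportional", 0.02), spec=model2_spec,
        )
        cfg = CohortConfig(n_subjects=40, group="augmented", seed=37)
        cohort = simulate_dataset(cfg, truth, model2_spec)
        res = PopPKModel(cohort, model2_spec).fit(init=truth)
        for got, want in zip(res.params.theta, model2_spec.theta):
            assert got == pytest.approx(want, rel=0.02)

    def test_deterministic_given_data_and_init(self, arc_cohort, model2_spec,
                                               model2_params):
        model = PopPKModel(arc_cohort, model2_spec)
        a = model.fit(init=model2_params)
        b = model.fit(init=model2_params)
        assert a.params.theta == b.params.theta
        assert a.ofv == b.ofv

    def test_subject_permutation_leaves_estimates_unchanged(
            self, arc_cohort, model2_spec, model2_params):
        rng = np.random.default_rng(41)
        perm = list(rng.permutation(len(arc_cohort)))
        res_a = PopPKModel(arc_cohort, model2_spec).fit(init=model2_params)
        res_b = PopPKModel([arc_cohort[i] for i in perm], model2_spec).fit(
            init=model2_params)
        # summation order changes round-off, hence the optimizer path;
        # agreement is to optimizer tolerance, not bit-for-bit
        assert res_a.ofv == pytest.approx(res_b.ofv, abs=1e-3)
        np.testing.assert_allclose(res_a.params.theta, res_b.params.theta, rtol=1e-3)

    def test_spurious_covariate_never_raises_ofv(self, arc_cohort, model2_spec,
                                                 model2_params):
        from dataclasses import replace

        base = PopPKModel(arc_cohort, model2_spec).fit(init=model2_params)
        spurious = replace(
            model2_spec, name="model2+ALB",
            cl_terms=(CovariateTerm("ALB", 35.1, "power"),),
            theta=tuple(base.params.theta) + (0.0,),
        )
        init = PopulationParameters(
            theta=spurious.theta, omega_cl=base.params.omega_cl,
            sigma=base.params.sigma, spec=spurious,
        )
        nested = PopPKModel(arc_cohort, spurious).fit(init=init)
        assert nested.ofv <= base.ofv + 1e-3

    def test_consistency_bias_shrinks_with_n(self, model2_spec, model2_params):
        errs = {}
        for n, seeds in ((32, range(8)), (128, range(8))):
            abs_err = []
            for s in seeds:
                cfg = CohortConfig(n_subjects=n, group="augmented", seed=900 + s)
                cohort = simulate_dataset(cfg, model2_params, model2_spec)
                res = PopPKModel(cohort, model2_spec).fit(
                    init=jittered_init(model2_params, np.random.default_rng(900 + s)))
                abs_err.append(abs(res.params.theta[0] - 0.756))
            errs[n] = float(np.median(abs_err))
        assert errs[128] < errs[32]

    def test_bsv_on_volume_supported(self, model2_spec):
        truth = PopulationParameters(
            theta=tuple(model2_spec.theta), omega_cl=0.3, omega_v=0.2,
            sigma=ResidualErrorSpec("proportional", 0.15), spec=model2_spec,
        )
        cfg = CohortConfig(n_subjects=30, group="augmented", seed=43)
        cohort = simulate_dataset(cfg, truth, model2_spec)
        res = PopPKModel(cohort, model2_spec, eta_on=("CL", "V")).fit(init=truth)
        assert np.isfinite(res.ofv)
        assert res.ebe.shape == (30, 2)
        assert res.params.omega_v > 0


class TestShrinkage:
    def _rich_cohort(self, spec, n_sub=50, n_obs=8, omega=0.3, sigma=0.15, seed=47):
        rng = np.random.default_rng(seed)
        from vancopk.cohort import Observation, SubjectRecord
        from vancopk.covariates import Covariates
        from vancopk.pk import DosingEvent

        subjects = []
        for i in range(n_sub):
            cov = Covariates(wt=4.6, ht=54.0, scr=16.8, age_months=1.0)
            doses = tuple(DosingEvent(8.0 * j, 60.0, 1.0) for j in range(6))
            typ = typical_parameters(spec, cov)
            eta = rng.normal(0, omega)
            ip = IndividualParameters(typ.cl * np.exp(eta), typ.v)
            times = np.linspace(2.0, 46.0, n_obs)
            obs = []
            for t in times:
                f = float(concentration_at(t, doses, ip))
                obs.append(Observation(float(t), f * (1 + sigma * rng.standard_normal()), ""))
            subjects.append(SubjectRecord(f"R{i}", cov, 127.9, "augmented",
                                          doses, tuple(obs)))
        return subjects

    def test_rich_design_has_low_eta_shrinkage(self, model2_spec):
        cohort = self._rich_cohort(model2_spec)
        init = params_for(model2_spec, omega=0.3, sigma=0.15)
        res = PopPKModel(cohort, model2_spec).fit(init=init)
        assert res.eta_shrinkage < 8.0

    def test_no_information_limit_shrinks_fully(self, model2_spec, arc_cohort):
        # enormous residual noise: EBEs collapse to the prior mode
        params = params_for(model2_spec, omega=0.3, sigma=50.0)
        model = PopPKModel(arc_cohort, model2_spec)
        eng = model._engine
        theta, omegas, sigma = model._params_tuple(params)
        eng.set_params(theta, omegas, sigma)
        eta, _, _, _ = eng.map_with_restart(None)
        shrink = 100 * (1 - np.std(eta[:, 0], ddof=1) / 0.3)
        assert shrink > 90.0
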