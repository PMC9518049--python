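"""Estimator behaviour: MNL recovery, nesting, cross-checks, result bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from rplogit.data import CrashDataset
from rplogit.design import build_design
from rplogit.draws import make_draws
from rplogit.estimation import (
    EstimationResult,
    MixedLogit,
    MultinomialLogit,
    fit_mixed_logit,
    fit_mnl,
)
from rplogit.likelihood import simulated_log_likelihood
from rplogit.simulate import (
    GeneratorConfig,
    generate_covariates,
    simulate_outcomes,
)
from rplogit.spec import ParameterSet, SeveritySpec, Term


@pytest.fixture(scope="module")
def mnl_truth_fit():
    """Fixed-coefficient data with known truth, fitted once for several tests."""
    spec = SeveritySpec(
        constants=["MI", "SI", "FI"],
        terms=[Term("a", "MI"), Term("b", "SI"), Term("c", "FI")],
    )
    truth = ParameterSet(
        constants={"MI": 0.8, "SI": 0.3, "FI": -0.4},
        beta={"a": 1.0, "b": -0.7, "c": 0.9},
    )
    cfg = GeneratorConfig(
        n_obs=2000,
        prevalences={"a": 0.4, "b": 0.5, "c": 0.3},
        truth=truth,
        spec=spec,
        seed=17,
    )
    cov = generate_covariates(cfg)
    ds = simulate_outcomes(cov, truth, spec, seed=18)
    design = build_design(ds, spec)
    return spec, truth, ds, design, fit_mnl(design)


class TestFitMnl:
    def test_recovers_truth_within_three_se(self, mnl_truth_fit):
        spec, truth, _, design, res = mnl_truth_fit
        assert res.converged
        for a, v in truth.constants.items():
            assert abs(res.params.constants[a] - v) < 3 * res.std_errors.constants[a]
        for k, v in truth.beta.items():
            assert abs(res.params.beta[k] - v) < 3 * res.std_errors.beta[k]

    def test_matches_statsmodels_mnlogit(self):
        """Independent fit of the same model by statsmodels.

        With one covariate entering every non-base severity function plus
        all three constants, the spec is exactly the textbook MNL that
        statsmodels estimates, so converged log-likelihoods must agree."""
        sm = pytest.importorskip("statsmodels.api")
        spec = SeveritySpec(
            constants=["MI", "SI", "FI"],
            terms=[Term("x_mi", "MI"), Term("x_si", "SI"), Term("x_fi", "FI")],
        )
        rng = np.random.default_rng(4)
        n = 800
        x = rng.integers(0, 2, n)
        df = pd.DataFrame({"x_mi": x, "x_si": x, "x_fi": x})
        truth = ParameterSet(constants={"MI": 0.5, "SI": -0.2, "FI": 0.1},
                             beta={"x_mi": 0.8, "x_si": 0.4, "x_fi": -0.6})
        ds = simulate_outcomes(df, truth, spec, seed=5)
        res = fit_mnl(build_design(ds, spec))

        code = {"NI": 0, "MI": 1, "SI": 2, "FI": 3}
        y = ds.outcomes().map(code).to_numpy()
        X = np.column_stack([np.ones(n), x])
        smres = sm.MNLogit(y, X).fit(disp=0)
        assert res.ll_convergence == pytest.approx(smres.llf, abs=1e-4)

    def test_rho2_consistent_with_log_likelihoods(self, mnl_truth_fit):
        *_, res = mnl_truth_fit
        assert res.rho2 == pytest.approx(1 - res.ll_convergence / res.ll_zero, abs=1e-12)
        assert res.ll_convergence >= res.ll_zero

    def test_t_stats_are_estimate_over_se(self, mnl_truth_fit):
        *_, res = mnl_truth_fit
        for k in res.params.beta:
            assert res.t_stats.beta[k] == pytest.approx(
                res.params.beta[k] / res.std_errors.beta[k]
            )


class TestMixedLogitNesting:
    def test_mixed_ll_at_mnl_solution_matches_closed_form(self, small_design):
        """With sigma, Theta and omega pinned at zero the simulated likelihood
        is the closed-form MNL likelihood for any draw count."""
        mnl = fit_mnl(small_design, std_errors=False)
        draws = make_draws(small_design.n_obs, ["major_arterial"], 200)
        ll_mixed = simulated_log_likelihood(mnl.vector, small_design, draws)
        assert ll_mixed == pytest.approx(mnl.ll_convergence, abs=1e-6)

    def test_mixed_fit_improves_on_mnl(self, small_design):
        mnl = fit_mnl(small_design, std_errors=False)
        draws = make_draws(small_design.n_obs, ["major_arterial"], 100)
        mixed = fit_mixed_logit(small_design, draws, std_errors=False)
        assert mixed.ll_convergence >= mnl.ll_convergence - 1e-8

    def test_draw_count_stability_at_optimum(self, mixed_spec):
        from rplogit.simulate import generate_dataset

        ds = generate_dataset(GeneratorConfig(n_obs=500, seed=23))
        design = build_design(ds, mixed_spec)
        draws1k = make_draws(500, ["major_arterial"], 1000)
        res = fit_mixed_logit(design, draws1k, std_errors=False)
        draws2k = make_draws(500, ["major_arterial"], 2000)
        ll2k = simulated_log_likelihood(res.vector, design, draws2k)
        assert abs(ll2k - res.ll_convergence) < 1e-3 * abs(res.ll_convergence)


class TestSklearnSurface:
    def test_fit_predict_proba_and_params(self, mixed_spec):
        from rplogit.simulate import generate_dataset

        ds = generate_dataset(GeneratorConfig(n_obs=250, seed=31))
        X, y = ds.covariates(), ds.outcomes()
        est = MixedLogit(spec=mixed_spec, n_draws=50)
        assert est.get_params()["n_draws"] == 50
        est.set_params(n_draws=60)
        est.fit(X, y)
        assert est.converged_
        assert est.rho2_ == pytest.approx(1 - est.ll_convergence_ / est.ll_zero_)
        P = est.predict_proba(X.head(10))
        assert P.shape == (10, 4)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert set(est.predict(X.head(10))) <= set(est.classes_)

    def test_invalid_param_name_rejected(self, mixed_spec):
        with pytest.raises(ValueError, match="invalid parameter"):
            MultinomialLogit(spec=mixed_spec).set_params(bogus=1)

    def test_zero_draws_rejected(self, mixed_spec, small_dataset):
        est = MixedLogit(spec=mixed_spec, n_draws=0)
        with pytest.raises(ValueError, match="n_draws"):
            est.fit(small_dataset.covariates(), small_dataset.outcomes())


class TestResultSerialization:
    def test_save_load_round_trip(self, tmp_path, mnl_truth_fit):
        spec, _, ds, _, res = mnl_truth_fit
        p = tmp_path / "result.json"
        res.save(p)
        back = EstimationResult.load(p, ds_for_design=ds)
        assert back.ll_convergence == pytest.approx(res.ll_convergence)
        assert back.n_params == res.n_params
        np.testing.assert_allclose(back.vector, res.vector)
        assert back.spec == spec
        assert back.params.beta["a"] == pytest.approx(res.params.beta["a"])
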