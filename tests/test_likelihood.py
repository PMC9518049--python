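"""Likelihood core: coefficient construction, softmax, null LL, simulated LL.

The key oracle here is a deliberately naive record-by-record, draw-by-draw
loop that rebuilds every coefficient with `construct_coefficients` and
evaluates plain softmax probabilities in Python floats; the vectorised
simulated likelihood must agree with it to near machine precision.
"""

import math

import numpy as np
import pytest

from rplogit.design import build_design
from rplogit.draws import make_draws
from rplogit.likelihood import (
    construct_coefficients,
    loglik_and_grad,
    mcfadden_rho2,
    mnl_probabilities,
    null_log_likelihood,
    simulated_log_likelihood,
    simulated_probabilities,
)
from rplogit.simulate import GeneratorConfig, generate_dataset
from rplogit.spec import ParameterSet


class TestConstructCoefficients:
    def test_degenerate_random_term_returns_beta(self):
        params = ParameterSet(beta={"x": 1.7}, sigma={"x": 2.0},
                              theta={("x", "z"): 0.0}, omega={("x", "w"): 0.0})
        got = construct_coefficients(params, {"z": 1, "w": 1}, nu={"x": 0.0})
        assert got["x"] == pytest.approx(1.7)

    def test_mean_shift_and_scale_arithmetic(self):
        # beta=1, Theta.Z=0.5, sigma=2, omega.W=0, nu=1 -> 1 + 0.5 + 2*1 = 3.5
        params = ParameterSet(beta={"x": 1.0}, theta={("x", "z"): 0.5},
                              sigma={"x": 2.0}, omega={("x", "w"): 0.0})
        got = construct_coefficients(params, {"z": 1, "w": 1}, nu={"x": 1.0})
        assert got["x"] == pytest.approx(3.5)

    def test_omega_w_log2_doubles_effective_sd(self):
        base = ParameterSet(beta={"x": 0.0}, sigma={"x": 1.3}, omega={("x", "w"): 0.0})
        double = ParameterSet(beta={"x": 0.0}, sigma={"x": 1.3},
                              omega={("x", "w"): math.log(2)})
        for nu in (0.7, -1.9):
            a = construct_coefficients(base, {"w": 1}, nu={"x": nu})["x"]
            b = construct_coefficients(double, {"w": 1}, nu={"x": nu})["x"]
            assert b == pytest.approx(2 * a)


class TestMnlProbabilities:
    def test_equal_utilities_give_equal_shares(self):
        np.testing.assert_allclose(mnl_probabilities(np.zeros(4)), np.full(4, 0.25))

    def test_matches_direct_softmax(self):
        u = np.array([0.0, 0.5, 1.0, -0.5])
        e = np.exp(u)
        np.testing.assert_allclose(mnl_probabilities(u), e / e.sum(), rtol=1e-14)

    def test_invariance_to_utility_shift(self):
        u = np.array([[0.2, -1.0, 3.0, 0.0]])
        np.testing.assert_allclose(
            mnl_probabilities(u), mnl_probabilities(u + 7.0), rtol=1e-14
        )

    def test_probabilities_normalise(self, small_design):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(small_design.n_params)
        draws = make_draws(small_design.n_obs, ["major_arterial"], 20)
        P = simulated_probabilities(v, small_design, draws)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestNullLogLikelihood:
    @pytest.mark.parametrize(
        "n, expected",
        [(2045, -2834.971), (2095, -2904.287), (2262, -3135.797),
         (5067, -7024.353), (5566, -7716.114), (7202, -9984.092)],
    )
    def test_printed_equal_share_values(self, n, expected):
        assert null_log_likelihood(n, 4) == pytest.approx(expected, abs=0.005)

    def test_single_record(self):
        assert null_log_likelihood(1, 4) == pytest.approx(-math.log(4))


def brute_force_simulated_ll(ds, spec, params, draws):
    """Independent oracle: explicit per-record, per-draw loops."""
    alts = list(spec.alternatives)
    rvars = [t.variable for t in spec.random_terms]
    ll = 0.0
    for n, rec in enumerate(ds.records()):
        probs = []
        for d in range(draws.n_draws):
            nu = {v: draws.draws[n, k, d] for k, v in enumerate(rvars)}
            coefs = construct_coefficients(params, rec.covariates, nu)
            util = {a: params.constants.get(a, 0.0) for a in alts}
            for t in spec.terms:
                util[t.target] += coefs[t.variable] * rec.covariates[t.variable]
            denom = sum(math.exp(util[a]) for a in alts)
            probs.append(math.exp(util[rec.outcome]) / denom)
        ll += math.log(sum(probs) / len(probs))
    return ll


class TestSimulatedLogLikelihood:
    def test_all_zero_parameters_reduce_to_null(self, small_design):
        v = np.zeros(small_design.n_params)
        draws = make_draws(small_design.n_obs, ["major_arterial"], 7)
        assert simulated_log_likelihood(v, small_design, draws) == pytest.approx(
            null_log_likelihood(small_design.n_obs, 4), abs=1e-10
        )

    def test_no_random_terms_independent_of_draw_count(self, tiny_dataset, tiny_mnl_spec):
        design = build_design(tiny_dataset, tiny_mnl_spec)
        rng = np.random.default_rng(3)
        v = rng.standard_normal(design.n_params)
        ll_none = simulated_log_likelihood(v, design, None)
        # no random terms: the mixture is degenerate whatever D is
        assert simulated_log_likelihood(v, design, None) == ll_none

    def test_matches_brute_force_oracle(self, mixed_spec):
        ds = generate_dataset(GeneratorConfig(n_obs=20, seed=5))
        design = build_design(ds, mixed_spec)
        draws = make_draws(20, ["major_arterial"], 50)
        rng = np.random.default_rng(11)
        v = 0.4 * rng.standard_normal(design.n_params)
        expected = brute_force_simulated_ll(ds, mixed_spec, design.unflatten(v), draws)
        got = simulated_log_likelihood(v, design, draws)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_analytic_score_matches_finite_differences(self, mixed_spec):
        ds = generate_dataset(GeneratorConfig(n_obs=60, seed=9))
        design = build_design(ds, mixed_spec)
        draws = make_draws(60, ["major_arterial"], 25)
        rng = np.random.default_rng(2)
        v = 0.3 * rng.standard_normal(design.n_params)
        _, g = loglik_and_grad(v, design, draws)
        h = 1e-6
        for j in range(design.n_params):
            vp, vm = v.copy(), v.copy()
            vp[j] += h
            vm[j] -= h
            fd = (
                simulated_log_likelihood(vp, design, draws)
                - simulated_log_likelihood(vm, design, draws)
            ) / (2 * h)
            assert g[j] == pytest.approx(fd, abs=1e-5)

    def test_non_finite_parameters_raise(self, small_design):
        v = np.zeros(small_design.n_params)
        v[0] = np.nan
        with pytest.raises(FloatingPointError):
            simulated_log_likelihood(v, small_design, None)


class TestMcFaddenRho2:
    @pytest.mark.parametrize(
        "ll_c, ll_0, expected",
        [(-1258.448, -2904.287, 0.567), (-5942.63, -9984.092, 0.405)],
    )
    def test_printed_goodness_of_fit_pairs(self, ll_c, ll_0, expected):
        assert mcfadden_rho2(ll_c, ll_0) == pytest.approx(expected, abs=5e-4)

    def test_zero_improvement_gives_zero(self):
        assert mcfadden_rho2(-100.0, -100.0) == 0.0
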