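"""Likelihood machinery for the random-parameters multinomial logit.

The latent severity function of alternative i for crash n is

    M_in = V_in + eps_in,      V_in = c_i + sum_{terms t: target=i} b_tn x_tn

with i.i.d. type-I extreme-value errors eps, which integrate analytically
to multinomial-logit (softmax) probabilities over the four severity levels.
A random term's coefficient varies across crashes:

    b_tn = beta_t + Theta_t . Z_n + sigma_t * exp(omega_t . W_n) * nu_tn

with standard-normal nu.  The resulting mixed-logit probability is the
integral of the softmax over nu, approximated by averaging over Halton
draws; the simulated log-likelihood is

    LL = sum_n log( (1/D) sum_d P_nd(y_n) ).

Both the simulated log-likelihood and its exact analytic score are
implemented here; with no random terms both collapse to the closed-form
multinomial logit for any number of draws.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .design import ModelDesign
from .draws import DrawSet
from .spec import ParameterSet


def construct_coefficients(
    params: ParameterSet,
    covariates: Mapping[str, float],
    nu: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-crash coefficient values b_tn for one record.

    Fixed terms return beta unchanged; a random term with mixing deviate
    nu returns beta + Theta.Z + sigma*exp(omega.W)*nu.  Pure function; used
    by the synthetic-data generator and as a readable single-record oracle
    for the vectorised likelihood.
    """
    nu = nu or {}
    out: dict[str, float] = {}
    for var, beta in params.beta.items():
        b = beta
        for (v, z), th in params.theta.items():
            if v == var:
                b += th * covariates[z]
        if var in params.sigma:
            ww = 0.0
            for (v, w), om in params.omega.items():
                if v == var:
                    ww += om * covariates[w]
            b += params.sigma[var] * math.exp(ww) * nu.get(var, 0.0)
        out[var] = b
    return out


def mnl_probabilities(utilities: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, guarded by max-subtraction.

    Invariant to adding any constant to all utilities of a record.
    """
    u = np.asarray(utilities, dtype=float)
    m = u.max(axis=-1, keepdims=True)
    e = np.exp(u - m)
    return e / e.sum(axis=-1, keepdims=True)


def null_log_likelihood(n_obs: int, n_alternatives: int = 4) -> float:
    """Log-likelihood with every parameter at zero: equal shares, -N ln(J)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -n_obs * math.log(n_alternatives)


def _utilities(design: ModelDesign, vec: np.ndarray, draws: DrawSet | None) -> np.ndarray:
    """Systematic utilities, shape (N, D, A); D=1 when there are no draws."""
    N, A = design.n_obs, len(design.alternatives)
    vfix = np.zeros((N, A))
    for i, a in enumerate(design.const_alt_indices):
        vfix[:, a] += vec[design.sl_constants.start + i]
    rand_idx = []
    for i, td in enumerate(design.terms):
        beta = vec[design.sl_beta.start + i]
        if td.term.role == "fixed":
            vfix[:, td.alt_index] += beta * td.x
        else:
            rand_idx.append(i)
    if not rand_idx or draws is None:
        U = vfix[:, None, :].copy()
        if rand_idx and draws is None:
            # closed-form evaluation: nu = 0, mean part only
            for i in rand_idx:
                td = design.terms[i]
                b = vec[design.sl_beta.start + i] + td.Z @ _theta_vec(design, vec, td)
                U[:, 0, td.alt_index] += b * td.x
        return U
    D = draws.n_draws
    U = np.repeat(vfix[:, None, :], D, axis=1)
    for k, i in enumerate(rand_idx):
        td = design.terms[i]
        b = vec[design.sl_beta.start + i] + td.Z @ _theta_vec(design, vec, td)
        s = vec[design.sigma_index[td.term.variable]] * np.exp(td.W @ _omega_vec(design, vec, td))
        coef = b[:, None] + s[:, None] * draws.for_term(k)      # (N, D)
        U[:, :, td.alt_index] += coef * td.x[:, None]
    return U


def _theta_vec(design: ModelDesign, vec: np.ndarray, td) -> np.ndarray:
    return np.array(
        [vec[design.theta_index[(td.term.variable, z)]] for z in td.term.het_mean_covariates]
    )


def _omega_vec(design: ModelDesign, vec: np.ndarray, td) -> np.ndarray:
    return np.array(
        [vec[design.omega_index[(td.term.variable, w)]] for w in td.term.het_variance_covariates]
    )


def simulated_probabilities(
    vec: np.ndarray, design: ModelDesign, draws: DrawSet | None = None
) -> np.ndarray:
    """Per-record outcome probabilities, draw-averaged; shape (N, A)."""
    P = mnl_probabilities(_utilities(design, vec, draws))
    return P.mean(axis=1)


def simulated_log_likelihood(
    vec: np.ndarray, design: ModelDesign, draws: DrawSet | None = None
) -> float:
    """The simulated log-likelihood at a flat parameter vector."""
    ll, _ = _loglik_core(vec, design, draws, want_grad=False)
    return ll


def loglik_and_grad(
    vec: np.ndarray, design: ModelDesign, draws: DrawSet | None = None
) -> tuple[float, np.ndarray]:
    """Simulated log-likelihood and its exact analytic score."""
    return _loglik_core(vec, design, draws, want_grad=True)


def _loglik_core(vec, design: ModelDesign, draws, want_grad: bool):
    vec = np.asarray(vec, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError(f"non-finite parameter vector: {vec}")
    has_random = bool(design.random_terms) and draws is not None
    if has_random:
        return _loglik_mixed(vec, design, draws, want_grad)
    return _loglik_closed_form(vec, design, want_grad)


def _loglik_closed_form(vec, design: ModelDesign, want_grad: bool):
    N = design.n_obs
    V = _utilities(design, vec, None)[:, 0, :]     # (N, A)
    P = mnl_probabilities(V)
    Py = np.clip(P[np.arange(N), design.y], 1e-300, None)
    ll = float(np.log(Py).sum())
    if not want_grad:
        return ll, None
    # MNL score: sum_n (1{a=y} - P_na) dV_na/dtheta
    E = -P
    E[np.arange(N), design.y] += 1.0
    g = np.zeros(design.n_params)
    for i, a in enumerate(design.const_alt_indices):
        g[design.sl_constants.start + i] = E[:, a].sum()
    for i, td in enumerate(design.terms):
        ex = E[:, td.alt_index] * td.x
        g[design.sl_beta.start + i] = ex.sum()
        if td.term.role == "random":
            # nu is absent: only the mean pathway (beta, Theta) contributes
            for j, z in enumerate(td.term.het_mean_covariates):
                g[design.theta_index[(td.term.variable, z)]] = (ex * td.Z[:, j]).sum()
    return ll, g


def _loglik_mixed(vec, design: ModelDesign, draws: DrawSet, want_grad: bool):
    """Simulated LL and score in (N, D) working arrays.

    Only alternatives targeted by a random term have draw-dependent
    utilities; the remaining alternatives are collapsed into a single
    per-record log-sum-exp, which keeps the inner arrays at (records,
    draws) rather than (records, draws, alternatives).
    """
    N, A = design.n_obs, len(design.alternatives)
    D = draws.n_draws
    y = design.y

    V = np.zeros((N, A))
    for i, a in enumerate(design.const_alt_indices):
        V[:, a] += vec[design.sl_constants.start + i]
    rand: list[tuple[int, object, np.ndarray, np.ndarray, np.ndarray]] = []
    rand_alts: list[int] = []
    k = 0
    for i, td in enumerate(design.terms):
        beta = vec[design.sl_beta.start + i]
        if td.term.role == "fixed":
            V[:, td.alt_index] += beta * td.x
        else:
            b = beta + td.Z @ _theta_vec(design, vec, td)
            scale = np.exp(td.W @ _omega_vec(design, vec, td))        # (N,)
            nu = draws.for_term(k)
            coef = (b[:, None] + (vec[design.sigma_index[td.term.variable]]
                                  * scale)[:, None] * nu) * td.x[:, None]
            rand.append((i, td, scale, nu, coef))
            if td.alt_index not in rand_alts:
                rand_alts.append(td.alt_index)
            k += 1

    fixed_alts = [a for a in range(A) if a not in rand_alts]
    # log sum of the draw-independent alternatives, stabilised
    if fixed_alts:
        Vf = V[:, fixed_alts]
        mf = Vf.max(axis=1)
        logZfix = mf + np.log(np.exp(Vf - mf[:, None]).sum(axis=1))   # (N,)
    else:
        logZfix = np.full(N, -np.inf)

    u = {a: np.repeat(V[:, a, None], D, axis=1) for a in rand_alts}   # (N, D)
    for _, td, _, _, coef in rand:
        u[td.alt_index] += coef

    logdenom = np.broadcast_to(logZfix[:, None], (N, D)).copy()
    for a in rand_alts:
        logdenom = np.logaddexp(logdenom, u[a])

    y_in_rand = np.isin(y, rand_alts)
    logPy = np.where(y_in_rand[:, None], 0.0, V[np.arange(N), y][:, None]) - logdenom
    for a in rand_alts:
        mask = y == a
        if mask.any():
            logPy[mask] += u[a][mask]
    Py = np.exp(logPy)                                                # (N, D)
    S = np.clip(Py.mean(axis=1), 1e-300, None)
    ll = float(np.log(S).sum())
    if not want_grad:
        return ll, None

    w = Py / (S[:, None] * D)                                         # rows sum to 1
    # G_na = sum_d w_nd (1{a=y_n} - P_nda)
    G = np.zeros((N, A))
    if fixed_alts:
        # sum_d w_nd P_nda = exp(V_na - logZfix) * sum_d w_nd Zfix_n/denom_nd
        T = (w * np.exp(logZfix[:, None] - logdenom)).sum(axis=1)     # (N,), <= 1
        for a in fixed_alts:
            G[:, a] = -np.exp(V[:, a] - logZfix) * T
    E_rand = {a: np.exp(u[a] - logdenom) for a in rand_alts}          # P_nd,a
    for a in rand_alts:
        G[:, a] = -(w * E_rand[a]).sum(axis=1)
    G[np.arange(N), y] += 1.0

    g = np.zeros(design.n_params)
    for i, a in enumerate(design.const_alt_indices):
        g[design.sl_constants.start + i] = G[:, a].sum()
    for i, td in enumerate(design.terms):
        if td.term.role == "fixed":
            g[design.sl_beta.start + i] = (G[:, td.alt_index] * td.x).sum()
    for i, td, scale, nu, _ in rand:
        a = td.alt_index
        ex = G[:, a] * td.x
        g[design.sl_beta.start + i] = ex.sum()
        for j, z in enumerate(td.term.het_mean_covariates):
            g[design.theta_index[(td.term.variable, z)]] = (ex * td.Z[:, j]).sum()
        # q_n = sum_d w_nd (1{a=y_n} - P_nd,a) nu_nd
        q = -(w * E_rand[a] * nu).sum(axis=1)
        mask = y == a
        if mask.any():
            q[mask] += (w[mask] * nu[mask]).sum(axis=1)
        sigma = vec[design.sigma_index[td.term.variable]]
        g[design.sigma_index[td.term.variable]] = (q * scale * td.x).sum()
        for j, wv in enumerate(td.term.het_variance_covariates):
            g[design.omega_index[(td.term.variable, wv)]] = (
                sigma * q * scale * td.W[:, j] * td.x
            ).sum()
    return ll, g


def mcfadden_rho2(ll_convergence: float, ll_zero: float) -> float:
    """McFadden pseudo R-squared, 1 - LL(beta)/LL(0)."""
    if ll_zero >= 0:
        raise ValueError("ll_zero must be negative")
    return 1.0 - ll_convergence / ll_zero
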