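"""Model fitting by (simulated) maximum likelihood, and sklearn-style estimators.

The simulated log-likelihood is maximised by quasi-Newton (BFGS) ascent
using the exact analytic simulated score; standard errors come from the
inverse numerical Hessian at the optimum (central differences of the
analytic score).  The mixed fit starts from the converged plain-MNL
estimates with each sigma initialised small (0.1) and all Theta/omega at
zero.  A normal mixing density is reported as |sigma| since the density is
symmetric in sigma's sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import CrashDataset
from .design import ModelDesign, build_design
from .draws import DEFAULT_N_DRAWS, DEFAULT_SKIP, DrawSet, make_draws
from .likelihood import (
    loglik_and_grad,
    mcfadden_rho2,
    null_log_likelihood,
    simulated_log_likelihood,
    simulated_probabilities,
)
from .spec import ParameterSet, SeveritySpec

DEFAULT_GTOL = 1e-5
DEFAULT_MAXITER = 500


@dataclass
class EstimationResult:
    """Converged estimates plus the bookkeeping the instability tests need."""

    params: ParameterSet
    std_errors: ParameterSet
    t_stats: ParameterSet
    ll_zero: float
    ll_convergence: float
    rho2: float
    n_obs: int
    n_params: int
    n_draws: int
    skip: int
    converged: bool
    spec: SeveritySpec
    vector: np.ndarray = field(repr=False)           # raw optimum (sigma signed)
    param_names: list[str] = field(default_factory=list, repr=False)
    se_vector: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "vector": list(map(float, self.vector)),
            "param_names": list(self.param_names),
            "se_vector": None if self.se_vector is None
            else [None if not np.isfinite(s) else float(s) for s in self.se_vector],
            "ll_zero": self.ll_zero,
            "ll_convergence": self.ll_convergence,
            "rho2": self.rho2,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "n_draws": self.n_draws,
            "skip": self.skip,
            "converged": self.converged,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path, ds_for_design: CrashDataset | None = None) -> "EstimationResult":
        """Rehydrate a saved result.  A dataset with the spec's variables is
        needed to rebuild the parameter index map; any dataset with those
        columns works (only the column names matter)."""
        d = json.loads(Path(path).read_text())
        spec = SeveritySpec.from_dict(d["spec"])
        vec = np.array(d["vector"])
        se = d.get("se_vector")
        se = None if se is None else np.array([np.nan if s is None else s for s in se])
        if ds_for_design is not None:
            design = build_design(ds_for_design, spec, check_identification=False)
            params = design.unflatten(vec)
            ses = design.unflatten(se) if se is not None else ParameterSet.zeros(spec)
        else:
            params = ParameterSet.zeros(spec)
            ses = ParameterSet.zeros(spec)
        params, ses, ts = _reported_parameters(params, ses)
        return cls(
            params=params, std_errors=ses, t_stats=ts,
            ll_zero=d["ll_zero"], ll_convergence=d["ll_convergence"], rho2=d["rho2"],
            n_obs=d["n_obs"], n_params=d["n_params"], n_draws=d["n_draws"],
            skip=d["skip"], converged=d["converged"], spec=spec,
            vector=vec, param_names=d.get("param_names", []), se_vector=se,
        )


def _reported_parameters(params: ParameterSet, ses: ParameterSet):
    """Report |sigma| and elementwise t = estimate / SE (NaN where SE is not)."""
    params.sigma = {k: abs(v) for k, v in params.sigma.items()}

    def tmap(est: dict, se: dict) -> dict:
        out = {}
        for k, v in est.items():
            s = se.get(k, np.nan)
            out[k] = v / s if (np.isfinite(s) and s > 0) else np.nan
        return out

    ts = ParameterSet(
        constants=tmap(params.constants, ses.constants),
        beta=tmap(params.beta, ses.beta),
        theta=tmap(params.theta, ses.theta),
        sigma=tmap(params.sigma, ses.sigma),
        omega=tmap(params.omega, ses.omega),
    )
    return params, ses, ts


def _neg_ll_and_grad(sub, full, free_idx, design, draws):
    full = full.copy()
    full[free_idx] = sub
    try:
        ll, g = loglik_and_grad(full, design, draws)
    except FloatingPointError:
        return np.inf, np.zeros(len(free_idx))
    return -ll, -g[free_idx]


def _maximize(design, start, draws, free_idx, gtol, maxiter):
    res = minimize(
        _neg_ll_and_grad,
        start[free_idx],
        args=(start, free_idx, design, draws),
        method="BFGS",
        jac=True,
        options={"gtol": gtol, "maxiter": maxiter},
    )
    full = start.copy()
    full[free_idx] = res.x
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success) or grad_norm < 100 * gtol
    return full, -float(res.fun), converged


def _hessian_std_errors(design, vec, draws, free_idx):
    """Central-difference Hessian of -LL from the analytic score; SEs from its inverse."""
    p = len(free_idx)
    H = np.zeros((p, p))
    for j, idx in enumerate(free_idx):
        h = 1e-5 * max(1.0, abs(vec[idx]))
        vp, vm = vec.copy(), vec.copy()
        vp[idx] += h
        vm[idx] -= h
        _, gp = loglik_and_grad(vp, design, draws)
        _, gm = loglik_and_grad(vm, design, draws)
        H[:, j] = -(gp[free_idx] - gm[free_idx]) / (2 * h)
    H = 0.5 * (H + H.T)
    se = np.full(design.n_params, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        with np.errstate(invalid="ignore"):
            se[free_idx] = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        pass
    return se


def _finish(design, vec, ll, converged, draws, free_idx, n_draws, skip, std_errors=True):
    se = (
        _hessian_std_errors(design, vec, draws, free_idx)
        if std_errors else np.full(design.n_params, np.nan)
    )
    params = design.unflatten(vec)
    ses = design.unflatten(se)
    params, ses, ts = _reported_parameters(params, ses)
    ll0 = null_log_likelihood(design.n_obs, len(design.alternatives))
    return EstimationResult(
        params=params,
        std_errors=ses,
        t_stats=ts,
        ll_zero=ll0,
        ll_convergence=ll,
        rho2=mcfadden_rho2(ll, ll0),
        n_obs=design.n_obs,
        n_params=len(free_idx),
        n_draws=n_draws,
        skip=skip,
        converged=converged,
        spec=design.spec,
        vector=vec,
        param_names=design.param_names,
        se_vector=se,
    )


def fit_mnl(
    design: ModelDesign,
    gtol: float = DEFAULT_GTOL,
    maxiter: int = DEFAULT_MAXITER,
    std_errors: bool = True,
) -> EstimationResult:
    """Closed-form multinomial logit fit (constants and betas; no mixing).

    On a spec with random terms this fits their means as fixed coefficients
    — the documented starting point for the mixed fit.
    """
    free_idx = np.arange(design.sl_constants.start, design.sl_beta.stop)
    start = np.zeros(design.n_params)
    vec, ll, converged = _maximize(design, start, None, free_idx, gtol, maxiter)
    return _finish(design, vec, ll, converged, None, free_idx, 0, 0, std_errors)


def fit_mixed_logit(
    design: ModelDesign,
    draws: DrawSet,
    start: np.ndarray | None = None,
    gtol: float = DEFAULT_GTOL,
    maxiter: int = DEFAULT_MAXITER,
    sigma_start: float = 0.1,
    n_restarts: int = 0,
    restart_scale: float = 0.25,
    restart_seed: int = 0,
    std_errors: bool = True,
) -> EstimationResult:
    """Simulated maximum-likelihood fit of the random-parameters logit.

    ``n_restarts`` optional seeded perturbation restarts guard against the
    multimodality simulated likelihoods can exhibit; the best optimum wins.
    """
    if not design.random_terms:
        return fit_mnl(design, gtol=gtol, maxiter=maxiter, std_errors=std_errors)
    if draws.n_records != design.n_obs:
        raise ValueError("draw set was built for a different number of records")
    if start is None:
        mnl = fit_mnl(design, gtol=gtol, maxiter=maxiter, std_errors=False)
        start = mnl.vector.copy()
        for idx in design.sigma_index.values():
            start[idx] = sigma_start
    free_idx = np.arange(design.n_params)
    vec, ll, converged = _maximize(design, start, draws, free_idx, gtol, maxiter)
    if n_restarts:
        rng = np.random.RandomState(restart_seed % (2**31))
        for _ in range(n_restarts):
            s = start + restart_scale * rng.standard_normal(design.n_params)
            v2, l2, c2 = _maximize(design, s, draws, free_idx, gtol, maxiter)
            if l2 > ll:
                vec, ll, converged = v2, l2, c2
    return _finish(design, vec, ll, converged, draws, free_idx, draws.n_draws, draws.skip, std_errors)


# ---------------------------------------------------------------------------
# sklearn-style estimator surface


def _dataset_from_xy(X: pd.DataFrame, y) -> CrashDataset:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame with named indicator columns")
    df = X.copy()
    df["outcome"] = np.asarray(y, dtype=object)
    df["period"] = "all"
    df["group"] = "all"
    return CrashDataset(df=df, variables=list(X.columns), provenance="from X,y")


class MultinomialLogit:
    """Plain multinomial logit classifier over the four severity levels.

    sklearn-compatible: ``fit(X, y)`` with X a DataFrame of 0/1 indicators
    and y severity labels; fitted attributes carry a trailing underscore.
    """

    def __init__(self, spec: SeveritySpec | None = None, gtol: float = DEFAULT_GTOL,
                 maxiter: int = DEFAULT_MAXITER):
        self.spec = spec
        self.gtol = gtol
        self.maxiter = maxiter

    # minimal get_params/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names()}

    def set_params(self, **kwargs):
        valid = self._param_names()
        for k, v in kwargs.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self

    @classmethod
    def _param_names(cls):
        import inspect

        return [p for p in inspect.signature(cls.__init__).parameters if p != "self"]

    def _check_spec(self):
        if self.spec is None:
            raise ValueError("a SeveritySpec must be supplied")
        return self.spec

    def fit(self, X: pd.DataFrame, y):
        spec = self._check_spec()
        ds = _dataset_from_xy(X, y)
        design = build_design(ds, spec)
        self.result_ = fit_mnl(design, gtol=self.gtol, maxiter=self.maxiter)
        self._copy_result_attrs()
        return self

    def _copy_result_attrs(self):
        r = self.result_
        self.params_ = r.params
        self.std_errors_ = r.std_errors
        self.t_stats_ = r.t_stats
        self.ll_zero_ = r.ll_zero
        self.ll_convergence_ = r.ll_convergence
        self.rho2_ = r.rho2
        self.n_obs_ = r.n_obs
        self.n_params_ = r.n_params
        self.converged_ = r.converged
        self.classes_ = np.asarray(r.spec.alternatives, dtype=object)

    def _prediction_design(self, X: pd.DataFrame) -> ModelDesign:
        dummy = np.full(len(X), self.result_.spec.base_alternative, dtype=object)
        return build_design(_dataset_from_xy(X, dummy), self.result_.spec,
                            check_identification=False)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design = self._prediction_design(X)
        return simulated_probabilities(self.result_.vector, design, self._draws_for(len(X)))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X: pd.DataFrame, y) -> float:
        """Mean per-record log-likelihood on (X, y)."""
        design = build_design(_dataset_from_xy(X, y), self.result_.spec)
        return simulated_log_likelihood(self.result_.vector, design, self._draws_for(len(X))) / len(X)

    def _draws_for(self, n_records: int) -> DrawSet | None:
        return None


class MixedLogit(MultinomialLogit):
    """Random-parameters logit with heterogeneity in means and variances,
    estimated by simulated maximum likelihood over Halton draws."""

    def __init__(
        self,
        spec: SeveritySpec | None = None,
        n_draws: int = DEFAULT_N_DRAWS,
        skip: int = DEFAULT_SKIP,
        scramble: bool = False,
        gtol: float = DEFAULT_GTOL,
        maxiter: int = DEFAULT_MAXITER,
        sigma_start: float = 0.1,
        n_restarts: int = 0,
        restart_scale: float = 0.25,
        random_state: int = 0,
    ):
        self.spec = spec
        self.n_draws = n_draws
        self.skip = skip
        self.scramble = scramble
        self.gtol = gtol
        self.maxiter = maxiter
        self.sigma_start = sigma_start
        self.n_restarts = n_restarts
        self.restart_scale = restart_scale
        self.random_state = random_state

    def _draws_for(self, n_records: int) -> DrawSet | None:
        rt = [t.variable for t in self.result_.spec.random_terms]
        if not rt:
            return None
        return make_draws(n_records, rt, self.n_draws, self.skip,
                          scramble=self.scramble, scramble_seed=self.random_state)

    def fit(self, X: pd.DataFrame, y):
        spec = self._check_spec()
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        ds = _dataset_from_xy(X, y)
        design = build_design(ds, spec)
        rt = [t.variable for t in spec.random_terms]
        draws = (
            make_draws(len(X), rt, self.n_draws, self.skip,
                       scramble=self.scramble, scramble_seed=self.random_state)
            if rt else None
        )
        if rt:
            self.result_ = fit_mixed_logit(
                design, draws, gtol=self.gtol, maxiter=self.maxiter,
                sigma_start=self.sigma_start, n_restarts=self.n_restarts,
                restart_scale=self.restart_scale, restart_seed=self.random_state,
            )
        else:
            self.result_ = fit_mnl(design, gtol=self.gtol, maxiter=self.maxiter)
        self._copy_result_attrs()
        self.n_draws_used_ = self.result_.n_draws
        return self


def fit_dataset(
    ds: CrashDataset,
    spec: SeveritySpec,
    n_draws: int = DEFAULT_N_DRAWS,
    skip: int = DEFAULT_SKIP,
    **kwargs,
) -> EstimationResult:
    """One-call fit of a spec on a CrashDataset (mixed if the spec has random terms)."""
    design = build_design(ds, spec)
    rt = [t.variable for t in spec.random_terms]
    if not rt:
        return fit_mnl(design, **kwargs)
    draws = make_draws(ds.n_obs, rt, n_draws, skip)
    return fit_mixed_logit(design, draws, **kwargs)
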