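"""Numeric design structures binding a dataset to a model specification.

``build_design`` validates that every variable the spec references exists
and varies in the data, extracts the covariate vectors each term needs, and
fixes a stable flat ordering of the parameter vector:

    constants (spec order), betas (term order),
    thetas (random-term order, Z order within), sigmas, omegas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CrashDataset
from .spec import ParameterSet, SeveritySpec, Term, count_parameters


@dataclass
class _TermData:
    term: Term
    alt_index: int
    x: np.ndarray                 # (N,) 0/1 covariate of the term
    Z: np.ndarray | None = None   # (N, nZ) heterogeneity-in-mean covariates
    W: np.ndarray | None = None   # (N, nW) heterogeneity-in-variance covariates


@dataclass
class ModelDesign:
    """Everything the likelihood needs: data arrays plus the parameter index map."""

    spec: SeveritySpec
    y: np.ndarray                       # (N,) chosen-alternative index
    alternatives: tuple[str, ...]
    const_alt_indices: list[int]
    terms: list[_TermData]
    param_names: list[str]
    n_obs: int
    n_params: int
    # index ranges into the flat vector
    sl_constants: slice = field(default_factory=lambda: slice(0, 0))
    sl_beta: slice = field(default_factory=lambda: slice(0, 0))
    theta_index: dict = field(default_factory=dict)   # (var, zvar) -> flat index
    sigma_index: dict = field(default_factory=dict)   # var -> flat index
    omega_index: dict = field(default_factory=dict)   # (var, wvar) -> flat index

    @property
    def random_terms(self) -> list[_TermData]:
        return [t for t in self.terms if t.term.role == "random"]

    def flatten(self, params: ParameterSet) -> np.ndarray:
        v = np.zeros(self.n_params)
        for i, a in enumerate(self.spec.constants):
            v[self.sl_constants.start + i] = params.constants.get(a, 0.0)
        for i, td in enumerate(self.terms):
            v[self.sl_beta.start + i] = params.beta.get(td.term.variable, 0.0)
        for key, idx in self.theta_index.items():
            v[idx] = params.theta.get(key, 0.0)
        for var, idx in self.sigma_index.items():
            v[idx] = params.sigma.get(var, 0.0)
        for key, idx in self.omega_index.items():
            v[idx] = params.omega.get(key, 0.0)
        return v

    def unflatten(self, v: np.ndarray) -> ParameterSet:
        v = np.asarray(v, dtype=float)
        ps = ParameterSet()
        for i, a in enumerate(self.spec.constants):
            ps.constants[a] = float(v[self.sl_constants.start + i])
        for i, td in enumerate(self.terms):
            ps.beta[td.term.variable] = float(v[self.sl_beta.start + i])
        for key, idx in self.theta_index.items():
            ps.theta[key] = float(v[idx])
        for var, idx in self.sigma_index.items():
            ps.sigma[var] = float(v[idx])
        for key, idx in self.omega_index.items():
            ps.omega[key] = float(v[idx])
        return ps


def build_design(
    ds: CrashDataset, spec: SeveritySpec, check_identification: bool = True
) -> ModelDesign:
    """Bind a validated dataset to a spec, producing the estimator's design.

    Raises if a spec variable is absent from the data or — when
    ``check_identification`` (fit-time default) — constant within it: a
    constant indicator is collinear with the alternative-specific constant
    and therefore non-identifiable.  Evaluation-only designs (prediction,
    marginal-effect scenarios, transfer of converged parameters) disable
    the constancy check since no parameters are estimated there.
    """
    alts = tuple(spec.alternatives)
    alt_idx = {a: i for i, a in enumerate(alts)}
    needed = {t.variable for t in spec.terms}
    for t in spec.random_terms:
        needed.update(t.het_mean_covariates)
        needed.update(t.het_variance_covariates)
    missing = sorted(needed - set(ds.variables))
    if missing:
        raise ValueError(f"spec references variables absent from the dataset: {missing}")

    X = ds.covariates()
    if check_identification:
        for t in spec.terms:
            if X[t.variable].nunique() < 2:
                raise ValueError(
                    f"non-identifiable term: variable {t.variable!r} is constant in the data"
                )

    y = np.array([alt_idx[o] for o in ds.outcomes()], dtype=np.intp)

    term_data: list[_TermData] = []
    for t in spec.terms:
        td = _TermData(term=t, alt_index=alt_idx[t.target], x=X[t.variable].to_numpy(float))
        if t.role == "random":
            td.Z = (
                X[list(t.het_mean_covariates)].to_numpy(float)
                if t.het_mean_covariates else np.zeros((ds.n_obs, 0))
            )
            td.W = (
                X[list(t.het_variance_covariates)].to_numpy(float)
                if t.het_variance_covariates else np.zeros((ds.n_obs, 0))
            )
        term_data.append(td)

    names: list[str] = [f"const[{a}]" for a in spec.constants]
    sl_constants = slice(0, len(names))
    beta_start = len(names)
    names += [f"beta[{t.variable}:{t.target}]" for t in spec.terms]
    sl_beta = slice(beta_start, len(names))
    theta_index, sigma_index, omega_index = {}, {}, {}
    for t in spec.random_terms:
        for z in t.het_mean_covariates:
            theta_index[(t.variable, z)] = len(names)
            names.append(f"theta[{t.variable}|{z}]")
    for t in spec.random_terms:
        sigma_index[t.variable] = len(names)
        names.append(f"sigma[{t.variable}]")
    for t in spec.random_terms:
        for w in t.het_variance_covariates:
            omega_index[(t.variable, w)] = len(names)
            names.append(f"omega[{t.variable}|{w}]")

    n_params = len(names)
    assert n_params == count_parameters(spec)

    return ModelDesign(
        spec=spec,
        y=y,
        alternatives=alts,
        const_alt_indices=[alt_idx[a] for a in spec.constants],
        terms=term_data,
        param_names=names,
        n_obs=ds.n_obs,
        n_params=n_params,
        sl_constants=sl_constants,
        sl_beta=sl_beta,
        theta_index=theta_index,
        sigma_index=sigma_index,
        omega_index=omega_index,
    )
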