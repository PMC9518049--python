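"""Publication-style table rendering for fitted models and test results.

Severity functions are tagged [NI]/[MI]/[SI]/[FI] (no/minor/severe/fatal
injury) next to each variable, matching the convention of injury-severity
modelling papers.
"""

from __future__ import annotations

import pandas as pd

from .effects import marginal_effects_comparison  # re-exported convenience
from .estimation import EstimationResult

__all__ = [
    "estimation_table",
    "render_estimation_report",
    "render_marginal_comparison",
    "marginal_effects_comparison",
]


def estimation_table(result: EstimationResult) -> pd.DataFrame:
    """Flat estimate/t-statistic table with severity tags and parameter kinds."""
    p, t = result.params, result.t_stats
    spec = result.spec
    rows = []
    for a in spec.constants:
        rows.append(("constant", f"Constant [{a}]", p.constants[a], t.constants[a]))
    for term in spec.random_terms:
        v = term.variable
        rows.append(("random mean", f"{v} [{term.target}]", p.beta[v], t.beta[v]))
        for z in term.het_mean_covariates:
            rows.append(("het. in mean", f"{v} : {z}", p.theta[(v, z)], t.theta[(v, z)]))
        rows.append(("random sd", f"{v} (sd)", p.sigma[v], t.sigma[v]))
        for w in term.het_variance_covariates:
            rows.append(("het. in variance", f"{v} : {w}", p.omega[(v, w)], t.omega[(v, w)]))
    for term in spec.fixed_terms:
        v = term.variable
        rows.append(("fixed", f"{v} [{term.target}]", p.beta[v], t.beta[v]))
    return pd.DataFrame(rows, columns=["kind", "parameter", "estimate", "t_stat"])


def render_estimation_report(result: EstimationResult, title: str = "Model estimation results") -> str:
    table = estimation_table(result)
    lines = [
        title,
        "=" * len(title),
        table.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
        "",
        f"Number of observations        {result.n_obs}",
        f"Number of parameters          {result.n_params}",
        f"Log-likelihood at zero        {result.ll_zero:.3f}",
        f"Log-likelihood at convergence {result.ll_convergence:.3f}",
        f"rho^2 = 1 - LL(beta)/LL(0)    {result.rho2:.3f}",
        f"Simulation draws              {result.n_draws} (Halton, skip {result.skip})",
        f"Converged                     {result.converged}",
        "Standard errors: inverse numerical Hessian of the simulated log-likelihood.",
    ]
    return "\n".join(lines)


def render_marginal_comparison(
    long_df: pd.DataFrame,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Wide marginal-effects comparison: rows variables, columns severity x period.

    With two groups, the second group's value is parenthesised next to the
    first's in the same cell; a variable absent from a model renders blank.
    """
    if groups is None:
        found = list(pd.unique(long_df["group"]))
        groups = tuple(found[:2]) if len(found) >= 2 else (found[0],)
    severities = [s for s in ("NI", "MI", "SI", "FI") if s in set(long_df["severity"])]
    periods = sorted(pd.unique(long_df["period"]))
    variables = sorted(pd.unique(long_df["variable"]))

    def lookup(var, sev, per, grp):
        m = long_df[
            (long_df["variable"] == var)
            & (long_df["severity"] == sev)
            & (long_df["period"] == per)
            & (long_df["group"] == grp)
        ]
        return None if m.empty else float(m["effect"].iloc[0])

    cols = pd.MultiIndex.from_product([severities, periods], names=["severity", "period"])
    out = pd.DataFrame("", index=variables, columns=cols)
    out.index.name = "variable"
    for var in variables:
        for sev in severities:
            for per in periods:
                a = lookup(var, sev, per, groups[0])
                b = lookup(var, sev, per, groups[1]) if len(groups) > 1 else None
                cell = "" if a is None else f"{a:.4f}"
                if b is not None:
                    cell = f"{cell} ({b:.4f})" if cell else f"({b:.4f})"
                out.loc[var, (sev, per)] = cell
    return out
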