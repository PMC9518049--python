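"""Marginal effects of indicator variables on severity probabilities.

For an indicator the marginal effect on outcome i is the change in the
(simulated) probability of i when the indicator is switched from 0 to 1,
averaged over all records in the estimation sample.  The switch is
propagated through every pathway the variable has into the model: its own
term's utility and any appearance in a random coefficient's
heterogeneity-in-mean (Z) or heterogeneity-in-variance (W) lists.  The same
draw set is used in both scenarios, so the four per-alternative effects of
any variable sum to zero exactly (probabilities sum to one in both
scenarios).
"""

from __future__ import annotations

import pandas as pd

from .data import CrashDataset
from .design import build_design
from .draws import DrawSet, make_draws
from .estimation import EstimationResult
from .likelihood import simulated_probabilities


def _pathway_variables(result: EstimationResult) -> set[str]:
    spec = result.spec
    vars_ = {t.variable for t in spec.terms}
    for t in spec.random_terms:
        vars_.update(t.het_mean_covariates)
        vars_.update(t.het_variance_covariates)
    return vars_


def _draws_for(result: EstimationResult, n_records: int) -> DrawSet | None:
    rt = [t.variable for t in result.spec.random_terms]
    if not rt or result.n_draws < 1:
        return None
    return make_draws(n_records, rt, result.n_draws, result.skip)


def _scenario_probs(result, ds: CrashDataset, variable: str, value: int, draws):
    df = ds.df.copy()
    df[variable] = value
    scenario = CrashDataset(df=df, variables=list(ds.variables),
                            provenance=f"{ds.provenance} | {variable}={value}")
    design = build_design(scenario, result.spec, check_identification=False)
    return simulated_probabilities(result.vector, design, draws)


def indicator_marginal_effects(
    result: EstimationResult,
    ds: CrashDataset,
    variable: str,
    draws: DrawSet | None = None,
) -> pd.Series:
    """Sample-average effect of switching `variable` 0 -> 1, per severity level."""
    if variable not in _pathway_variables(result):
        raise ValueError(
            f"variable {variable!r} has no pathway into probabilities "
            "(not in the spec's terms or Z/W lists)"
        )
    if draws is None:
        draws = _draws_for(result, ds.n_obs)
    p1 = _scenario_probs(result, ds, variable, 1, draws)
    p0 = _scenario_probs(result, ds, variable, 0, draws)
    effects = (p1 - p0).mean(axis=0)
    return pd.Series(effects, index=list(result.spec.alternatives), name=variable)


def marginal_effects_table(
    result: EstimationResult,
    ds: CrashDataset,
    draws: DrawSet | None = None,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Marginal effects of every model variable; rows variables, columns severities."""
    if variables is None:
        variables = sorted(_pathway_variables(result))
    if draws is None:
        draws = _draws_for(result, ds.n_obs)
    rows = [indicator_marginal_effects(result, ds, v, draws) for v in variables]
    return pd.DataFrame(rows)


def marginal_effects_comparison(
    results: dict,
    datasets: dict,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format comparison of marginal effects across (group, period) models.

    `results` and `datasets` are keyed by (group, period).  A variable absent
    from a model's spec simply has no rows for that model, which renders as a
    blank cell in the wide layout.
    """
    if not results:
        raise ValueError("at least one result is required")
    frames = []
    for key, result in results.items():
        group, period = key
        ds = datasets[key]
        model_vars = sorted(_pathway_variables(result))
        if variables is not None:
            model_vars = [v for v in model_vars if v in variables]
        table = marginal_effects_table(result, ds, variables=model_vars)
        long = table.reset_index(names="variable").melt(
            id_vars="variable", var_name="severity", value_name="effect"
        )
        long["group"] = group
        long["period"] = period
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out[["variable", "severity", "period", "group", "effect"]]
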