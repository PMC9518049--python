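"""Likelihood-ratio machinery for temporal instability and transferability.

Two tests are provided.

Global instability: with period-specific models and one pooled model of the
same rider group,

    chi2 = -2 [ LL(pooled) - sum_t LL(period t) ]

is chi-square distributed with degrees of freedom equal to the summed
period parameter counts minus the pooled parameter count.  Rejection means
the period models jointly fit better than a single set of parameters: the
parameters are temporally unstable.

Pairwise transferability (default "restricted-evaluation" reading): take
the converged parameters of period t2's model, evaluate their (simulated)
log-likelihood on period t1's data with the parameters held fixed, giving
LL(beta_t2|t1); then

    chi2 = -2 [ LL(beta_t2|t1) - LL(beta_t1) ],    dof = n_params(t2).

When the two periods share a specification this is a restricted-vs-free
comparison on the same data, so the statistic is non-negative by
construction and exactly zero for self-transfer.  The alternative
"respecify-refit" mode refits t2's specification freely on t1's data; it
compares specifications rather than parameter values and can go negative,
so it warns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .data import CrashDataset
from .design import build_design
from .draws import make_draws
from .estimation import EstimationResult, fit_mixed_logit, fit_mnl
from .likelihood import simulated_log_likelihood


def critical_chi_square(confidence: float, dof: int) -> float:
    """Upper-tail chi-square quantile: reject equality when the statistic exceeds it."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return float(chi2_dist.ppf(confidence, dof))


def chi_square_confidence(stat: float, dof: int) -> float:
    """The confidence level at which `stat` rejects equality (chi-square CDF)."""
    if stat < 0:
        raise ValueError("statistic must be >= 0")
    return float(chi2_dist.cdf(stat, dof))


@dataclass
class InstabilityTestResult:
    chi2: float
    dof: int
    confidence: float               # configured test level
    critical_value: float
    decision: str                   # "reject-equality" | "fail-to-reject"
    achieved_confidence: float = 0.0  # chi-square CDF of the statistic
    direction: tuple | None = None  # (t1, t2) for pairwise tests
    warning: str | None = None

    def render(self) -> str:
        """Publication-style cell: "value (dof) [>99%]"."""
        conf = self.achieved_confidence
        tag = ">99%" if conf >= 0.99 else f"{conf * 100:.0f}%"
        return f"{self.chi2:.3f} ({self.dof}) [{tag}]"


_CELL_RE = re.compile(r"^\s*([-\d.]+)\s*\((\d+)\)\s*\[>?(\d+(?:\.\d+)?)%\]\s*$")


def parse_rendered_cell(text: str) -> tuple[float, int, float]:
    """Inverse of :meth:`InstabilityTestResult.render` (value, dof, confidence)."""
    m = _CELL_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse instability cell {text!r}")
    return float(m.group(1)), int(m.group(2)), float(m.group(3)) / 100.0


def _decide(chi2: float, dof: int, confidence: float, direction=None, warning=None):
    crit = critical_chi_square(confidence, dof)
    return InstabilityTestResult(
        chi2=chi2,
        dof=dof,
        confidence=confidence,
        critical_value=crit,
        decision="reject-equality" if chi2 > crit else "fail-to-reject",
        achieved_confidence=chi_square_confidence(max(chi2, 0.0), dof),
        direction=direction,
        warning=warning,
    )


def global_instability_test(
    ll_pooled: float,
    ll_periods: list[float],
    params_pooled: int,
    params_periods: list[int],
    confidence: float = 0.99,
) -> InstabilityTestResult:
    """Multi-period likelihood-ratio test of parameter equality over time."""
    if len(ll_periods) < 2:
        raise ValueError("need at least two periods")
    if params_pooled < 1 or any(p < 1 for p in params_periods):
        raise ValueError("parameter counts must be positive")
    chi2 = -2.0 * (ll_pooled - sum(ll_periods))
    dof = sum(params_periods) - params_pooled
    if dof < 1:
        raise ValueError(f"degrees of freedom {dof} < 1; check parameter counts")
    warning = None
    if chi2 < 0:
        warning = (
            "negative statistic: the pooled model fits better than the period "
            "models combined, which indicates a mis-converged pooled model"
        )
    return _decide(chi2, dof, confidence, warning=warning)


def transferability_test(
    result_t2: EstimationResult,
    data_t1: CrashDataset,
    result_t1: EstimationResult,
    confidence: float = 0.99,
    mode: str = "restricted-evaluation",
    direction: tuple | None = None,
) -> InstabilityTestResult:
    """Can period t2's converged parameters explain period t1's data?"""
    spec = result_t2.spec
    design = build_design(data_t1, spec,
                          check_identification=(mode == "respecify-refit"))
    rt = [t.variable for t in spec.random_terms]
    draws = (
        make_draws(data_t1.n_obs, rt, result_t2.n_draws, result_t2.skip)
        if rt and result_t2.n_draws >= 1 else None
    )
    warning = None
    if mode == "restricted-evaluation":
        ll_t2t1 = simulated_log_likelihood(result_t2.vector, design, draws)
    elif mode == "respecify-refit":
        refit = (
            fit_mixed_logit(design, draws, std_errors=False)
            if draws is not None else fit_mnl(design, std_errors=False)
        )
        ll_t2t1 = refit.ll_convergence
        warning = "respecify-refit mode compares specifications; negative statistics possible"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    chi2 = -2.0 * (ll_t2t1 - result_t1.ll_convergence)
    if mode == "restricted-evaluation" and chi2 < -1e-8:
        raise RuntimeError(
            "transferability statistic is negative in restricted-evaluation mode "
            f"(chi2={chi2:.6g}): the transferred parameters fit the target data "
            "better than its own converged model, which violates nesting — the "
            "target-period model is likely mis-converged "
            f"(LL(beta_t2|t1)={ll_t2t1:.6f}, LL(beta_t1)={result_t1.ll_convergence:.6f})"
        )
    chi2 = max(chi2, 0.0) + 0.0  # normalise -0.0
    return _decide(chi2, result_t2.n_params, confidence, direction=direction, warning=warning)


def instability_matrix(
    results: dict,
    datasets: dict,
    confidence: float = 0.99,
    mode: str = "restricted-evaluation",
) -> dict:
    """Both-direction transferability tests for every ordered period pair.

    Returns {(t1, t2): InstabilityTestResult} for t1 != t2, where the cell
    applies t2's converged parameters to t1's data.
    """
    if set(results) != set(datasets):
        raise ValueError("results and datasets must share the same period keys")
    out = {}
    for t1 in results:
        for t2 in results:
            if t1 == t2:
                continue
            out[(t1, t2)] = transferability_test(
                results[t2], datasets[t1], results[t1],
                confidence=confidence, mode=mode, direction=(t1, t2),
            )
    return out


def render_instability_matrix(matrix: dict) -> pd.DataFrame:
    """Wide text table: rows t1, columns t2, cells "value (dof) [>99%]"."""
    periods = sorted({t for pair in matrix for t in pair})
    table = pd.DataFrame("-", index=periods, columns=periods)
    table.index.name = "t1"
    table.columns.name = "t2"
    for (t1, t2), res in matrix.items():
        table.loc[t1, t2] = res.render()
    return table


def global_test_summary(
    label_to_inputs: dict,
    confidence: float = 0.99,
) -> pd.DataFrame:
    """Table-style summary of global instability tests for several groups.

    `label_to_inputs` maps a column label to a dict with keys
    ``ll_pooled``, ``ll_periods`` (mapping period -> LL), ``params_pooled``,
    ``params_periods`` (mapping period -> count).
    """
    cols = {}
    for label, d in label_to_inputs.items():
        periods = sorted(d["ll_periods"])
        res = global_instability_test(
            d["ll_pooled"],
            [d["ll_periods"][p] for p in periods],
            d["params_pooled"],
            [d["params_periods"][p] for p in periods],
            confidence=confidence,
        )
        rows = {"LL(pooled)": round(d["ll_pooled"], 3)}
        for p in periods:
            rows[f"LL({p})"] = round(d["ll_periods"][p], 3)
        rows["chi2"] = round(res.chi2, 2)
        rows["dof"] = res.dof
        rows["confidence"] = f"{confidence * 100:.0f}%"
        rows[f"critical chi2 ({confidence * 100:.0f}%)"] = round(res.critical_value, 2)
        rows["conclusion"] = (
            "temporally unstable" if res.decision == "reject-equality" else "stable"
        )
        cols[label] = rows
    return pd.DataFrame(cols)
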