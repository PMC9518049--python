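"""Simulation studies validating the estimator and the instability tests.

These are first-class package functionality (the real registry is not
public, so simulation is the only way to demonstrate that the estimator
recovers known truth and that the likelihood-ratio machinery has the right
size and power), shared by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import build_design
from .draws import make_draws
from .estimation import fit_mixed_logit, fit_mnl
from .spec import ParameterSet, SeveritySpec, Term
from .simulate import (
    DEFAULT_PREVALENCES,
    GeneratorConfig,
    default_spec,
    default_truth,
    generate_dataset,
    generate_study_like,
)
from .stability import (
    global_instability_test,
    instability_matrix,
    transferability_test,
)
from .data import split_dataset


@dataclass
class RecoveryStudyResult:
    """Per-replication estimates/SEs for the random term's beta, Theta, sigma, omega."""

    truth: dict
    estimates: list = field(default_factory=list)   # list of {name: (est, se)}
    n_reps: int = 0

    def within_counts(self, k_se: float = 3.0) -> dict:
        """How many replications put each parameter within k_se SEs of truth."""
        counts = {name: 0 for name in self.truth}
        for rep in self.estimates:
            for name, (est, se) in rep.items():
                if np.isfinite(se) and abs(est - self.truth[name]) <= k_se * se:
                    counts[name] += 1
        return counts


def parameter_recovery_study(
    n_reps: int = 20,
    n_obs: int = 4000,
    n_draws: int = 500,
    seed: int = 0,
    spec: SeveritySpec | None = None,
    truth: ParameterSet | None = None,
) -> RecoveryStudyResult:
    """Repeatedly simulate from known truth and refit the mixed logit.

    Monitors the four parameter classes of the random coefficient: its mean
    beta, heterogeneity-in-mean Theta, scale sigma, and
    heterogeneity-in-variance omega.  Draws are reused across replications
    (they depend only on the record count, not the data).
    """
    spec = spec or default_spec()
    truth = truth or default_truth()
    rterm = spec.random_terms[0]
    zvar = rterm.het_mean_covariates[0]
    wvar = rterm.het_variance_covariates[0]
    truth_map = {
        "beta": truth.beta[rterm.variable],
        "theta": truth.theta[(rterm.variable, zvar)],
        "sigma": abs(truth.sigma[rterm.variable]),
        "omega": truth.omega[(rterm.variable, wvar)],
    }
    out = RecoveryStudyResult(truth=truth_map, n_reps=n_reps)
    draws = make_draws(n_obs, [t.variable for t in spec.random_terms], n_draws)
    for rep in range(n_reps):
        cfg = GeneratorConfig(n_obs=n_obs, truth=truth, spec=spec, seed=seed + 1000 * rep)
        ds = generate_dataset(cfg)
        design = build_design(ds, spec)
        result = fit_mixed_logit(design, draws)
        p, s = result.params, result.std_errors
        out.estimates.append(
            {
                "beta": (p.beta[rterm.variable], s.beta[rterm.variable]),
                "theta": (p.theta[(rterm.variable, zvar)], s.theta[(rterm.variable, zvar)]),
                "sigma": (p.sigma[rterm.variable], s.sigma[rterm.variable]),
                "omega": (p.omega[(rterm.variable, wvar)], s.omega[(rterm.variable, wvar)]),
            }
        )
    return out


def fixed_effects_spec() -> SeveritySpec:
    """A fixed-coefficient specification for instability simulations."""
    return SeveritySpec(
        constants=["MI", "SI", "FI"],
        terms=[
            Term("male", "MI"),
            Term("below_20", "SI"),
            Term("distraction", "MI"),
            Term("over_speeding", "FI"),
            Term("large_truck", "SI"),
        ],
    )


def fixed_effects_truth() -> ParameterSet:
    return ParameterSet(
        constants={"MI": 1.0, "SI": 0.6, "FI": -0.3},
        beta={"male": 1.2, "below_20": 0.75, "distraction": -1.0,
              "over_speeding": -1.2, "large_truck": 0.8},
    )


@dataclass
class InstabilityStudyResult:
    rejections: int
    n_reps: int
    chi2_values: list
    pairwise_min_chi2: float = np.inf
    self_transfer_chi2: float = np.nan

    @property
    def rejection_rate(self) -> float:
        return self.rejections / self.n_reps


def instability_study(
    n_reps: int = 20,
    period_sizes: dict | None = None,
    shift: dict | None = None,
    seed: int = 0,
    confidence: float = 0.99,
    spec: SeveritySpec | None = None,
    truth: ParameterSet | None = None,
    run_pairwise_on_first: bool = False,
) -> InstabilityStudyResult:
    """Size/power study of the global instability test on synthetic 3-period data.

    With ``shift=None`` all periods share the truth (size: rejections should
    be rare); a shift like ``{"beta": {"male": 2.2}}`` applied to the last
    period creates genuine instability (power: rejections should dominate).
    Period models and the pooled model share one specification, so the
    degrees of freedom are (P-1) * n_params for P periods.
    """
    spec = spec or fixed_effects_spec()
    truth = truth or fixed_effects_truth()
    period_sizes = period_sizes or {"2017": 2045, "2018": 2095, "2019": 2262}
    periods = sorted(period_sizes)
    rejections = 0
    chi2_values = []
    pairwise_min = np.inf
    self_chi2 = np.nan
    for rep in range(n_reps):
        profiles = {p: (period_sizes[p], None) for p in periods}
        if shift is not None:
            profiles[periods[-1]] = (period_sizes[periods[-1]], shift)
        cfg = GeneratorConfig(
            truth=truth, spec=spec, seed=seed + 7919 * rep, period_profiles=profiles,
        )
        study = generate_study_like(cfg)
        parts = split_dataset(study, by="period")
        fits = {p: fit_mnl(build_design(parts[p], spec), std_errors=False) for p in periods}
        pooled = fit_mnl(build_design(study, spec), std_errors=False)
        res = global_instability_test(
            pooled.ll_convergence,
            [fits[p].ll_convergence for p in periods],
            pooled.n_params,
            [fits[p].n_params for p in periods],
            confidence=confidence,
        )
        chi2_values.append(res.chi2)
        if res.decision == "reject-equality":
            rejections += 1
        if run_pairwise_on_first and rep == 0:
            matrix = instability_matrix(fits, parts, confidence=confidence)
            pairwise_min = min(r.chi2 for r in matrix.values())
            self_res = transferability_test(
                fits[periods[0]], parts[periods[0]], fits[periods[0]],
                confidence=confidence,
            )
            self_chi2 = self_res.chi2
    return InstabilityStudyResult(
        rejections=rejections,
        n_reps=n_reps,
        chi2_values=chi2_values,
        pairwise_min_chi2=pairwise_min,
        self_transfer_chi2=self_chi2,
    )
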