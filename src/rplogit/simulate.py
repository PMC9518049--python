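"""Synthetic crash-data generator.

The real emergency-service crash registry behind this kind of analysis is
not publicly deposited, so the generator produces datasets with exactly the
statistical structure the estimator assumes: independent Bernoulli
indicator covariates at realistic prevalences, and a four-alternative logit
outcome process with alternative-specific constants, fixed coefficients,
and a normally distributed random coefficient whose mean shifts with Z
covariates and whose standard deviation scales multiplicatively with W
covariates.  Outcomes are drawn by adding independent Gumbel(0,1) noise to
each alternative's systematic utility and taking the argmax, which is
distributionally identical to sampling from the softmax probabilities.

Covariates are generated independently; real indicators (road class, speed
limit, ...) are correlated, so parameter-recovery results here speak to the
estimator, not to any real-world identification problem.  An optional
Gaussian-copula mode introduces exchangeable pairwise correlation for
stress tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri

from .data import CrashDataset
from .spec import ParameterSet, SeveritySpec, Term

#: Indicator prevalences patterned on an urban motorcycle-crash registry
#: (roadway class, violations, rider age bands, collision partners).
DEFAULT_PREVALENCES: dict[str, float] = {
    "major_arterial": 0.597,
    "lane2": 0.212,
    "collector_road": 0.142,
    "below_20": 0.208,
    "between_20_30": 0.354,
    "male": 0.877,
    "large_truck": 0.059,
    "passenger_car": 0.165,
    "distraction": 0.272,
    "over_speeding": 0.690,
    "u_turn": 0.030,
    "weekday": 0.711,
}


def default_spec() -> SeveritySpec:
    """Smallest spec with the full random-parameter structure: three
    constants, six fixed terms, and one random term with one Z and one W."""
    return SeveritySpec(
        constants=["MI", "SI", "FI"],
        base_alternative="NI",
        terms=[
            Term("major_arterial", "FI", role="random",
                 het_mean_covariates=("large_truck",),
                 het_variance_covariates=("between_20_30",)),
            Term("lane2", "MI"),
            Term("male", "MI"),
            Term("below_20", "SI"),
            Term("distraction", "MI"),
            Term("over_speeding", "FI"),
            Term("u_turn", "FI"),
        ],
    )


def default_truth() -> ParameterSet:
    """Ground-truth parameters for the default spec (moderate, recoverable)."""
    return ParameterSet(
        constants={"MI": 1.0, "SI": 0.6, "FI": -0.3},
        beta={
            "major_arterial": 0.5,
            "lane2": -0.8,
            "male": 1.2,
            "below_20": 0.75,
            "distraction": -1.0,
            "over_speeding": -1.2,
            "u_turn": -1.5,
        },
        theta={("major_arterial", "large_truck"): -0.8},
        sigma={"major_arterial": 2.0},
        omega={("major_arterial", "between_20_30"): 0.6},
    )


@dataclass
class GeneratorConfig:
    n_obs: int = 2000
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    truth: ParameterSet = field(default_factory=default_truth)
    spec: SeveritySpec = field(default_factory=default_spec)
    seed: int = 0
    group: str = "helmet"
    period: str = "2017"
    #: period -> (n_obs, truth-override dict); enables known-instability studies
    period_profiles: dict | None = None
    correlation: float = 0.0  # exchangeable Gaussian-copula correlation

    def __post_init__(self):
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        for var, p in self.prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {var!r} must be in (0, 1), got {p}")

    def provenance(self) -> str:
        return f"synthetic(seed={self.seed}, n_obs={self.n_obs})"


def generate_covariates(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Seeded Bernoulli indicator block, one column per variable."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_obs
    cols = {}
    if config.correlation > 0.0:
        r = config.correlation
        common = rng.standard_normal(n)
        for var, p in config.prevalences.items():
            z = np.sqrt(r) * common + np.sqrt(1 - r) * rng.standard_normal(n)
            cols[var] = (z < ndtri(p)).astype(int)
    else:
        for var, p in config.prevalences.items():
            cols[var] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(cols)


def simulate_outcomes(
    covariates: pd.DataFrame,
    truth: ParameterSet,
    spec: SeveritySpec,
    seed: int | np.random.Generator = 0,
    period: str = "2017",
    group: str = "helmet",
) -> CrashDataset:
    """Draw severity outcomes from the random-parameters logit process.

    Per record: standard-normal nu for each random term, coefficients
    beta + Theta.Z + sigma*exp(omega.W)*nu, systematic utilities, plus
    independent Gumbel(0,1) noise per alternative; the argmax is the outcome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(covariates)
    alts = list(spec.alternatives)
    A = len(alts)
    alt_idx = {a: i for i, a in enumerate(alts)}

    X = {v: covariates[v].to_numpy(float) for v in covariates.columns}
    V = np.zeros((n, A))
    for a, c in truth.constants.items():
        V[:, alt_idx[a]] += c

    nu = {t.variable: rng.standard_normal(n) for t in spec.random_terms}
    for t in spec.terms:
        b = np.full(n, truth.beta[t.variable])
        if t.role == "random":
            for z in t.het_mean_covariates:
                b = b + truth.theta[(t.variable, z)] * X[z]
            ww = np.zeros(n)
            for w in t.het_variance_covariates:
                ww += truth.omega[(t.variable, w)] * X[w]
            b = b + truth.sigma[t.variable] * np.exp(ww) * nu[t.variable]
        V[:, alt_idx[t.target]] += b * X[t.variable]

    gumbel = rng.gumbel(size=(n, A))
    chosen = (V + gumbel).argmax(axis=1)

    df = covariates.copy()
    df["outcome"] = np.array(alts, dtype=object)[chosen]
    df["period"] = period
    df["group"] = group
    return CrashDataset(
        df=df,
        variables=list(covariates.columns),
        provenance=f"simulate_outcomes(n={n})",
    )


def _override_truth(truth: ParameterSet, overrides: dict | None) -> ParameterSet:
    """Apply {'beta': {...}, 'constants': {...}, ...} overrides to a copy of truth."""
    new = ParameterSet(
        constants=dict(truth.constants),
        beta=dict(truth.beta),
        theta=dict(truth.theta),
        sigma=dict(truth.sigma),
        omega=dict(truth.omega),
    )
    for block, vals in (overrides or {}).items():
        target = getattr(new, block)
        for k, v in vals.items():
            key = tuple(k) if isinstance(k, (list, tuple)) else k
            target[key] = v
    return new


def generate_dataset(config: GeneratorConfig) -> CrashDataset:
    """Single-period synthetic dataset from a config."""
    rng = np.random.default_rng(config.seed)
    cov = generate_covariates(config, rng)
    ds = simulate_outcomes(cov, config.truth, config.spec, rng,
                           period=config.period, group=config.group)
    ds.provenance = config.provenance()
    return ds


def generate_study_like(config: GeneratorConfig) -> CrashDataset:
    """Multi-period dataset: one block per period profile, concatenated.

    ``period_profiles`` maps period label -> (n_obs, truth-overrides); a
    non-empty override creates a known-instability scenario for testing the
    likelihood-ratio machinery.
    """
    if not config.period_profiles or len(config.period_profiles) < 2:
        raise ValueError("period_profiles must define at least two periods")
    rng = np.random.default_rng(config.seed)
    parts = []
    for period in sorted(config.period_profiles):
        n_obs, overrides = config.period_profiles[period]
        truth = _override_truth(config.truth, overrides)
        sub = GeneratorConfig(
            n_obs=n_obs, prevalences=config.prevalences, truth=truth,
            spec=config.spec, seed=config.seed, group=config.group,
            period=str(period), correlation=config.correlation,
        )
        cov = generate_covariates(sub, rng)
        parts.append(
            simulate_outcomes(cov, truth, config.spec, rng,
                              period=str(period), group=config.group).df
        )
    df = pd.concat(parts, ignore_index=True)
    first = parts[0]
    variables = [c for c in first.columns if c not in ("outcome", "period", "group")]
    return CrashDataset(df=df, variables=variables, provenance=config.provenance())


def write_manifest(config: GeneratorConfig, path: str | Path) -> None:
    """Sidecar JSON recording how a synthetic dataset was produced."""
    doc = {
        "n_obs": config.n_obs,
        "seed": config.seed,
        "prevalences": config.prevalences,
        "spec": config.spec.to_dict(),
        "truth": {
            "constants": config.truth.constants,
            "beta": config.truth.beta,
            "theta": {f"{k[0]}|{k[1]}": v for k, v in config.truth.theta.items()},
            "sigma": config.truth.sigma,
            "omega": {f"{k[0]}|{k[1]}": v for k, v in config.truth.omega.items()},
        },
        "period_profiles": {
            str(p): {"n_obs": n, "overrides": o is not None and o or {}}
            for p, (n, o) in (config.period_profiles or {}).items()
        },
        "correlation": config.correlation,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a generator config from YAML/JSON (spec and truth included)."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    spec = SeveritySpec.from_dict(d["spec"]) if "spec" in d else default_spec()
    truth = default_truth()
    if "truth" in d:
        t = d["truth"]
        truth = ParameterSet(
            constants=dict(t.get("constants", {})),
            beta=dict(t.get("beta", {})),
            theta={tuple(k.split("|")): v for k, v in t.get("theta", {}).items()},
            sigma=dict(t.get("sigma", {})),
            omega={tuple(k.split("|")): v for k, v in t.get("omega", {}).items()},
        )
    profiles = None
    if "period_profiles" in d:
        profiles = {
            str(p): (v["n_obs"], v.get("overrides") or None)
            for p, v in d["period_profiles"].items()
        }
    return GeneratorConfig(
        n_obs=d.get("n_obs", 2000),
        prevalences=d.get("prevalences", dict(DEFAULT_PREVALENCES)),
        truth=truth,
        spec=spec,
        seed=d.get("seed", 0),
        group=d.get("group", "helmet"),
        period=str(d.get("period", "2017")),
        period_profiles=profiles,
        correlation=d.get("correlation", 0.0),
    )
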