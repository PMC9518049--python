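"""Model specification: which variable enters which severity function.

A :class:`SeveritySpec` lists the four alternatives, the base alternative
(whose latent severity function is normalised to zero), the alternatives
carrying an alternative-specific constant, and the :class:`Term` list.
Each term attaches one variable to exactly one alternative's severity
function, either with a fixed coefficient or as a normally distributed
random coefficient

    beta_n = beta + Theta . Z_n + sigma * exp(omega . W_n) * nu_n

whose mean shifts linearly with the heterogeneity-in-mean covariates Z and
whose standard deviation scales multiplicatively (always positive) with the
heterogeneity-in-variance covariates W; nu_n is a standard-normal mixing
deviate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data import SEVERITY_LEVELS


@dataclass(frozen=True)
class Term:
    variable: str
    target: str
    role: str = "fixed"  # "fixed" | "random"
    het_mean_covariates: tuple[str, ...] = ()   # Z
    het_variance_covariates: tuple[str, ...] = ()  # W

    def __post_init__(self):
        if self.role not in ("fixed", "random"):
            raise ValueError(f"term role must be 'fixed' or 'random', got {self.role!r}")
        if self.role == "fixed" and (self.het_mean_covariates or self.het_variance_covariates):
            raise ValueError(
                f"term {self.variable!r} is fixed but has heterogeneity covariates"
            )
        object.__setattr__(self, "het_mean_covariates", tuple(self.het_mean_covariates))
        object.__setattr__(self, "het_variance_covariates", tuple(self.het_variance_covariates))


@dataclass
class SeveritySpec:
    """Specification of a four-alternative injury-severity model."""

    terms: list[Term]
    constants: list[str] = field(default_factory=lambda: ["MI", "SI", "FI"])
    base_alternative: str = "NI"
    alternatives: tuple[str, ...] = SEVERITY_LEVELS
    mixing_distribution: str = "normal"

    def __post_init__(self):
        alts = tuple(self.alternatives)
        if self.base_alternative not in alts:
            raise ValueError(f"base alternative {self.base_alternative!r} not in {alts}")
        if self.base_alternative in self.constants:
            raise ValueError("base alternative cannot carry a constant")
        for c in self.constants:
            if c not in alts:
                raise ValueError(f"constant on unknown alternative {c!r}")
        if len(set(self.constants)) != len(self.constants):
            raise ValueError("duplicate constants")
        seen = set()
        for t in self.terms:
            if t.target not in alts:
                raise ValueError(f"term {t.variable!r} targets unknown alternative {t.target!r}")
            if t.target == self.base_alternative:
                raise ValueError(
                    f"term {t.variable!r} targets the base alternative "
                    f"{self.base_alternative!r}; the base severity function is "
                    "normalised to zero (non-identifiable)"
                )
            if t.variable in seen:
                raise ValueError(f"variable {t.variable!r} enters more than one term")
            seen.add(t.variable)
        if self.mixing_distribution != "normal":
            raise NotImplementedError(
                f"mixing distribution {self.mixing_distribution!r}; only 'normal' is implemented"
            )

    @property
    def random_terms(self) -> list[Term]:
        return [t for t in self.terms if t.role == "random"]

    @property
    def fixed_terms(self) -> list[Term]:
        return [t for t in self.terms if t.role == "fixed"]

    def to_dict(self) -> dict:
        return {
            "base": self.base_alternative,
            "constants": list(self.constants),
            "mixing": self.mixing_distribution,
            "terms": [
                {
                    "variable": t.variable,
                    "target": t.target,
                    "role": t.role,
                    "Z": list(t.het_mean_covariates),
                    "W": list(t.het_variance_covariates),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeveritySpec":
        terms = [
            Term(
                variable=t["variable"],
                target=t["target"],
                role=t.get("role", "fixed"),
                het_mean_covariates=tuple(t.get("Z") or ()),
                het_variance_covariates=tuple(t.get("W") or ()),
            )
            for t in d["terms"]
        ]
        return cls(
            terms=terms,
            constants=list(d.get("constants", [])),
            base_alternative=d.get("base", "NI"),
            mixing_distribution=d.get("mixing", "normal"),
        )


def load_spec(path: str | Path) -> SeveritySpec:
    """Read a severity-model spec from YAML or JSON."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return SeveritySpec.from_dict(d)


def save_spec(spec: SeveritySpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def count_parameters(spec: SeveritySpec) -> int:
    """Number of estimable parameters: constants + betas + Thetas + sigmas + omegas.

    This is the "number of parameters" figure that enters the degrees of
    freedom of the likelihood-ratio instability tests.
    """
    n = len(spec.constants) + len(spec.terms)
    for t in spec.random_terms:
        n += len(t.het_mean_covariates)   # Theta
        n += 1                            # sigma
        n += len(t.het_variance_covariates)  # omega
    return n


@dataclass
class ParameterSet:
    """All estimable quantities of the model, keyed by name.

    ``beta`` holds fixed coefficients and random-coefficient means alike
    (one entry per term variable); ``theta``/``omega`` are keyed by
    (term variable, covariate).
    """

    constants: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    theta: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    omega: dict[tuple[str, str], float] = field(default_factory=dict)

    def count(self) -> int:
        return (
            len(self.constants) + len(self.beta) + len(self.theta)
            + len(self.sigma) + len(self.omega)
        )

    @classmethod
    def zeros(cls, spec: SeveritySpec) -> "ParameterSet":
        ps = cls()
        for a in spec.constants:
            ps.constants[a] = 0.0
        for t in spec.terms:
            ps.beta[t.variable] = 0.0
        for t in spec.random_terms:
            for z in t.het_mean_covariates:
                ps.theta[(t.variable, z)] = 0.0
            ps.sigma[t.variable] = 0.0
            for w in t.het_variance_covariates:
                ps.omega[(t.variable, w)] = 0.0
        return ps
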