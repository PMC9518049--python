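# Methods

## Model and assumptions

The package estimates an unordered four-alternative logit over the severity
levels NI < MI < SI < FI (the scale is kept as labels; nothing exploits the
ordering).  One alternative — configurable, NI by default — is the base:
its severity function is normalised to zero, it carries no constant and no
terms, and constants are free exactly for the alternatives the
specification lists, so model layouts with one, two or three constants are
all expressible.  Every variable enters exactly one severity function
(generic coefficients shared across alternatives are deliberately not
supported), and every covariate is a 0/1 indicator.

A random coefficient follows

    β_n = β + Θ·Z_n + σ·exp(ω·W_n)·ν_n,   ν_n ~ N(0,1) i.i.d. across crashes,

so the effective standard deviation σ·exp(ω·W_n) is strictly positive for
any finite parameters.  The mixing density is normal; the choice is a
config field (`mixing_distribution`) so that alternative densities can be
compared empirically, but only the normal is currently implemented.
σ is unconstrained during optimisation (the normal density is symmetric in
its sign) and reported as |σ|.

Each crash is a single observation: there is no panel structure and no
cross-observation correlation in the likelihood.

## Estimation

* Simulated log-likelihood: LL = Σ_n ln[(1/D) Σ_d P_nd(y_n)] with softmax
  probabilities guarded by max-subtraction.  With no random terms this is
  exactly the closed-form MNL log-likelihood for any D.
* Draws: Halton radical-inverse sequences, one prime base per random term
  (2, 3, 5, ... in term order, never reused), the first 10 elements
  discarded by default (`skip`; early elements are highly structured), each
  record taking a contiguous non-overlapping block of D elements, mapped to
  normals by the inverse normal CDF.  D defaults to 1000.  How draws are
  allocated across observations is a convention, not an estimand; the
  contiguous-block choice is fixed and documented so results are exactly
  reproducible.  Optional deterministic digit-scrambling (`scramble=True`)
  is available for high-dimensional specifications.
* Optimiser: BFGS on the negative simulated log-likelihood with the
  *exact analytic simulated score* (gradient sup-norm tolerance 1e-5,
  500 iterations maximum).  The analytic score was chosen over numerical
  differentiation because it is exact (finite-difference noise on a
  simulated objective can stall quasi-Newton updates) and roughly p times
  cheaper per iteration; the test suite verifies it against central
  finite differences at ~1e-5 absolute agreement.  A run that exhausts
  iterations is returned flagged `converged=False`, never silently.
* Starting values: the converged closed-form MNL fit (random-term means
  treated as fixed coefficients), then σ = 0.1, Θ = ω = 0.  Optional seeded
  perturbation restarts (`n_restarts`) guard against multimodality; the
  default is the single documented start.
* Standard errors: inverse numerical Hessian of the simulated
  log-likelihood at the optimum, built by central differences of the
  analytic score (step 1e-5·max(1,|θ_j|), symmetrised).  A singular
  Hessian yields NaN standard errors with estimates still reported.
  t-statistics are estimate/SE; the covariance is Hessian-based, not
  sandwich, and reports say so.
* LL(0) is −N ln 4 (every parameter zero, equal shares); ρ² = 1 −
  LL(β)/LL(0).

## Marginal effects

For each indicator, probabilities are simulated twice — variable forced to
1 and to 0 for every record, the same draw set both times — and the
per-record differences averaged over the full estimation sample (the
standard convention for indicators; effects at the means are not meaningful
for 0/1 variables).  The switch propagates through every pathway: the
variable's own term and any appearance in a Z or W list, so a variable
appearing only as a heterogeneity covariate still has a well-defined
effect.  By construction the four per-alternative effects of any variable
sum to zero.

## Instability tests

The global test statistic is −2[LL(pooled) − Σ_t LL(t)] with dof computed
from the supplied parameter counts (Σ_t K_t − K_pooled), never inferred.
A negative statistic (possible only if the pooled model is mis-converged)
is returned with a warning flag, not clamped.

The pairwise test defaults to *restricted evaluation*: period t2's
converged parameter vector is evaluated, fixed, on period t1's data
(fresh draws for t1's records, same draw configuration), and compared with
t1's own converged log-likelihood; dof equals t2's parameter count.  When
both periods share a specification this is a nested restricted-vs-free
comparison, so the statistic is non-negative and exactly zero for
self-transfer; a negative value aborts with diagnostics.  The alternative
reading — refitting t2's specification freely on t1's data
(`mode="respecify-refit"`) — compares specifications rather than parameter
values, can legitimately go negative, and is therefore flagged with a
warning.  Confidence levels at or above 99% render as ">99%" in the
matrix cells ("value (dof) [>99%]"); the exact chi-square CDF value is
stored alongside.

## Synthetic-data generator

The generator emulates the structure the estimator assumes: independent
Bernoulli indicators at registry-like prevalences (defaults between 0.03
and 0.88, e.g. major arterial 0.597, over-speeding 0.690), and outcomes
drawn by adding independent Gumbel(0,1) noise to the systematic utilities
and taking the argmax — distributionally identical to sampling the softmax.
The default truth is the smallest shape exercising every parameter class:
three constants, six fixed terms, one random term with one Z and one W
covariate (13 parameters), with coefficients of moderate size (|β| ≤ 1.5,
σ = 2.0, Θ = −0.8, ω = 0.6).  The σ value was fixed by a standard
simulation-design step: an observed-information analysis at the truth
showed that σ below ≈1 is statistically indistinguishable from the σ = 0
boundary at n = 4000 (singular information; the MLE collapses to σ ≈ 0 in
a third of samples), which would make a coverage-based recovery study
vacuous, whereas σ = 2.0 has an information ratio σ/SE(σ) ≈ 4.5 — and is
the realistic magnitude for the random parameters this literature reports.

What the generator does **not** emulate: correlation among indicators
(real road-class and speed-limit indicators are strongly dependent; an
optional exchangeable Gaussian-copula mode exists for stress tests but is
off by default), unknown or missing covariates, reporting error in the
severity outcome, and any spatial structure.  Passing tests therefore
demonstrate that the estimator and tests behave correctly when the model
is true — not that the model is adequate for any particular registry.

## Validation-study problem sizes

* Parameter recovery: 20 replications at n = 4000 observations and D = 500
  draws; success is each of β, Θ, σ, ω falling within 3 SEs of truth in at
  least 18 of 20 replications.
* Instability size/power: 20 replications of three-period studies at
  period sizes 2045/2095/2262 with a fixed-coefficient specification (the
  likelihood-ratio machinery is identical for mixed fits, and
  fixed-coefficient fits keep the study fast); power scenario shifts one
  coefficient by +1 in the final period.
* Oracle equivalence: 25-record, 50-draw toys against a pure-Python
  per-record, per-draw loop (agreement to 1e-10).
* Draw-count stability: at a 1000-draw optimum, doubling to 2000 draws
  moves the log-likelihood by well under 0.1%.

## Degenerate inputs and numerical choices

Rows failing validation (non-binary indicator, unmappable outcome, missing
period/group — including crashes of unknown rider group) are rejected into
a report, never coerced or imputed.  A spec variable that is constant in
the data is refused at fit time as non-identifiable; evaluation-only
designs (prediction, marginal-effect scenarios, parameter transfer) skip
that check since nothing is estimated.  Simulated probabilities are clipped
at 1e-300 before the log; a non-finite parameter vector raises, and the
optimiser's line search backtracks.  Ties in the Gumbel-argmax generator
have probability zero and are resolved by numpy's argmax (first index).

## Known limitations

Only the normal mixing density; no ordered-response or panel variants; no
Bayesian estimation; no variable-selection machinery; spatial instability
is out of scope.  Standard errors ignore simulation noise in the draws
(as is conventional at D ≥ 500); very small σ puts the parameter near the
boundary of identifiability, where its SE is large and the 3-SE coverage
criterion is conservative rather than sharp.
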