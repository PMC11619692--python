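# Methods

`lcmgof` is a simulation laboratory for a specific methodological question
in diagnostic-accuracy research: when a two-class latent class model (LCM)
that assumes *conditional independence* (CInd) between tests is fitted to
data in which two tests are in fact *conditionally dependent*, do the
standard goodness-of-fit tools — residual correlation plots and overall /
pairwise χ² and G² statistics — point at the right place?

## Models

**Conditional-independence model (the fitted model).** Four binary tests
T₁..T₄ on each subject; latent disease status D ∈ {0, 1} with prevalence
π = P(D=1); sensitivities Seᵢ = P(Tᵢ=1 | D=1) and specificities
Spᵢ = P(Tᵢ=0 | D=0). Given D the tests are independent, so the probability
of a result pattern (t₁..t₄) is

    P(t) = π ∏ᵢ Seᵢ^tᵢ (1−Seᵢ)^(1−tᵢ) + (1−π) ∏ᵢ Spᵢ^(1−tᵢ) (1−Spᵢ)^tᵢ .

**Conditional-dependence model (the generating model).** Identical, except
that a fixed-effect covariance `covse12 = Cov(T₁, T₂ | D=1) ≥ 0` is added to
the diseased-class product over tests 1–2 when t₁ = t₂ and subtracted when
t₁ ≠ t₂. Tests 3–4 and the whole disease-free class stay conditionally
independent. Validity of all 16 pattern probabilities bounds the covariance
by `min(Se₁, Se₂) − Se₁Se₂`; scenarios parameterise it as a fraction ω of
that bound. Because every grid scenario has Se₁ = Se₂, ω equals the
conditional Pearson correlation Corr(T₁, T₂ | D=1) =
covse12 / √(Se₁(1−Se₁)Se₂(1−Se₂)).

Pattern probabilities are stored at index k = 8t₁ + 4t₂ + 2t₃ + t₄ (test 1
most significant). The generating model never states an ordering; one
declared convention keeps observed/expected cells aligned everywhere.

## Scenario grid

Sample size n_obs ∈ {500, 2000, 5000}; π ∈ {0.2, 0.5}; ω ∈ {0.5, 0.9};
sensitivities take the six H/L patterns HHLL, HHHL, HHHH, LLLL, LLHL, LLHH
(tests 1–2 jointly High = 0.9 or Low = 0.6) and specificities the seven
patterns HHLL, HHHL, HHHH, LLLL, LLHL, LLHH, LHLH — 504 scenarios in all.
Scenario labels are the concatenated codes ("LLHH-LLHH") so results can be
cross-referenced against the published tables. The grid is emitted by a
pure function; subsets and reduced-replication runs are ordinary configs.

## Data generation

One data set is a single multinomial draw of size n_obs over the 16 exact
pattern probabilities, kept as the 16-cell count vector — the sufficient
statistic for the fit and all assessments. The generator emulates exactly
the sampling model above: no missingness, no covariates, no clustering, no
test dependence in the disease-free class, and a single dependent pair.
Passing tests therefore demonstrate correctness of the machinery under this
idealised design, not robustness of the tools on real data with richer
dependence structure.

## Fitting: data-augmentation Gibbs sampler

The CInd model is fitted in a Bayesian framework with independent
Beta(1, 1) priors on all nine parameters, jointly truncated to
{Seᵢ ≥ 1 − Spᵢ}. The constraint removes the mirror mode (Se, Sp) →
(1−Se, 1−Sp) that would otherwise allow label switching between the
classes.

Each iteration:

1. allocate each pattern's count between the two classes with a binomial
   draw at the conditional membership probability implied by the current
   parameters;
2. update π from its Beta full conditional;
3. update each Seᵢ from its Beta full conditional truncated to
   [1 − Spᵢ^(current), 1], then each Spᵢ truncated to [1 − Seᵢ^(new), 1],
   via inverse-CDF sampling of the truncated Beta (regularised incomplete
   beta function and its inverse). Inverse-CDF sampling is exact and free
   of rejection loops even when the posterior presses against the
   constraint.

Initial values are independent draws from the constrained uniform prior per
chain (a uniform draw on the unit square reflected into the half-square
Se + Sp ≥ 1), giving overdispersed starts that make R-hat meaningful.
Numerical guards clip parameters to [1e−12, 1−1e−12]; degenerate inputs
(empty count vectors) are rejected up front.

Run lengths default to the study protocol: 3 chains, 5000 burn-in, 10000
retained iterations per chain. The sampler state is vectorized across a
*batch* of independent chains, so the chains of many replicates advance in
lockstep through the same numpy/scipy calls. This is the package's central
performance choice: a 100-replicate scenario at full settings fits in about
a minute on one CPU. The cost is that a replicate's draws depend on the
composition of its batch (one RNG stream drives the whole chunk), so
results are reproducible for a fixed study configuration (fixed chunk size
and root seed) rather than per-replicate in isolation. Data simulation, by
contrast, does use one derived stream per replicate.

Convergence screening follows the study protocol: a fit is excluded when
any parameter has R-hat > 1.1 or effective sample size < 400. The modern
rank-normalized split R-hat and the matching multi-chain bulk ESS are used
(via ArviZ); the split variant is the more conservative reading of the 1.1
rule. The ESS threshold of 400 (equivalent to a Monte Carlo error of 5% of
the posterior SD) is applied to the pooled multi-chain estimate.
Zero-variance chains — impossible in normal operation — report R-hat 1 with
a warning and ESS 0.

Posterior summaries are pooled-across-chains medians and equal-tailed 95%
credible intervals.

## Goodness-of-fit tools

* **Residual correlations.** For pair (i, j): the observed phi coefficient
  of the marginal 2×2 table minus the model-fitted phi, the fitted term
  recomputed at every retained draw (the observed term is constant). A pair
  is flagged when the equal-tailed 95% CrI of the residual strictly
  excludes zero; the residual *plot* flags lack of overall fit when any
  pair is flagged. Replicates in which a test is all-positive or
  all-negative leave the observed correlation undefined; they are flagged
  degenerate, counted, and excluded from the residual-tool denominators
  rather than silently propagating NaNs.
* **Overall χ² and G².** Computed over the 16 cells from observed counts
  and expected frequencies at the *posterior medians* (plug-in, not
  per-draw — the choice that keeps the statistics comparable with their
  frequentist originals), with the 0·log 0 = 0 convention, referred to the
  95% critical value of χ² with df = 2⁴ − 9 − 1 = 6.
* **Pairwise χ² and G².** The same statistics on the collapsed 2×2
  agreement table of each pair, df = 1. Critical values come from the χ²
  quantile function at runtime, never hard-coded literals.
* **Agreement probabilities.** P(Tᵢ = Tⱼ) observed, fitted (at posterior
  medians) and under the generating parameters with ω = 0 ("true CInd") —
  the quantity that explains the tools' behaviour: the fitted CInd model
  tends to accommodate the largest pairwise agreement, which is usually,
  but not always, the truly dependent pair.

## Performance measures

Per scenario, over converged replicates: detection percentages per tool
(overall and per pair) with exact Clopper–Pearson 95% Monte Carlo CIs; bias
of posterior-median estimates (mean with MCSE-based interval, and median
with 2.5th/97.5th percentiles; the mean of |bias| is also exported since
"average absolute bias" admits both readings — the signed mean is primary
because over/under-estimation direction is the finding of interest);
coverage of 95% CrIs with Clopper–Pearson CIs. Cross-scenario summaries
pool the flat replicate table (never averages of scenario summaries),
grouped by prevalence, ω, or sample size. Replicate accounting is conserved:
n_sim = converged + excluded, with degenerate replicates tracked within the
converged set.

The replicate-count formula n_req = (z₀.₉₇₅ √(p(1−p)) / (L/2))² gives the
replicates needed for a 95% Monte Carlo CI of length L around a detection
proportion p; it is rounded to the nearest integer (983 at p = 0.8,
L = 0.05). The full study protocol uses 1000 replicates per scenario.

## Problem sizes used in the shipped checks

The package's own verification runs are desk-scale by design: three
illustrative scenarios (π = 0.5, ω = 0.5, n_obs = 2000; sensitivity–
specificity combinations LLHH-LLHH, HHHH-HHHH, HHHH-HHLL) at 100
replicates each under the full MCMC protocol, a 60-replicate
correctly-specified run for coverage and null calibration (shortened
chains), and a six-scenario ω = 0.9 sub-grid at 15 replicates for the
directional cross-scenario pattern. At 100 replicates a detection
percentage carries a Clopper–Pearson interval of roughly ±10 points, which
is the tolerance used when comparing against published percentages. The
full 504-scenario × 1000-replicate design is expressible as a one-line
config (`scenarios: full-grid`) but is a cluster-scale computation and is
not part of any shipped test.

## Known limitations

* Fixed at four tests, one dependence term, diseased class only; no
  random-effects (latent-trait) dependence models.
* The CDep model itself is never fitted — only the misspecified CInd model,
  which is the point of the study design.
* The sampler targets the exact posterior, but ESS/R-hat variants differ
  slightly from older Gibbs-sampler tooling; the screening rule (1.1 / 400)
  is the same, so exclusion sets may differ marginally on borderline fits.
* Batched fitting ties a replicate's RNG stream to its chunk, as described
  above.
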