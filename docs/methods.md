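# Methods

## Model

The burden model for a continuous trait is

    y = F α + g_φ(X, A) β + ε,    ε ~ N(0, σ² I_N)

with the saturated additive aggregation

    g_φ(X, A) = sigmoid(X A φ − b0).

`X` (N×S) holds minor-allele dosages of a gene's rare variants (MAF
below the filter threshold, default 0.1%), `A` (S×L) processed
annotations with higher values meaning more deleterious, `F` (N×K)
covariates including an intercept. Binary traits use a Bernoulli
likelihood with sigmoid link on `F α + g β`; all derivations carry over
by substituting the likelihood.

Assumptions worth stating explicitly:

- **Additivity in annotations.** A variant's contribution to the
  pre-activation is linear in its annotation row; annotation×annotation
  interactions are out of scope.
- **Saturation.** One fully disruptive variant is enough: the sigmoid
  caps the burden near 1, so additional hits in an already-disrupted gene
  change the score marginally.
- **Allelic series prior.** `φ` has independent Gaussian priors chosen so
  that pLoF variants almost surely disrupt (single-carrier burden ≈ 1),
  other consequence classes have weaker, more uncertain effects, and
  continuous annotation columns make moderate positive adjustments. Signs
  are not constrained; positivity is encouraged through the prior means
  only.

## Annotation processing

Consequence terms are classified into pLoF (splice donor/acceptor,
frameshift, stop gained/lost, start lost), missense, other
nonsynonymous, or excluded (synonymous/non-coding; unknown terms are
excluded with a warning rather than silently dropped). Consequence
classes enter `A` as binary one-hots and are not rescaled.

Each continuous score column is (1) oriented so higher = more
deleterious (declared per column in a sidecar config; SIFT-like scores
and allele frequency are reversed), (2) median-imputed, (3) Phred-scaled
by descending rank, `−10 log10(rank/M)` with average ranks on ties, and
(4) divided by its maximum so entries lie in [0, 1]. The ranking
population `M` is every qualifying variant in the loaded dataset, not the
single gene — per-gene ranking would make annotation scales depend on
gene size. Range normalisation puts all columns on a common scale so one
set of prior hyperparameters is meaningful across heterogeneous scores.
Allele frequency appears twice with different roles: the MAF *filter*
restricts which variants enter `X`; the oriented, scaled MAF *column* is
an ordinary annotation in `A`.

## Priors and fixed constants

| parameter | default | role |
|---|---|---|
| `b0` | 5 | offset; non-carrier burden sigmoid(−5) ≈ 0.0067 |
| pLoF prior | N(10, 1²) | single carrier burden sigmoid(10−5) ≈ 0.993 |
| missense prior | N(2, 2²) | weaker, uncertain effect |
| other nonsynonymous | N(1, 2²) | weaker still |
| continuous columns | N(0.25, 0.5²) | moderate positive adjustment |

`b0` is a fixed constant, not estimated: it only shifts the
pre-activation so non-carriers land near zero, and freeing it would add a
`β`–`φ`–`b0` identifiability dimension for no modelling gain. All
hyperparameters are overridable through the prior config; a
`flat_consequence` ablation gives all three consequence classes the
missense prior, removing the pLoF-dominant assumption. The exact numeric
values are this package's choices, fixed once; they reproduce the
qualitative ordering (pLoF ≫ missense > other > continuous) the model is
built around.

## Inference

The marginal likelihood integrates over `φ`, so the model is fitted by
black-box variational inference with a mean-field Gaussian
`q(φ) = N(μ, diag(exp(ω))²)`. The objective is a Monte Carlo ELBO with
the Gaussian–Gaussian KL in closed form and the expectation approximated
with `n_mc = 16` reparameterised draws `φ_m = μ + exp(ω)·ε_m`. The base
samples `ε_m` are drawn once per gene — seeded by (global seed, CRC32 of
the gene id) — and held fixed, making the objective smooth and
deterministic so quasi-Newton optimisation applies. L-BFGS maximises the
ELBO jointly over `{α, β, log σ², μ, ω}` with analytic gradients,
gradient tolerance 1e-5 and at most 500 iterations (typical smooth
low-dimensional defaults); initialisation is the exact null fit
(`α, σ²` from OLS / logistic ML, `β = 0`) with `q` = prior. On optimiser
failure the fit restarts once from a jittered initialisation (seed + 1)
and is otherwise flagged non-converged.

**Sparse non-carrier shortcut.** Individuals with no variant in the gene
have `g = sigmoid(−b0)` independent of `φ`, so their likelihood terms
(and gradients) are computed once per objective evaluation instead of
once per Monte Carlo sample. The fit cost then scales with the carrier
count, which at rare-variant frequencies is a small fraction of N. The
sparse and dense paths agree to ≤1e-10 (tested).

The covariates-only null does not depend on the gene, so scans fit it
once per trait and reuse it (cache keyed by the actual phenotype and
covariate content, making reuse safe even with heterogeneous providers).

## Association testing

The exact LRT needs the alternative's log marginal likelihood, which is
intractable. It is replaced by the importance-weighted ELBO

    IW-ELBO = E[ log (1/K) Σ_k p(y|θ̂,φ_k) p(φ_k) / q(φ_k) ],  φ_k ~ q,

averaged over 30 independent estimates of K = 16 importance samples
(log-sum-exp throughout; non-carrier terms again computed once). The
statistic is `max(0, 2·(IW-ELBO − ℓ₀))` with the null log-likelihood ℓ₀
exact, referred to χ² with 1 degree of freedom: the alternative adds the
single parameter β, and `φ` is marginalised under both hypotheses. Small
negative bound gaps are estimator slack, not evidence, hence the clamp.
Since the alternative is lower-bounded while the null is exact, the test
is conservative relative to the exact LRT; tightness improves with K.

**Annotation importance scores (AIS).** For a group of annotation
columns, replace them in `A` by their per-variant-set medians (`A0`) and
report `s_i = E_q[g(X, A) − g(X, A0)]_i`, estimated from posterior draws
(default 64). Non-carriers score exactly 0. With collinear annotations
the per-column attribution is confounded; grouped scores (consequence
classes, functional, splicing, RBP, regulatory) are the supported
reading, and per-column AIS sits behind an explicit `groups` argument.

## Baselines

pLoF burden (unweighted dosage sum over pLoF variants — the classical
mask, deliberately unsaturated), ACAT-Conseq (per-consequence-class mask
burdens combined with the aggregated Cauchy association test) and
ACAT-MultiAnnot (one annotation-weighted burden `X A[:,l]` per column,
Cauchy-combined). All burden tests are likelihood-ratio tests:
`N log(RSS₀/RSS₁)` on χ²(1) for continuous traits, logistic ML fits for
binary. ACAT uses equal weights, p-values clipped to
[1e-300, 1 − 1e-16], the `1/(pπ)` tangent asymptote below 1e-15, and the
`1/(Tπ)` shortcut for extreme statistics.

## Synthetic data generator

The generator emulates the statistical structure of biobank exome data
for one gene: MAFs log-uniform on [1e-4, 1e-3], dosages independent
Binomial(2, MAF) (no linkage disequilibrium), consequence classes
multinomial with probabilities (0.1, 0.6, 0.3) for (pLoF, missense,
other), 21 i.i.d. standard-normal continuous scores in four groups
(functional 5, splicing 2, RBP 8, regulatory 6) plus the MAF column —
the 25-column panel — all pushed through the same orientation/Phred
pipeline as real annotations. Covariates are an intercept plus one
standard-normal column with effects (0, 0.1).

Phenotypes come from the saturated model itself with truth weights
mirroring the allelic-series ordering: pLoF 10, missense 2, other 1,
plus weight 2 on the first `k` contributing continuous columns ("C+k"
scenarios). `β*` is rescaled so the burden term explains the target
fraction of total phenotypic variance (empirical burden variance;
unit-variance noise). Binary traits use a latent-logistic variance
target and solve the intercept numerically for the requested prevalence.
The deviation scenario adds per-variant pre-activation effects
N(0, sd²) independent of annotations, breaking the allelic-series
assumption on purpose.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, correlated annotations (real pathogenicity scores
are strongly collinear), annotation–consequence dependence, population
structure, relatedness and case–control sampling biases. Passing
calibration and power checks on this generator therefore demonstrate
correctness of the statistical machinery under the model's assumptions,
not performance on real cohorts.

## Study harnesses and problem sizes

Null calibration draws a fresh gene and null phenotype per replicate
(2,000 replicates at n = 2,000, S = 50 by default) and reports rejection
fractions at α ∈ {0.05, 0.01, 1e-3} with binomial standard errors; a
permuted-phenotype mode covers permutation nulls. Power studies run 100
replicates per scenario. The desk-scale preset uses n = 5,000 with
variance explained 0.005 — chosen so the pLoF baseline lands near 30%
power — and a significance threshold of 1e-4, since 100 replicates
cannot resolve the exome-wide 2.5e-6; that threshold remains the default
for full-scale runs. These sizes keep the complete study suite in the
minutes range on one CPU.

## Numerical choices

- Ties in Phred ranking: average rank (deterministic, order-independent).
- `σ²` optimised on the log scale; logistic fits use `log_expit` for
  stable log-likelihoods; importance weights combined by log-sum-exp.
- Degenerate inputs: an all-zero or covariate-collinear burden yields an
  NA p-value ("degenerate burden"); a perfectly fitted phenotype raises a
  degenerate-phenotype error; a gene with no qualifying variants is a
  typed empty-gene signal that scans record as NA.
- Determinism: every random stream descends from (seed, gene-id hash)
  via `SeedSequence`; identical inputs and seed reproduce results
  bit-identically, independent of gene processing order.

## Known limitations

- The Cauchy combination behind ACAT-MultiAnnot is mildly
  anticonservative at moderate significance levels when combining many
  strongly dependent tests (its accuracy guarantee is asymptotic for
  small α): under the 25-column null simulation its type-I error at
  α = 0.05 measures ≈ 0.055–0.065. The effect reproduces with exactly
  uniform component p-values, so it is a property of the combination
  rule, not of the burden tests. At the stringent thresholds used for
  discovery (≤1e-4) the combination is accurate.
- The approximate LRT is conservative by construction; very small
  effects near the significance boundary pay the bound gap.
- Binary traits use the plain Bernoulli likelihood without small-sample
  bias correction; severely imbalanced case–control ratios with near-zero
  carrier counts inherit the usual logistic small-sample caveats.
- AIS values for collinear annotations should be read at the group
  level only.
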