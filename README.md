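# bayesrvat

Bayesian gene-level rare-variant association testing with
annotation-weighted burden scores.

## The problem

Gene-based rare-variant association tests (RVATs) look for genes whose
rare variants (here MAF < 0.1%) jointly influence a trait. Classical
burden tests collapse a fixed set of "qualifying" variants — typically
putative loss-of-function (pLoF) — into one count per individual and
regress the trait on it. That throws away the rich landscape of variant
annotations now available (consequence classes, CADD/SIFT-style
pathogenicity scores, splicing and regulatory predictions), and a rigid
mask cannot adapt to gene- and trait-specific genetic architectures.

This package implements a Bayesian burden test that models how all
annotations combine into a burden score, learns that combination per
gene-trait pair, and still produces a calibrated p-value.

## The model

For trait values `y` (N individuals), dosages `X` (N×S rare variants),
processed annotations `A` (S×L, higher = more deleterious) and covariates
`F` (N×K):

```
y = F α + g_φ(X, A) β + ε,          ε ~ N(0, σ² I)
g_φ(X, A) = sigmoid(X A φ − b0)
```

The saturated aggregation `g_φ` maps each individual to a burden in
(0, 1): non-carriers sit near zero (offset `b0`), and once a gene is
disrupted further variants change little (sigmoid saturation). The
aggregation weights `φ` carry independent Gaussian priors encoding an
*allelic series*: a strong positive prior for pLoF (a single carrier is
pushed to burden ≈ 1), weaker and wider priors for missense and other
nonsynonymous classes, and small positive-mean priors for continuous
annotation columns. Binary traits replace the Gaussian likelihood with a
Bernoulli likelihood and sigmoid link.

Fitting maximises a fixed-noise Monte Carlo ELBO jointly over
`θ = {α, β, σ²}` and a mean-field Gaussian posterior `q(φ)` with L-BFGS;
non-carriers (the vast majority) are handled in closed form outside the
Monte Carlo loop. The gene-level p-value comes from an approximate
likelihood-ratio test: the alternative log marginal likelihood is
replaced by the importance-weighted ELBO (mean of 30 estimates with 16
importance samples each), the null is exact, and the statistic
`max(0, 2·(IW-ELBO − ℓ₀))` is referred to χ²(1). Because the IW-ELBO is a
lower bound, p-values err on the conservative side.

Also included: the classical baselines (pLoF burden, ACAT-Conseq,
ACAT-MultiAnnot with the aggregated Cauchy combination), annotation
importance scores (expected burden drop when an annotation group is reset
to its median), a full synthetic-data generator, and calibration/power
study harnesses.

## Worked example

Simulate one gene for 5,000 individuals where the burden explains 1% of
trait variance through consequence classes plus two continuous
annotations, then test it:

```python
import bayesrvat as b

scenario = b.SimScenario(n_individuals=5000, variance_explained=0.01,
                         n_contributing_continuous=2, seed=7)
data, truth = b.simulate_dataset(scenario)
res = b.test_gene(data, config=b.TestConfig(seed=0))
print(res.null_loglik, res.alt_bound, res.lrt_stat, res.p_value)
```

prints

```
gene=simgene n_variants=50 n_carriers=140
null loglik = -7075.70
IW-ELBO     = -7049.96
LRT stat    = 51.48, p = 7.23e-13
```

The burden carries genuine signal: the bound exceeds the null
log-likelihood by ~26 nats, giving a statistic of 51.5 on χ²(1), far past
the exome-wide threshold 2.5e-6. The baselines on the same gene
(`b.plof_burden(data)`, `b.acat_conseq(data)`, `b.acat_multiannot(data)`)
give 7.5e-13, 2.3e-12 and 1.9e-11. Annotation importance scores for the
fitted model rank pLoF first (mean carrier burden shift +0.125), with the
contributing functional group visible above the noise groups.

The same pipeline runs from the shell on VCF/TSV inputs:

```
bayesrvat test --genotypes cohort.vcf --annotations variants.tsv \
    --scores-config scores.yaml --phenotype pheno.tsv \
    --covariates covar.tsv --gene ENSG00000198691 --out results/ --seed 1
```

with subcommands `baselines`, `ais`, `simulate`, `calibrate` and `power`
for the rest of the toolkit. Multi-gene scans support two-stage
prefiltering (`--prefilter`): a cheap stage-1 test on every gene, the
Bayesian test only where stage-1 p < 1e-2, with the Bonferroni family
size always the full gene×trait grid.

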