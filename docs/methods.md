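# Methods

## Model and test

RNA-seq counts are modelled as compositions: only relative abundances within
a sample are informative. After gene filtering, each sample column is
centered log-ratio (CLR) transformed with natural logarithms over the G
retained genes, so each transformed column sums to zero and is invariant to
per-sample scaling (sequencing depth). No count normalization (TMM,
median-of-ratios, …) is applied or needed: depth cancels inside the CLR.

Per gene and group, CLR values are modelled skew-normal. We work in the
centered parametrization (μ mean, σ SD, γ skewness; |γ| < k ≈ 0.9953)
rather than the direct one (ξ, ω, α) for two reasons: the parameter under
test is σ itself, and the Fisher information is singular in direct
coordinates at α = 0 but regular in centered coordinates, so Wald inference
on σ is well posed even for near-symmetric genes. Differential variability
between groups 1 (reference/control) and 2 (treatment) is tested per gene
with Z = (σ̂₂ − σ̂₁)/√(Var σ̂₂ + Var σ̂₁), two-sided against N(0,1): the
method flags variability changes in both directions, and the effect size
log₂(σ̂₂/σ̂₁) keeps their sign. Multiplicity is handled with
Benjamini–Yekutieli (BY) rather than Benjamini–Hochberg because CLR couples
all genes within a sample, and BY's FDR guarantee holds under arbitrary
dependence. The BY family contains only genes with successful fits in both
groups; failed fits are reported with a `fit_failed` status instead of being
silently dropped.

CLR is computed once on the pooled filtered matrix and columns are then
split by group: the transform defines each sample's relative expression
against the common gene panel, and filtering on pooled samples keeps that
panel identical across groups.

## Estimation

Maximum likelihood runs in direct coordinates over (ξ, log ω, α) with
analytic gradients (BFGS, gradient tolerance 1e-8 scaled by n), started from
method-of-moments values with sample skewness clamped to ±0.95k. The
skew-normal likelihood has two known pathologies — a stationary point at
α = 0 and divergence of α̂ to ±∞ when all standardized residuals share a
sign — handled by a three-rung ladder:

1. plain MLE; accepted if the optimizer converges, |α̂| ≤ 50 and the
   observed information in centered coordinates is invertible with positive
   diagonal;
2. otherwise, penalized likelihood with the logarithmic shape penalty
   c₁·log(1 + c₂α²), c₁ = 0.87591, c₂ = 0.85625 (the standard choice in the
   penalized-MLE literature for keeping γ̂ off the boundary), restarted from
   the moment start and a fixed grid of shape starts {−5, −1, 1, 5}; the
   reported log-likelihood is always the unpenalized one;
3. otherwise, the normal submodel (γ̂ = 0) with closed-form standard errors.

Because the penalty is non-negative and vanishes at α = 0, every rung's
fitted log-likelihood is at least the best normal fit's — a property the
test suite checks. Fits are deterministic given the data.

Standard errors come from the numerically computed observed information
(central differences) of the log-likelihood expressed directly in centered
coordinates. Observed rather than expected information: it is what the
Hessian of the attained likelihood surface supports, and it avoids fragile
analytic expected-information expressions near γ = 0 (the centered-to-direct
map is non-smooth at γ = 0 in its intermediate quantities, but the composed
likelihood is smooth, so finite differences are stable there). A minimum of
20 observations per group is enforced and fits below 50 warn: the σ
estimate is unreliable in small samples.

## Numerical conventions

- Pseudo-count: zero cells are replaced by 0.5 before the CLR; non-zero
  counts are untouched. Replacing only the affected cells (rather than
  shifting whole rows/columns) leaves all observed counts exactly as
  measured.
- Filtering: a gene is removed when mean CPM over all (pooled) samples is
  strictly below 0.5, or its zero fraction is ≥ 0.85; library sizes come
  from the pre-filtering matrix. Filtering is idempotent.
- BY adjustment uses the harmonic constant c(m) computed with `math.fsum`,
  so the adjusted values are independent of summation order and agree bit
  for bit with a literal step-up scan.
- γ from the direct→centered map is clamped one ulp inside ±k; rounding at
  |α| ~ 1e8 can otherwise land exactly on the open boundary.
- The NB2 dispersion is floored at 1e-8 (size = 1/φ), which degenerates
  gracefully to Poisson sampling.

## Simulation protocol and its scope

The benchmark draws per-gene counts from NB2 models (variance μ + φμ²) with
both groups sharing parameters except a fraction (default 10%) of spiked
genes, whose size parameter 1/φ in the treatment group is multiplied by a
fold x: one of the intervals (0.25, 0.5) or (2, 4) is chosen with
probability ½, then x is uniform within it. Spiking changes variance only —
means are identical by construction, so any detected signal is pure
variability. Folds are drawn independently per gene; the spiked group and
the interval weighting are configurable. Post-simulation, the standard
filter is re-applied before testing. The benchmark default in tests and the
acceptance script is 2,000 genes, 100 samples per group, 5 instances — a
problem size chosen so the whole evaluation runs in minutes on one CPU while
the Monte-Carlo error on mean FDR stays well below the 0.05 target.

The synthetic parameter generator emulates *expression-filtered bulk*
RNA-seq at a nominal 20M-read depth: log₂ CPM ~ N(5, 1.7) clipped to
CPM ∈ [1, 1000] (so expected counts span roughly 20–20,000) and a
decreasing mean–dispersion trend φ = (0.1 + 2/μ)·LogNormal(0, 0.4),
i.e. biological CV ≈ 0.32 for well-expressed genes. It does **not** emulate
library-size heterogeneity across samples, correlated gene modules, batch
effects, or the long low-expression tail that filtering removes in real
data; passing benchmarks therefore demonstrate calibration and power under
a clean NB2 world, not robustness to those artifacts. Real-data NB2
parameters can be supplied instead (`estimate_nb2`, or `--params` on the
CLI) to benchmark under an empirical parameter distribution.

Power depends on expression level: the CLR variance of an NB2 gene is
approximately φ + 1/μ, so for weakly expressed genes Poisson noise 1/μ
dilutes a dispersion fold and the test (correctly) has little to detect.
The power tests condition on the predicted SD shift for this reason.

## Goodness of fit

Model adequacy is assessed per gene with a one-sample Kolmogorov–Smirnov
test of the CLR values against the fitted skew-normal CDF with estimated
parameters plugged in, p-values from the asymptotic Kolmogorov distribution.
Plug-in KS with estimated parameters is biased conservative for rejection
(the fit is tailored to the sample), and no parametric-bootstrap correction
is applied — the summary statistic (proportion of genes with p > 0.05) is
meant as a model-adequacy screen, not a calibrated test. At the protocol's
n = 500 replicates, exact small-sample KS corrections are immaterial.

## Known limitations

- Two groups only; no covariates, no paired designs.
- The test is asymptotic; below ~50 samples per group the Wald statistic on
  σ is unreliable (warned, not blocked at ≥ 20).
- Differential skewness and mean differences are estimated (μ̂, γ̂) but not
  tested.
- The MP-type matching penalty is not implemented as a distinct rung; the
  logarithmic shape penalty followed by the normal submodel covers the same
  failure modes and is flagged in the `method` field.
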