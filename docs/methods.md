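# Methods

## Data model and screening

Input is a probes × samples matrix of log-transformed, normalized expression
values with a per-sample dose and a declared log base. Columns are
canonicalized to ascending dose; the minimum dose group is the control (it
need not be literally zero). Probes with any non-finite value or zero
variance across all samples are flagged invalid and excluded — a choice made
here because zero-variance probes leave the trend statistic's pooled SD
undefined.

Fold change folds the anti-logged ratio between each dose group and control
into a signed magnitude (≥ 1 up-regulated, ≤ −1 down-regulated) and takes
the level with the largest absolute value. The screen keeps probes with
|f| ≥ 2 (inclusive) *and* a test p-value < 0.05 (strict); the fold-change
boundary is inclusive and the p boundary strict because only the fold-change
cutoff has an established convention — the p rule is this package's
documented choice, as is the default of filtering on raw rather than
BH-adjusted p.

The monotone trend statistic standardizes the isotonic (monotone-constrained,
size-weighted max–min) MLE of the group means against the observed control
mean, using the unbiased pooled within-group SD over *all* groups including
control (standard Williams practice; the maximization runs over treated
groups only). The statistic is computed for both directions and the larger
value wins, so up- and down-regulation are treated symmetrically. Its null
distribution is resampled: permutation of dose labels for the Williams-type
test, pooled bootstrap for the Oriogen-style variant (implemented as the
same statistic under a monotonicity assumption — a documented
interpretation, not a reimplementation of the original Oriogen). p-values
use the +1-corrected estimator p = (1 + #{T_b ≥ T}) / (B + 1), B ≥ 100,
default 1,000, always seeded. Within-group values are sorted before
resampling so results are exactly invariant to input column order.

## Dose–response models and priors

Seven continuous mean functions on the rescaled dose axis x ∈ [0, 1]
(dose / max dose; BMDs are rescaled back, and dose-scaling equivariance is
exact):

| model  | f(x)                              | parameters |
|--------|-----------------------------------|------------|
| linear | a + s·b·x                         | a, b       |
| power  | a + s·b·x^g                       | a, b, g    |
| hill   | a + s·b·x^g / (c^g + x^g)         | a, b, c, g |
| exp2   | a·exp(s·b·x)                      | a, b       |
| exp3   | a·exp(s·(b·x)^g)                  | a, b, g    |
| exp4   | a·(c − (c−1)·exp(−b·x))           | a, b, c    |
| exp5   | a·(c − (c−1)·exp(−(b·x)^g))       | a, b, c, g |

s = ±1 is the adversity direction, fixed per probe as the sign of (top-dose
mean − control mean); for exp4/5 the direction is carried by the plateau
factor c (> 1 increasing, in (0, 1) decreasing). b ≥ 0 and g ∈ [1, 18]
throughout, so every curve is monotone and shape parameters never drop below
1. Responses are Normal(f(x), σ). These are the standard EPA-style
continuous parameterizations; they are kept behind one module so they can be
swapped wholesale if a different convention is needed.

Default priors are weakly informative and data-scaled, held in a
`PriorConfig` rather than hard-coded: a ~ Normal(control mean, 2·SD(y) with
a floor), b ~ HalfNormal(2·range(y)) for the increment models and
HalfNormal(5) for the exponential rates (on the rescaled dose axis),
g ~ Uniform[1, 18], Hill c ~ Uniform(0, 30], exp4/5 c ~ Uniform(1, 30] or
Uniform(0, 1) by direction, σ ~ HalfNormal(2·pooled within-group SD). All
priors are proper, which the marginal-likelihood estimate requires.

## Posterior sampling

Each model is sampled with emcee's affine-invariant ensemble
(2·ndim+2 walkers, minimum 8). The conventional settings — iterations,
chains, warm-up fraction, seed; production default 30,000 / 1 / 50% — map
onto the ensemble so that the flattened post-warm-up draw count equals
iterations × (1 − warm-up) per chain; the *last* draws are kept so warm-up
stragglers never leak into the sample. Identical settings and seed give
bit-identical draws.

Positive scale parameters (b, σ, Hill's c, and the exp4/5 plateau excess
c − 1 or deficit 1 − c) are sampled on the log scale with the exact Jacobian
correction. This matters: when the response is far from plateau, exp4/5
identify only the product b·(c − 1), a curved ridge in the natural
parameters that ensemble moves traverse poorly; in log coordinates the ridge
is straight and mixing is fast. Without the transform, posterior BMD
intervals for exp4/5 were systematically too narrow — an artifact that
*worsened* with more data, the signature of a sampler (not model) problem.

Convergence is flagged, never fatal: each fit carries its mean acceptance
fraction and a minimum effective sample size from the integrated
autocorrelation time, and probes with poor diagnostics are labeled in the
output while still receiving estimates.

## Model weights and averaging

Posterior model weights are π(M_k | y) ∝ f̂(y | M_k)·π(M_k) with uniform
prior weights 1/K by default. The marginal likelihood f̂ is estimated by
iterative (Meng–Wong) bridge sampling against a Gaussian proposal
moments-matched to the posterior draws, computed in the log-transformed
sampling space where the posterior is closest to Gaussian; if the bridge
iteration fails to converge or the draw covariance is singular, a
Laplace–Metropolis estimate is used instead, and the estimator name is
recorded in the fit diagnostics. The model-averaged BMD posterior resamples
model indices from the weights and draws uniformly from the chosen model's
BMD sample, seeded.

## Benchmark dose

Two BMR definitions: relative change (|f(BMD) − f(0)| = value·|f(0)|) and
SD shift (= k·σ, using each draw's own σ). All seven models admit closed
forms for the BMD, verified against an independent bracketed root-finder
(relative tolerance 1e-10). A draw whose curve never reaches the BMR (e.g. a
Hill plateau below the BMR amount, or a near-zero slope) is capped at 100×
the maximum dose and the per-probe capped fraction reported — so a BMD is
always finite and positive, never "not available". Whether to cap, truncate,
or extrapolate such draws is not externally prescribed; capping keeps the
no-failure contract while exposing the pathology. BMDs above the maximum
dose are retained in the posterior (flagged per probe); an exclusion option
exists for cross-tool comparisons. BMD/BMDL/BMDU are the 50th/5th/95th
percentiles of the (averaged) BMD sample.

## Pathway aggregation

Probes mapping to more than one gene are removed; several probes on one gene
average their BMD/BMDL/BMDU. Category statistics (min/max/mean/median BMD,
median BMDL/BMDU) use only genes with estimates. Enrichment is a two-tailed
Fisher exact test on genes with vs. without BMD estimates, inside vs.
outside the category; the universe is all uniquely-mapped genes on the
platform annotation (the natural reading when the comparison population is
otherwise unspecified). Enriched categories require p < 0.05 (strict), more
than one responsive gene (strict), and percentage ≥ 3% (inclusive); BEPOD is
the median of their median BMDs (even counts: mean of the middle two).
POD–BEPOD agreement uses Pearson r and RMSD on log10 values. Annotations
come from local GMT and two-column probe-map files; no live database access.

## Synthetic data

The generator emulates the designs this pipeline targets: 5 dose levels
(0 plus four geometric doses, default 0/12.5/25/50/100), 4 replicates per
level, log2 scale, backgrounds uniform in [6, 10] (typical microarray
intensities), residual σ = 0.25 by default. Responsive probes draw a model
from the seven-model mix and a *target* true BMD log-uniform in 0.1–2× the
maximum dose (so the above-max-dose path is exercised); shape parameters are
drawn and the rate/increment parameter solved so the curve crosses the BMR
amount exactly at the target, with shape bounds keeping top-dose responses
in a plausible range for the saturating-at-nothing models (power, exp3).
The recorded true BMD is computed by the same algebra the estimation side
uses. Null probes are flat noise. The annotation gives each probe one gene
(plus a few deliberate multi-gene probes), puts the earliest responders into
one designed category, and mixes leftover responders into background
categories the way real pathways share stray members.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, normalization residue, correlated probes, or non-normal
noise. Passing tests therefore demonstrate the statistical machinery under
its own assumptions, not robustness to real-data pathologies.

## Validation problem sizes

The validation suite uses reduced problem sizes chosen to exercise each
claim meaningfully: the zero-failure battery fits 200 probes × 7 models at
5,000 iterations; posterior-coverage studies use 100 replicates per model at
n = 50/dose and 10,000 iterations (shorter chains visibly underestimate tail
spread, which shows up as under-coverage); truth-recovery uses 60 responsive
probes with large effects (3-SD BMR, σ = 0.1); enrichment replicates use 60
probes, 6 categories and 1,000-iteration fits with the full model set, since
enrichment depends on which genes get BMDs and their ranking rather than on
tail accuracy. The enrichment study generates and estimates under the same
4-SD BmrSpec — defining "true BMD" and "estimated BMD" at the same benchmark
response is the coherent comparison.

## Known limitations

- The marginal-likelihood estimator (bridge with Laplace fallback) is itself
  an approximation; model weights inherit its Monte Carlo error (log-scale
  SD ~0.1 at default settings).
- With 5 dose levels the 4-parameter models are nearly saturated; their
  parameters are weakly identified (the BMD functional is much better
  behaved) and weights between nested models are driven largely by the
  Occam penalty of the priors.
- Multiple-testing correction across pathway categories is deliberately
  absent (the enrichment filter operates on raw Fisher p).
- One ensemble "chain" is the default; multi-chain R-hat gating is not
  implemented (convergence is flagged from acceptance and autocorrelation
  instead).
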