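# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the underlying conventions
are genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design the package assumes

Three diets — basal (CON), nonfat dried milk (NFDM) and defatted bovine
colostrum (BC) — fed to fast-growing broiler chickens in two experiment
replicates, pooled for analysis (defaults 11/11/20 animals per diet). Each
animal contributes an ileal-digesta metabolite profile, a nitrotyrosine (NT)
immunofluorescence readout of the villus epithelium, 16S phylotype counts
per gut site and fraction (luminal digesta vs mucosal scraping), and
morphometric measurements. All inputs are delimited text; upstream chemistry,
imaging and read processing are out of scope — the package consumes the
extracted tables.

## Scaled Imputed Values

Untargeted LC-MS intensities are missing predominantly because a compound
fell below its detection limit in that sample, i.e. missingness is
left-censored rather than random. The normalization is therefore:

1. impute each missing cell with the **minimum observed value** of that
   metabolite — the conventional stand-in for vendor-processed "imputed"
   datasets of this kind; the censoring mechanism guarantees the imputed
   value is an upper bound on the truth;
2. divide each metabolite column by its post-imputation **median**, so each
   column's median is exactly 1 (even-n medians use the mean of the two
   central order statistics). Scaling is across all animals provided in one
   table; callers who want within-batch scaling split the table first.

The result is scale-free: multiplying a raw column by any c > 0 leaves its
SIV column unchanged (property-tested). Detection defaults to "observed"
(non-missing); per-metabolite numeric thresholds can be supplied instead.
Diet-level detection requires at least one detected animal of that diet,
matching how supplement-style detection tables are summarized.

**Outlier screen.** The exclusion convention "> 3 SD" does not by itself fix
a statistic. We score each animal by the mean of its per-metabolite z-scores
computed within diet, and exclude when the score deviates from the diet mean
by more than k score-SDs (k = 3 default, k = ∞ disables). The choice is
logged in output so a reanalysis can reproduce it; exclusion never reduces a
diet below two animals.

## Anti-inflammatory index

Candidates are per-animal pathway-group SIV sums (or single-metabolite
columns). Qualification requires all three of: a literature
anti-inflammatory flag supplied by the caller; a significant planned diet
contrast on the pooled data (α = 0.05 default); and a same-direction
significant-or-trend (p < 0.10) contrast in each replicate separately.
The screens run through the shared GLM-ANOVA module (below).

**Forward retention.** Candidates are offered in descending |Pearson r| with
log10 NT (alphabetical tie-break) unless an explicit order is given; the
order is *always* recorded in the results because inclusion is genuinely
order-dependent — two orders can retain different sets, and the package
surfaces rather than hides that. A candidate is retained iff the adjusted R²
of the model including it exceeds the current model's by more than 1e-10
(strict inequality; the tolerance only absorbs floating-point ties).
Both a "linear" and an "exponential" response fit are offered to the
comparison; since the NT response is already log10-transformed, the
log-linearized exponential fit y = a·e^{bx} is an affine transformation of
the same response and yields the identical R², so the two modes coincide —
both code paths exist for completeness and the equivalence is intentional,
not an omission.

Under the null (a candidate unrelated to the response), a single offered
regressor increases the adjusted R² exactly when its |t| exceeds 1, which
happens with probability ≈ 0.32. This chance-inclusion rate is a property of
the adjusted-R² criterion itself, not a bug; the test suite verifies it
against a permutation estimate. It is why the qualification screens matter:
retention alone does not control false inclusion. Exact recovery of a
planted inclusion set is therefore asserted on noiseless responses, where
the model saturates (R² = 1) once the true groups are in and every further
candidate is rejected.

The index is the exact per-animal sum of the retained predictors; the final
regression reports slope, intercept, R² (both plain and adjusted for the
multiple-predictor model) and the slope's t-test p-value. Animals with
missing NT are dropped listwise (logged); zero NT densities are floored at
half the smallest positive density before log10 (logged).

## GLM ANOVA with planned contrasts

One-way fixed-effects ANOVA with the residual (animal-within-treatment) mean
square as the error term. A contrast with weights w has

    t = Σ w_i ȳ_i / sqrt(MSE · Σ w_i²/n_i),   df = N − g,

handling the study's unbalanced groups. An optional additive block factor
(experiment replicate) removes the block sum of squares from the residual.
No multiple-testing correction is applied by default (raw contrast p-values
are the reporting convention for this design); Benjamini–Hochberg is
available for users who want it. The implementation is direct arithmetic;
the test suite cross-checks it against statsmodels' independent OLS contrast
machinery and a hand-worked ANOVA table.

## Community typing

Compositions are compared with the Jensen-Shannon metric: the square root of
the base-2 Jensen-Shannon divergence, which lies in [0, 1] (0·log 0 ≡ 0;
non-normalized inputs are normalized with a warning). Base 2 is the choice
that makes "normalized" exact — disjoint supports give divergence 1 and
metric 1. Ward linkage is applied to this metric matrix directly via the
Lance–Williams recurrence (scipy), although Ward formally assumes Euclidean
input; this mirrors established community-state-typing practice and is a
deliberate, documented deviation from Ward's original setting. The tree is
cut at k clusters (k = 5 default, exposed because the "right" k is a
judgment call); labels are Roman numerals by decreasing cluster size with
ties broken by first sample position after a canonical (sorted) ordering, so
the labelling is invariant to input row order. Shannon diversity uses
natural logarithms.

## LEfSe-style biomarker scores

Per phylotype: a Kruskal–Wallis sum-rank test on relative abundances across
classes at α = 0.05; constant phylotypes are skipped with a log entry. For
passers, the effect size follows the published LEfSe convention: 30
bootstrap rounds, two-thirds of each class per round, a linear discriminant
fitted jointly over all phylotypes (lsqr solver with automatic shrinkage, as
sample counts are typically below feature counts), and each feature scored
as the mean of its raw class-mean difference and its weight-scaled share of
the class separation along the unit discriminant axis; the score is
log10(max(effect, 1)). Effect sizes are computed on abundances scaled to
one million per sample — the normalization the original tool applies — so
the conventional discriminative threshold of 2.0 retains its meaning; the KW
screen itself uses plain proportions (scale-invariant). Multi-class inputs
use the stricter all-against-all strategy: the reported score is the
smallest pairwise effect involving the enriched class.

## Bayesian Poisson model of type counts

Counts on the complete diet × type grid (zero-filled) follow
y_i ~ Poisson(λ_i), log λ_i = a + b_diet + c_cluster + d_diet,cluster.
The published description of this model specifies neither priors nor
identifiability constraints, so the package declares its own: independent
Normal(0, sd = 10) priors on the free coefficients, and sum-to-zero
constraints on b, c and both margins of d (a corner-constraint mode, first
level fixed at zero, is available; the constraint in force is recorded in
the results). The sampler is an adaptive random-walk Metropolis-within-Gibbs:
single-site Gaussian proposals, scales adapted every 50 sweeps toward ~44%
acceptance during burn-in and frozen afterwards, thinning 10 to bound
memory at the full 100,000-iteration setting, 4 chains by default (at least
2 are required for the PSRF). The free-parameter-to-η map is linear, so each
proposal updates the likelihood incrementally over only the grid cells its
basis direction touches.

Convergence uses the Gelman–Rubin potential scale reduction factor,
PSRF = sqrt(((n−1)/n·W + B/n)/W), with W the mean within-chain variance and
B/n the variance of chain means; note PSRF ≥ sqrt((n−1)/n), so values a hair
below 1 are the identical-chain limit, not an error. Coefficients pinned by
a constraint (zero variance) report PSRF = NaN. Reported frequencies are λ
normalized within diet per posterior draw (so they sum to 1 in every draw),
summarized by the mean and the 2.5/97.5 percentiles; a warning fires if the
maximum PSRF exceeds 1.1.

Correctness checks in the suite: a prior-only run reproduces the prior;
saturated-model posterior means match observed counts; simulation-based
calibration covers generating coefficients at near-nominal rates; credible
intervals contract as counts grow.

## Morphometry

Relative villus area is the raw three-factor product
width × length × villi-per-unit-length — "relative" because no unit
normalization is imposed; it is linear in each factor. Villus:crypt ratios
are computed per animal before group averaging (a ratio of group means is a
different, generally non-equal statistic). NT density is pixels/nuclei;
group summaries are mean ± SEM with pairwise percent differences
100·(a/b − 1).

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, with
one RNG stream per table derived from the master seed by fixed offsets
(adding a table never perturbs existing ones; a fixed seed is bit-identical
on disk):

* **Metabolites**: log-normal intensities (per-metabolite level spread
  SD 1.0 on the natural-log scale, within-metabolite SD 0.4), with
  multiplicative diet effects on the planted pathway groups (defaults:
  informative groups ×1.4 NFDM, ×2.5 BC; sialyllactoses ×2.0 NFDM, ×5.7 BC,
  matching the fold-changes such supplementation produces). Missingness is
  left-censored: each metabolite's lowest 15% of values fall below the
  detection quantile (rate configurable), not missing-at-random.
* **NT**: log10(pixels/cell) = 3.0 − 0.05 × (true index) + N(0, 0.25), the
  true index being the informative groups' summed SIVs computed through the
  *actual* SIV pipeline, so recovery can be asserted to machine precision.
  Pixel counts are kept real-valued so the noiseless limit is exact; a real
  imaging assay would round to integers.
* **OTU counts**: per sample, a latent community type drawn from
  diet-specific frequencies (defaults qualitatively mirror a
  colostrum-enriches-types-I-and-IV pattern), composition drawn
  Dirichlet(concentration × type base composition) around well-separated
  block-structured bases, counts multinomial at depth 50,000 (the order of a
  deep 16S V4 run). The SFB phylotype in ileum-scraping samples is
  overwritten with round(10^(1.0 + 0.8·oligo-SIV-sum + N(0, 0.15))), tying
  mucosa-associated SFB abundance to sialyllactose level.
* **Morphometry**: per-diet normal draws around plausible means (villus
  lengths 265/280/250 µm, crypt depths 28/31/37 µm for CON/NFDM/BC, 5% CV).
* **Truth record**: group memberships, the informative (index-forming) set,
  per-animal true index and oligosaccharide sums, NT and SFB coefficients,
  per-sample type labels and the diet frequency simplices — serialized as
  JSON next to the tables so recovery tests never re-derive planted values.

What it does **not** emulate: compositional correlation structure between
metabolites beyond group effects, batch/run effects, phylogenetic structure
among phylotypes, site-specific metabolite gradients (sites are labels
only), overdispersion beyond the Dirichlet, or integer pixel quantization.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative assumptions, not robustness to everything real
data can do.

Defaults were fixed once, for testability at desk scale (120 metabolites
standing in for a ~950-compound profile; effect sizes large enough that
recovery is determined by estimator correctness rather than power).

## Problem sizes used in validation

The acceptance checks run at desk scale on one CPU: 100 seeded studies for
slope coverage, 20 for typing recovery (150 samples each) and Poisson
calibration (10,000 iterations + 10,000 burn-in, 2 chains), 1000 null tables
for the Kruskal–Wallis calibration, 10⁴ random triples for the metric
axioms. `scripts/acceptance.py` uses the same machinery at slightly smaller
replicate counts and finishes in about a minute.

## Known limitations

* The retention procedure's outcome depends on candidate order; the package
  records the order rather than optimizing over orders.
* The LEfSe-style score is a reimplementation of the published convention,
  not a wrapper of the original tool; small numerical differences from the
  reference implementation are expected (bootstrap draws differ).
* Ward-on-JS is heuristic (non-Euclidean input), as in the community-typing
  literature it follows.
* The Poisson model's priors/constraints are package declarations, not
  inferences from any external fit; corner vs sum-to-zero changes coefficient
  meaning (results record which was used).
* The GLM module is fixed-effects only; replicate enters as an optional
  additive block, not a random effect.
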