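# Methods

## Data model

An editing matrix is the triplet (level, edited-G reads, A+G coverage)
over sites × samples. Coordinates are 1-based, closed, strand-explicit;
the canonical site token is `chrom:pos` followed by the strand character
(`chr8:56069413-`). Editing levels are fractions in [0, 1]; inputs
formatted as percentages are rejected rather than silently converted,
because a 100× unit error would corrupt every downstream threshold.
Missing cells are `NA` in all three layers. Zero coverage is recorded
(cov = 0, g = 0) and is distinct from missingness, but a level cannot be
formed at cov = 0, so validation requires the level to be present
exactly when cov > 0; the generator draws coverage with a floor of one
read so simulated matrices are fully populated.

## Site filtering

A cell counts as edited when A+G ≥ 10, G ≥ 3, and an exact upper-tail
binomial test of G out of A+G reads against a null editing rate of 0.1%
(the assumed sequencing-error scale) is significant after
Benjamini–Hochberg adjustment at 0.05. The BH family is all non-missing
cells of the call — a per-run family chosen for reproducibility, since
any narrower family makes a cell's verdict depend on how the matrix was
chunked. Cells with missing counts are excluded, not imputed.
Discriminative sites additionally require inter-patient variation:
median(|xᵢ − Q3|) > 0 with Q3 the 0.75 quantile under the
linear-interpolation (type-7) convention, fixed here because the
quantile convention is otherwise ambiguous for small n. Samples with
more than 20% low-coverage (cov < 10 or missing) sites are dropped;
exactly 20% is retained. All inequalities are deliberately strict or
non-strict exactly as stated ("≥ 10", "> 0", "more than 20%").

## Survival machinery

Kaplan–Meier estimation, the unweighted log-rank test, and Cox
proportional-hazards fits are provided by lifelines; Cox ties use the
Efron approximation (the safer default for day-resolution data with
heavy ties) and per-covariate Wald p-values accompany HR with 95% CI.
All of them are cross-checked in the test suite against from-scratch
oracles (hand product-limit computation, the observed-minus-expected
log-rank formula, permutation calibration). BH adjustment is the
standard step-up procedure. The sex-dependent dichotomisation labels
the top 30% of editing values "high" within females and the top 70%
within males, with the cut count k = round(frac·n) and ties resolved by
stable sample order; sexes with fewer than four samples or constant
values are flagged rather than split.

## Subtyping

Editing profiles (per-site median-imputed; residual missingness is small
after coverage QC) are embedded to two dimensions with UMAP
(n_neighbors 15, min_dist 0.1, fixed seed) and clustered with HDBSCAN
over a grid of (min_cluster_size ∈ {5, 10, 20},
cluster_selection_epsilon ∈ {0, 0.5}, min_samples = 5). Each grid point
with at least two non-noise clusters is scored by the log-rank p of
overall survival across its labels, noise excluded; the minimum-p
labeling wins, ties going to the earlier grid point. Because minimum-p
selection looks at the data many times, every run returns the full
audit table and the reported selection p must equal its minimum.
The selection test is pooled over sexes (one survival objective); sex
stratification is evaluation-only. A sex is evaluable when it has at
least two populated clusters; its direction of effect compares the
highest- versus lowest-label cluster by restricted mean survival time
(RMST) up to the last observed time — KM medians can be undefined under
censoring, and RMST makes the "median-survival ordering" total. Note
that when the subtype effect has opposite sign in the two sexes, the
pooled selection p is weak by construction even though the within-sex
tests are strong; cluster recovery then rests on the embedding geometry,
with the survival objective arbitrating between near-equivalent
labelings.

## Differential editing

Per comparison (case vs. reference within one sex), the cascade first
removes near-constant sites — modal editing value in > 70% of samples
*and* variance in the bottom 20% of the per-site distribution (the
conjunctive reading; a flag switches to the disjunctive one) — then
sites with |case median − reference median| ≤ 0.03. The remaining sites
are tested with a two-sided Mann–Whitney U (exact for small tieless
groups, normal approximation with continuity and tie correction
otherwise); BH runs within the comparison only, never pooled across
comparisons, and adjusted p < 0.05 defines a DES. Genes with ≥ 1 DES
are differentially edited. Gene rankings use the gene's most significant
site: score = sign(Δmedian) · (−log₁₀ raw p), capped at 300 when p
underflows, ties broken by gene symbol. RRHO grids evaluate, for each
pair of rank thresholds, the one-sided hypergeometric enrichment of the
overlap between top slices over the common gene universe; the default
step is max(1, N/100) since no canonical step exists.

A caveat worth stating: the median-difference prefilter uses the same
data as the downstream test, so the *observed* FDR among sites surviving
the full cascade exceeds the nominal BH level (measured at roughly 0.13
when nominal is 0.05 under the reference simulation). The FDR guarantee
belongs to the test + BH step over its tested family; the cascade trades
a modest FDR inflation for a large reduction in tested sites, exactly as
published cascades of this shape do.

## Regulation inference

For each DES with an annotated host gene, ordinary least squares of
log(abundance + 0.5) on [editing level, age] gives the editing
coefficient and its t-test p; the 0.5 pseudo-count keeps zero-abundance
genes finite while barely perturbing typical RSEM-scale values. BH runs
across all tested DES–gene pairs of the run; FDR < 0.10 flags
expression-correlated sites, and each gene is represented by its
smallest-FDR site. A gene is *editing-regulated* iff its knockdown
response is significant (adjusted p < 0.05) with sign opposite to the
editing coefficient — knockdown removes editing, so a stabilising
(positive) coefficient should show reduced expression. Genes absent
from the knockdown table are "untested", never negative evidence.
Region enrichment is a two-sided Fisher exact test of 3′UTR membership,
foreground = expression-correlated DESs against background = all tested
DESs with intergenic sites excluded; the direction bias among
positive-coefficient regulated genes is an exact two-sided binomial
test against 0.5. The prognostic screen fits, per site and sex, Cox of
survival on [editing, age], BH within sex, FDR < 0.15; sexes with fewer
than 10 events are not screened and non-convergent or constant sites are
skipped and logged.

## Cross-cohort classifiers

Initial features are DESs below the sex-specific adjusted-p cut
(5×10⁻⁴ females, 10⁻⁵ males) shared with the target cohort, ordered by
significance. Collinearity pruning is a greedy pass in that order
keeping a site only if |Pearson r| < 0.9 with every kept site — the cut
is a package choice; published feature reductions of ~60% suggest
aggressive pruning but no published value exists. Tuning crosses a
random-forest parameter grid with a feature-count grid (top-k by mean
importance over the folds): stratified five-fold CV, out-of-fold
predictions pooled, and the log-rank p of training survival by pooled
predicted labels minimised. Pooling (rather than averaging per-fold
p-values) keeps the objective stable with small folds. The winning
configuration is refit on the full training cohort and evaluated on the
target by per-sex KM/log-rank and Cox controlling for age (and MGMT
status when supplied). The whole path is deterministic given the seed.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
cluster ~ Bernoulli(0.5); sex ~ Bernoulli(0.5); age ~ N(55, 10) years
truncated above 18; per-site baseline editing rate ~ Beta(2, 8) (mean
0.2, right-skewed like bulk editing levels), shifted by +Δ (default
0.15) in cluster 2 at 200 of 2000 planted informative sites; coverage
~ NegBin(mean 50, dispersion 5) floored at one read; G ~ Binomial(cov,
rate), level = G/cov. Survival is exponential with baseline hazard
log 2 / 450 days (GBM-scale median) times a cluster-2 hazard ratio of 3
for females and 1/3 for males, with independent exponential censoring
(rate 5×10⁻⁴/day, ~25% censoring). For 30 regulated genes, log
abundance = intercept + 2.0 × level(anchor site) + 0.005 × age +
N(0, 0.1); anchors are annotated 3′UTR, mirroring the 3′UTR
concentration of expression-coupled editing in tumors. The knockdown
table gives regulated genes log₂FC = −sign(coef)·1 ± 0.1 at adjusted
p ~ 10⁻⁴ and null genes N(0, 0.2) at p ~ U(0.2, 1). The site/gene
universe, baseline rates and planted sets derive from a separate
structural seed so that two cohorts can share a universe while being
sample-independent — the cross-cohort setting. Effect sizes are chosen
to make recovery tests informative at desk scale, not to mimic any
particular cohort's unpublished magnitudes.

What the generator does **not** model: read-level sequence context (Alu
embedding), tumor purity and cell-type mixture, covariance between
nearby sites beyond the planted cluster structure, non-exponential
hazards, and informative censoring. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to those real-data complications.

## Problem sizes and numerical choices

Recovery tests run at n = 200 samples × 2000 sites (stratification,
20 seeds), 80 × 500 (differential power, 20 seeds), 100 × 600
(regulation, 20 seeds), n = 500 (Cox calibration, 50 seeds), and 20
train/target pairs at 200 × 1000 with Δ = 0.2 and a deliberately small
forest grid (one parameter point, 25 features) for the transfer check —
sizes at which the planted effects are comfortably identifiable and the
suite stays quick. Degenerate inputs follow documented behavior rather
than erroring where a downstream stage can proceed: coincident embedding
points may yield one cluster or all noise; constant dichotomisation
values yield a single flagged label; p = 0 in rankings is capped at
−log₁₀ p = 300. Level/count consistency on load uses a 10⁻⁹ tolerance;
TSV floats are written with round-trip precision.

## Known limitations

- Minimum-p selection (subtyping and CV tuning) is a multiple-looking
  procedure; selected p-values are optimistic and are reported alongside
  the full audit trail rather than treated as calibrated.
- The observed-FDR inflation of the differential-editing cascade
  (above) applies equally to real data.
- The prognostic screen fits many small Cox models; per-unit-editing
  hazard ratios are large in magnitude because editing levels live on
  [0, 1], and should be read per 0.1 editing change in practice.
- Proportional-hazards diagnostics are limited to lifelines'
  convergence/separation warnings, surfaced as fit flags.
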