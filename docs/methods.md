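# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
generator does and does not emulate.

## Data model

A dataset is a samples × compounds matrix of percent relative abundances
(each profile closed to 100, tolerance 1e-6), per-compound annotations
(identity token, free-text name, optional PubChem ChemID, molecular class
from a controlled vocabulary, optional spectral match score in percent), and
per-sample factors `species ∈ {marthae, subcristatus}`, `sex ∈ {F, M}`,
integer `year`, `season ∈ {rs, nrs}`.  Compound identity is the
`compound_id` token throughout; ChemID is annotation only, since distinct
compounds can share names.  Missing matrix cells are read as zeros (a
compound not identified in a profile is absent) with a logged count; negative
values and duplicate identifiers are hard errors.  The optional match-score
filter drops compounds with a score strictly below a threshold (compounds
without a score are kept) and re-normalizes rows; normalization assumes
relative abundance is computed over the retained compounds.

Subsetting by a metadata predicate keeps compound columns even when they are
all-zero in the subset, so column indices stay aligned across season or year
subsets — required for intersecting marker sets across subsets.

## Synthetic generator

The generator provides data with the statistical structure the analysis
assumes, for testing and calibration.  For sample *s* in design cell *g* and
compound *i*:

    y = exp(m_i + effects(g, i) + ε),  ε ~ N(0, σ²)     latent intensity
    z ~ Bernoulli(π_i(g))                               presence
    value = z · y, row closed to 100                     observed percent

Defaults (`default_study_spec`):

- **Design**: the fixed 11-cell year × species × sex layout totalling 227
  samples (three field seasons; the 2015 female cell of one species is
  empty), seasons `rs` for 2012/2014 and `nrs` for 2015.
- **Compounds**: p = 113, class labels drawn to fixed proportions
  (fatty acids 34%, fatty alcohols 16%, alkanes 12%, alkenes 10%, sterols
  10%, pregnane steroids 6%, aldehydes 5%, other 7% — a lipid-dominated
  profile typical of femoral-gland secretions).
- **Baselines**: m_i ~ N(0, 1), giving a realistic spread of abundances
  across ~3 orders of magnitude after closure.
- **Presence**: bimodal π_i — 60% of compounds from Beta(4, 1.2) (a common
  core), 40% from Beta(0.6, 1.8) floored at 0.04 (occasionally-detected
  tail).  The floor keeps the probability that a compound is absent from
  all 227 samples negligible, so full-dataset richness is 113 while
  per-group richness varies with group size (roughly 90–113), as in real
  compound tables.
- **Effects**: multiplicative log-effects on small index sets; a factor
  level carries ±δ/2 (first level +, last level −; three-level year is
  spaced evenly).  Defaults plant δ_species = 2 on 7 compounds,
  δ_sex = 1 on 4, δ_year = 1 on 5 — a strong species signal with weaker
  nuisance factors, matching the analysis questions.  Effects act on
  log-intensity *before* closure, so planted markers leak into every
  relative abundance (compositional leakage); recovery tests therefore
  exercise SIMPER and the forest under the same constraint real closed data
  impose.
- **Noise**: σ = 0.6 lognormal sample noise.
- **Determinism**: spec construction and generation use separate child
  streams of one seed; the same seed always reproduces the same table.
  A sample drawing all-zero presence is redrawn (at most 100 times, then an
  error).

`null_spec` zeroes every effect magnitude, making all group labels
exchangeable by construction; it is the basis of the type-I-error and
dispersion calibrations.

What the generator does **not** emulate: chromatographic artifacts,
retention-time drift, detection-limit censoring, year-specific compound
pools (a logit shift of presence by year is exposed but defaults to 0), and
correlated compound families.  Passing recovery tests therefore show the
pipeline behaves correctly under a sparse compositional lognormal model,
not that any particular field dataset will separate.

## Diversity

`H_chem = −Σ pᵢ ln pᵢ` with pᵢ = value / row sum and 0·ln 0 = 0 (natural
log; invariant to percent-vs-proportion scaling).  `R_chem` counts compounds
with strictly positive abundance in ≥1 sample.  Group summaries report n,
R_chem, and mean ± SD of H_chem with the n−1 sample SD; a singleton group's
SD is reported as not available.  Display rounding is 2 decimals; full
precision is retained internally.

## Bray–Curtis

`d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)` on percent abundances with no further
transformation (no square root, no double standardization).  For rows closed
to 100 this equals Σ|xᵢ−yᵢ|/200, an identity cross-checked in tests.
Bray–Curtis is a semi-metric: the triangle inequality may fail, so the
matrix is passed downstream with no metric correction and PCoA must carry
the negative eigenvalues.

## Ordination

**PCoA**: A = (d²ᵢⱼ), G = −½ J A J with J = I − 11ᵀ/n; eigendecomposition of
G.  Axes with eigenvalues above a relative tolerance (1e-9 of the spectral
radius) are real coordinates scaled by √λ; eigenvalues below −tolerance
yield "imaginary" axes scaled by √(−λ), kept separately.  Variance explained
is over the positive part only.

**nMDS**: Kruskal stress-1,
`√(Σ(d̂ᵢⱼ − θ(dᵢⱼ))² / Σ d̂ᵢⱼ²)`, minimized by the Guttman majorization
transform with a monotone-regression step per iteration.  Ties in the input
dissimilarities get the primary (weak) treatment: tied values are ordered by
their current configuration distances before the isotonic fit.  Defaults:
k = 3 dimensions (profiles are plotted along X–Y–Z axes), 20 starts (one
PCoA-seeded, the rest random), tolerance 1e-7 on the stress decrease,
max 300 iterations.  An iteration that would increase stress-1 is rejected
and the start terminates, so the recorded stress history is non-increasing
by contract; the lowest-stress start wins.  A start hitting the iteration
cap returns `converged = False` with a warning rather than failing.

## Dispersion homogeneity

Samples are embedded by PCoA keeping real and imaginary parts.  Squared
distance to the own-group centroid is (real-part squared distance) −
(imaginary-part squared distance), clamped at 0 with a warning when the
correction overshoots — the standard treatment for semi-metric input.
Groups of size 1 are excluded with a warning.  The homogeneity test is a
one-way ANOVA on the distances with the classical F p-value, followed by
Tukey HSD (studentized range) over all group pairs; the headline summary is
the fraction of pairs *not* significantly different at α = 0.05 (the
"homogeneity percentage").  If every distance is zero the result is flagged
degenerate instead of producing an undefined F.

## PERMANOVA

Sequential (Type I) decomposition: for the ordered term list, nested design
matrices are built from treatment-coded mains (first level dropped) and
their products for interactions; ranks come from a QR with relative
tolerance 1e-8, and a term adding no rank is reported as aliased.  With
H_k the hat matrix of terms 1..k and G the Gower-centered matrix,
`ss_k = tr(H_k G) − tr(H_{k−1} G)`, residual SS = tr(G) − tr(H_K G), total
SS = tr(G) = Σᵢ<ⱼ d²ᵢⱼ / n, pseudo-F_k = (ss_k/df_k)/(ss_res/df_res), and
R²_k = ss_k / total.  p-values permute whole samples (rows of the
dissimilarity matrix), restricted within strata levels when a strata factor
is given, with the +1 correction
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` — a permutation p can never be
0.  All terms are evaluated on the same permutation stream.  Defaults:
the full 7-term factorial in year, species, sex; 9,999 permutations; strata
= year (the design is three sampling years each containing the four
species × sex treatments).  Year is categorical by default (df = 2 for
three years); a numeric coding (df = 1) is available since both conventions
appear in practice and the sequential decomposition is order- and
coding-dependent.  When the residual SS is numerically zero (no variation),
F is defined as 0 so all p-values come out 1.

The trace machinery reduces to classical ANOVA on Euclidean input — the
sequential SS equal coordinate-wise Type I ANOVA SS summed over coordinates
— which is the main correctness oracle, alongside exhaustive permutation
enumeration at n = 6 and a 500-dataset null calibration.

## SIMPER

For each between-group pair (j,k), compound i contributes
`|x_ij − x_ik| / Σ_i (x_ij + x_ik)`; contributions sum over compounds to the
pair's Bray–Curtis dissimilarity, so per-compound averages over all
between-group pairs sum *exactly* to the mean between-group dissimilarity
(asserted to 1e-10 on every input).  Significance permutes group labels
over samples with a one-sided (greater) tail — the question is whether a
compound contributes more than expected by chance; the observed and permuted
statistics are computed with a fixed group orientation so relabeling the two
groups reproduces bit-identical p-values.  The Bonferroni flag uses
α = 0.05 / p_total with p_total the total number of identified compounds
(not the number tested).  Markers are "consistent" when their permutation
p < α (default 0.01) in every analyzed season; the same intersection under
Bonferroni flags is reported alongside, since either convention is
defensible.  The PCA of the marker submatrix is correlation-mode by default
(abundances span scales); covariance mode is a flag.  Components are
retained while cumulative explained variance stays ≤ 0.75 (at least one),
and the top-variance compound is the one with the largest absolute loading
on the first component.

## Random-forest stability protocol

The protocol, not the tree learner, is the object of interest; trees are
scikit-learn's RandomForestClassifier (bootstrap per tree, `mtry` candidate
variables per split, Gini impurity, majority voting).  Defaults follow the
tuned operating point of the study this emulates: 500 trees, mtry = 17,
1,000 runs, stratified 50/50 train/test splits (per-class train count =
round(n·fraction), halves rounded up), positive class `marthae`.  Tuning
minimizes out-of-bag error over a user grid with ties broken toward smaller
mtry then fewer trees.  Per run: test-set confusion (tp/fp/tn/fn), accuracy
with exact (Clopper–Pearson) binomial 95% bounds, Cohen's κ
(`(p_o − p_e)/(1 − p_e)`), sensitivity, specificity, the top-1 compound by
mean decrease in Gini (exact ties broken lexicographically with a warning),
and per-test-sample positive-class vote fractions.  A run whose train or
test split collapses to one class is discarded, logged, and replaced.

Aggregation: pick-frequency table; χ² of uniform pick probability with
expected count n_runs/k over the k compounds ever observed as top-1
(df = k−1; with k = 1 the statistic is 0 and p = 1 — total concentration
leaves nothing to test over the observed set, and `chi2_uniform` accepts an
explicit category universe when a wider null is wanted); means of the
per-run metrics (averaged accuracy is the mean of per-run accuracies, never
a pooled confusion); ROC from the pooled vote fractions across all runs
with trapezoidal AUC (per-run AUC averaging available).  Child seeds for
splits and forests come from one deterministic stream of the master seed,
so the whole protocol is bit-reproducible.

## Pipeline

One master seed fans out per-stage seeds, every stage consumes the same
in-memory objects, and a failed stage is reported as skipped with its error
while independent stages still run.  Desk-scale defaults for the synthetic
demo are 999 permutations (PERMANOVA and SIMPER), 4 nMDS starts, and 100
forest runs; these sizes make a full run take a few minutes on one CPU
while leaving every test statistic with enough resolution (the smallest
attainable permutation p is 1e-3).  Reports serialize at full precision;
tables display at 2–3 decimals.

## Calibration and test problem sizes

- PERMANOVA type-I error: 500 exchangeable null datasets (2 groups × 15
  samples, 15 compounds), 199 permutations each; the α = 0.05 rejection
  count must fall in the exact binomial 99% interval.
- Dispersion calibration: 200 null datasets (2 × 20 samples) for p-value
  uniformity (KS); 60 replicates of a 4 × 30 design with one group's spread
  ×5 for power.
- Forest recovery: the full 227 × 113 design with 3 planted species markers
  (δ = 3), 100 runs.

## Known limitations

- Type I (sequential) SS only; term order matters and is reported.  No
  Type II/III option.
- The dispersion test uses the classical F p-value (not a permutation
  p-value); calibration under the generator's null supports this at the
  sample sizes used, but very small or very unbalanced groups deserve
  caution.
- SIMPER's permutation cost grows with n_A·n_B·p per permutation; the
  implementation is vectorized but dense, so very large tables may want
  fewer permutations.
- The χ² uniformity test over observed top-1 categories is undefined under
  total concentration (k = 1); use an explicit candidate universe there.
- Bray–Curtis is the only dissimilarity offered; the workflow is defined
  around it.
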