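# Methods

This note records the model behind `stwmd`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions adopted where the procedure left genuine freedom.

## Data model and assumptions

The unit of analysis is a four-way tensor `y[t, i, r, g] ≥ 0` of expression
abundances over stages `t = 0..T`, samples `i = 1..N_t` within stage,
regions `r = 1..R` and genes `g = 1..G`.  Stages are cross-sectional:
sample IDs are scoped per stage and no longitudinal linkage is attempted
(both motivating study designs — a brain-bank disease cohort and a
developmental atlas — are cross-sectional).  Measurements may be missing at
the (stage, sample, region) level; missingness is represented by an
explicit boolean mask, never by sentinel values, and every operation
averages over observed entries only.  A minimum-regions-per-sample filter
(`min_regions`, the generalization of keeping only samples covered in at
least three regions) can drop thin samples up front; emptying a stage this
way is a fatal error, since every downstream contrast needs all stages.

Stage `t = 0` is the biological reference (healthy controls, or the
earliest developmental window).  The loader moves the configured reference
stage to index 0, so all fold changes are defined against it.

## Region weighting

1. **Normalization.**  Per (stage, sample, gene), regional values are
   min-max scaled to `[1, a+1]` with `a = 3` (range [1, 4]).  The lower
   bound of 1 guarantees strictly positive stage means, so every fold
   change downstream is well defined.  A regionally constant profile maps
   to 1 everywhere (the scaled fraction is defined as 0), which keeps the
   degenerate case deterministic and inside the stated range.  The
   transform is invariant to positive affine rescaling of a sample's
   regional profile, which removes sample-level scale/offset artifacts; it
   also makes the weighting *relative*: a gene elevated in a subset of
   regions necessarily looks depressed in the complement.  Consequences of
   this relativity are flagged below where they bite.

2. **Weights.**  `FC[t, r, g]` is the ratio of the stage-`t` mean to the
   reference-stage mean of normalized values; `FC ≡ 1` at the reference
   stage.  Weights are `|log2 FC|` rectified at `log2 f` with `f = 1.5`,
   the conventional differential-expression fold-change cutoff: below the
   cutoff the weight is exactly 0.  Rectification is the core design
   point — signed log2 FC weights let up- and down-regulated regions cancel
   in the aggregation and produce near-zero denominators, whereas the
   rectified weights are nonnegative, so the aggregate is always a convex
   combination of the contributing regional values.

3. **Aggregation.**  `y_fc(t, i, g)` is the weighted mean of the sample's
   observed normalized regional values.  Two conventions close gaps the
   definition leaves open:
   * the reference stage, whose own fold changes are identically 1 and
     would carry zero weight, borrows per (region, gene) the mean adjusted
     weight of the non-reference stages, keeping it on the same weighted
     scale as the stages it is compared against;
   * any (t, i, g) whose available weights sum to zero (a gene with no
     differential region at that stage, or a sample missing all weighted
     regions) falls back to the arithmetic mean over its observed regions.
     Fallbacks are counted and reported (`fallback_count`); a large count
     is expected and harmless for genes whose regional pattern is
     individually variable, because stage-level fold changes then hover
     near 1.

**Pre-weighting screens.**  Weighting every gene is wasteful when most
genes do not change.  Two screens are provided: `per_region_de` runs the
moderated-t test within every region for every stage pair on the raw data
and keeps the union of significant genes (adjusted p ≤ 0.05 and fold
change ≥ 1.5 by default) — appropriate when informative genes shift
consistently within at least one region; and `top_fraction` ranks genes per
stage pair by the across-region mean `|log2 FC|` of normalized stage means
and keeps the top fraction `q` (default 0.05), the screen of choice when
region-level tests are underpowered or most genes change.  The pipeline
weights only prescreened genes; `prescreen_mode: none` disables this.

## Differential testing on the weighted matrix

The two-group test is the empirical-Bayes moderated t: pooled per-gene
variance `s_g²` with `d_g` degrees of freedom, a scaled-inverse-chi-square
prior `(d0, s0²)` fitted across genes by the method of moments on
`log s_g²` (trigamma inversion, Newton iteration; `d0` capped at 1e6 when
the observed spread of log-variances is consistent with a common variance),
posterior variance `(d0·s0² + d_g·s_g²)/(d0 + d_g)` and `d0 + d_g` degrees
of freedom.  Setting the prior df to 0 recovers the ordinary pooled t
exactly — the documented escape hatch.  Tests are two-sided; BH correction
is applied within each stage-pair contrast separately; the DEG union over
all unordered stage pairs (earlier stage as baseline) carries per-contrast
direction provenance.

One deliberate default deviates from the shared `f = 1.5` convention: on
the *weighted* matrix the pipeline applies only the significance gate
(`de_fc = 1.0`).  Weighted values live on the [1, 4] scale, where the
maximal achievable fold change is 4 and typical true effects move a value
from ≈2.5 to ≈2 or ≈3 — a 1.5-fold gate on this compressed scale would
discard genuinely differential genes whose fold-change evidence was already
enforced region-wise by the Eq.-style weights.  `select_degs` itself keeps
`f = 1.5` as its default for raw-scale use; the gate is one config knob
away for analysts who want it on weighted data too.

## Gene classes and eigen-features

DEG profiles are z-scored per gene (shape, not level, defines a class) and
clustered by k-means (10 restarts, seeded).  An optional 2-D t-SNE or UMAP
embedding can precede k-means; full-dimensional clustering is the default
for reproducibility, but the embedding route concentrates fuzzy,
hierarchically structured classes and is what the reference study uses —
mean silhouette over the full-dimensional profiles tends to favour a
coarse up/down split, whereas silhouette over the embedding resolves the
finer class structure.  k is chosen by maximal mean silhouette over
k ∈ [2, 8] unless pinned.  Classes are named ClusterA, ClusterB, … by
decreasing size (ties by smallest gene index) purely for determinism;
cluster identities are dataset-specific.

Each class is summarized by PC1 of its samples × genes submatrix.  Scores
are zero-mean over samples; the sign is fixed so PC1 correlates
nonnegatively with the class's mean expression profile.  The
variance-contribution rate (VCR = top eigenvalue over the eigenvalue sum)
measures how adequately one component summarizes the class; classes below
50% are flagged, following the usual adequacy benchmark for eigen-feature
summaries.  A singleton class is its own centered profile with VCR 1.

## Staging trees

CART with Gini impurity and minimum leaf size 2, grown fully and then
pruned top-down on the misclassification-risk scale: a split survives only
if it reduces training misclassification risk by at least `cp × R(root)`
(`cp = 0.05`).  Risk-scale pruning is the classification-tree convention
behind a "complexity parameter" and was validated against rpart on noise
benchmarks; impurity-scale (Gini) pruning at the same nominal cp prunes far
too little, because optimizing a split over hundreds of candidate
thresholds always finds spurious Gini gain.

Evaluation: repeated stratified cross-validation (20 repeats × 5 folds by
default; folds redrawn each repeat from the seeded generator), one-vs-rest
ROC/AUC from pooled held-out leaf class proportions, pairwise stage trees,
and a stability analysis that refits the tree on 100 stratified 80%
subsamples and counts recurrence of the tree *signature* — the sorted
multiset of split features.  Sorting (rather than preorder) makes the
signature canonical: two equally discriminative features tie at the root
and swap sides across subsamples, which is one tree identity, not two.
Thresholds are excluded from the signature deliberately; they jitter with
the subsample while the feature identity is the finding.

## Enrichment

Gene-set over-representation per class: upper hypergeometric tail
`P(X ≥ k)` for overlap `k` between a class of `n` genes and a set of `K`
members in a universe of `N`, BH-corrected within each class.  The universe
defaults to all genes surviving the dataset's background filter and is
overridable.  Gene sets come from user-supplied GMT files; no ontology
data ships with the package and no DAG propagation is attempted.

## The synthetic generator

The generator emulates the structure of stage × region brain expression
studies: log-normal baselines per gene, multiplicative stage × region
effects (`2^effect`, so log2 fold change is the natural effect unit),
log-normal measurement noise (default sd 0.2 log2 units), and per
(stage, sample, region) dropout with a floor of one observed region per
sample.  Planted gene classes share a carrier-region territory — modelling
co-regulated modules that occupy common regional real estate — and a
per-stage effect profile.  Two heterogeneity schemes cover the spatial
behaviour seen in real data:

* **fixed** — a deterministic fraction of carriers has the sign flipped,
  the "same gene up in one region, down in another" scenario;
* **mosaic** — carrier signs are redrawn per (stage, sample) with a
  class-level up-probability, shared across the class's genes: individuals
  differ in *which* regions are affected, the way regional disease burden
  varies between patients.  Mosaic classes are the only way to give
  class-level summaries realistic within-stage spread: with fully
  deterministic effects, min-max normalization plus weighting turns every
  planted class into a near-noiseless stage separator and CART split
  choice degenerates into tie-breaking.

The **reference study** (`reference_spec()`): three stages × 30 samples,
8 regions, 2000 genes, five planted classes of 120/110/100/90/80 genes.
Two classes are deterministic: `late_up` (effect only in the late stage,
carriers in 6 of 8 regions) and `prog_down` (down from the middle stage
onward) — these are the discriminative classes a staging tree should
anchor on.  Three mosaic classes (up-probabilities 0.75/0.75/0.25 on
different stage profiles) are robustly differential but individually
variable, so they separate stages only noisily.  Effects are ±2 log2
units, noise sd 0.2, dropout 5%.  The companion `reference_config()` uses
the top-fraction prescreen with `q = 0.30` (a quarter of the genes carry
planted effects, so a per-region test screen would miss the mosaic classes
whose regional means barely move, and `q` must sit above the planted
fraction) and the t-SNE embedding before k-means.

What passing the recovery checks on this generator shows — and what it
does not: it demonstrates that the implementation recovers planted
structure of the kind the method targets (heterogeneous regional effects,
individual mosaicism, missing regions) at realistic noise, but real tissue
data adds features the generator omits: correlated noise across genes and
regions, batch structure, library-size artifacts, non-log-normal tails,
and stages whose boundaries are themselves uncertain.  Results on the
synthetic study bound implementation correctness, not biological
performance.

The counterbalance demonstration deserves one note: on normalized data a
*deterministic* half-up/half-down gene gives the signed-weight scheme a
stable nonzero denominator (down-shifted regions get larger |log2 FC| on
the [1, 4] scale than up-shifted ones), so the signed scheme only breaks —
denominators crossing zero, aggregates escaping the [1, 4] hull — once
per-sample missing regions vary each sample's weight subset.  The shipped
fixture therefore includes 20% dropout, and separation is measured as
|stage-mean difference| / pooled within-stage SD, since raw mean
differences would reward the signed scheme's explosive out-of-range
values.

## Numerical conventions and degenerate inputs

* Duplicate (stage, sample, region, gene) rows are an error, never
  silently averaged.
* Fold changes are computed only where both stage means exist; undefined
  cells are excluded from the weight sum rather than imputed.
* `bh_adjust` is the exact step-up rule (sorted `p·m/rank`, cumulative
  minimum from the largest rank, capped at 1).
* Zero-variance genes in a two-group test: with shrinkage enabled the
  posterior variance is positive and the statistic finite; with shrinkage
  disabled the statistic is 0 (p = 1) when the means also agree and ±inf
  (p = 0) otherwise, and the gene is flagged.
* k-means and every other stochastic step take the config seed; t-SNE
  perplexity is clamped to (n−1)/3 for small gene sets.
* Tree fits inside CV/stability derive per-fit seeds from the run seed, so
  reports are reproducible end-to-end while split tie-breaking is not
  frozen to one arbitrary feature order.

## Problem sizes

Default test and acceptance runs use the reference study (2000 genes, 90
samples, 8 regions) and smaller toys; a full pipeline run at this size
takes a few seconds on one core, and the whole test suite runs in well
under a minute.  The data structures are dense numpy arrays; studies of
atlas scale (≈20k genes × ≈20 regions × ≈100 samples) fit comfortably in
memory at ≈1 GB.

## Known limitations

* Count-model testing (negative-binomial DE), covariate adjustment and
  multi-factor designs are out of scope; the moderated t assumes
  approximately Gaussian within-group variation on the analysed scale.
* The weighting is relative per sample: a gene uniformly elevated in *all*
  regions of a sample is invisible after min-max normalization.  Such
  global shifts must be caught before region collapsing if they matter.
* Cluster identities (which class ends up named ClusterB) are
  dataset-dependent; only the procedure, not the labels, is reproducible
  across datasets.
* Alternative weighting metrics (t-statistic or p-value based), ensemble
  tree models and imputation-based aggregation baselines are noted
  extension points, not implemented.
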