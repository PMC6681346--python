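# Methods

## The measurement model

Mild alkaline CuO oxidation of plant tissue releases sixteen phenolic
monomers that are quantified by GC–MS and normalized to total organic
carbon (g kg⁻¹ TOC). An internal standard (ethylvanillin) measures the
fraction of analyte surviving work-up; dividing every content by this
recovery fraction restores the pre-loss values. `phenotax` starts from
the quantified compound table — instrument-level processing (peak
integration, derivatization artifacts, co-elution) is out of scope.

The six diagnostic group sums are fixed linear aggregations:

- *p*-hydroxy = 4-hydroxybenzaldehyde + 4-hydroxyacetophenone +
  4-hydroxybenzoic acid
- vanillyl (V) = vanillin + 4-hydroxy-3-methoxyacetophenone + vanillic acid
- syringyl (S) = syringaldehyde + 3,5-dimethoxy-4-hydroxyacetophenone +
  syringic acid
- coumaryl (C) = *p*-coumaric acid + ferulic acid
- benzoic acids = benzoic + salicylic + phthalic acid
- hydroxy-benzoic acids = 3-hydroxybenzoic + 4-hydroxybenzoic +
  3,5-dihydroxybenzoic acid

4-hydroxybenzoic acid is a member of both the *p*-hydroxy and the
hydroxy-benzoic family. The package deliberately keeps both definitions
rather than renormalizing: the six sums minus the plain 16-compound total
equal that one compound's content, an identity the test suite enforces
exactly. Relative abundances divide each group sum by the plain total, so
the six fractions can sum slightly above 1. Note that "coumaryl" and
"cinnamyl" name the same family in the field literature; C/V means
coumaryl over vanillyl here.

The Shannon–Wiener index H = −Σ pᵢ ln pᵢ is computed over the sixteen
individual compounds (not the six groups), with pᵢ each compound's share
of the sample total and 0·ln 0 = 0. This compound-level reading is the
only one consistent with published per-species values, which exceed ln 6
but stay below ln 16. H is scale- and permutation-invariant.

## The Erica biomarker rule

A sample is called *Erica* when

    relative coumaryl > 0.20   (strict)
    0.05 ≤ relative benzoic ≤ 0.12   (closed interval)

The boundary semantics follow the published thresholds (a strict ">" for
coumaryl, a dash range for benzoic acids); `RuleResult` reports both
component decisions and the raw fractions so boundary cases can be
audited. Because both inputs are fractions, the rule is invariant to
overall phenol abundance — it survives the TOC normalization and
recovery correction unchanged.

## Clustering and ordination

Hierarchical clustering follows the standard chemometric recipe: Z-score
each feature (sample sd, n−1 denominator; constant columns map to zero
with a warning), Euclidean distances, Ward minimum-variance linkage, cut
at k groups. The default feature space is the sixteen absolute contents
in g kg⁻¹ TOC (recovery-corrected when the information is present); the
six group sums are available as an alternative (`level="groups"`).
Linkage is delegated to scipy; merge heights are reported as Ward cost
increments — the growth in total within-cluster sum of squares caused by
each merge, i.e. scipy's cophenetic distance squared over two — because
"Ward height" conventions differ between implementations and the cost
increment is the one with a direct variance interpretation.

PCA is computed by SVD of the centered matrix. Loadings are orthonormal,
explained-variance fractions are non-increasing and sum to ≤ 1, and each
component is sign-fixed so its largest-magnitude loading entry is
positive, making results reproducible across platforms.

## Trees and forests

CART trees are grown by recursive binary partitioning on Gini impurity
1 − Σ (n_c/n)². Candidate thresholds are midpoints between consecutive
distinct sorted values of each feature; the split maximizing the weighted
impurity decrease wins; both children must keep at least `min_leaf_size`
samples; values ≤ threshold route left. In the deterministic single-tree
API ties break by (feature order, lower threshold). Inside the forest,
per-split candidate features are drawn without replacement (mtry =
⌊√p⌋ by default) and scanned in draw order, so exact ties — common in
small, deep nodes — fall to a random candidate rather than systematically
to low-index features; with the seed fixed the ensemble is still
bit-reproducible. This distinction exists because an always-first-feature
tie-break measurably biases impurity importances toward early columns on
pure-noise data.

The forest bags trees on bootstrap resamples of size n and predicts by
majority vote, ties going to the class of lower sorted order. Feature
importance is the classical mean decrease in Gini: each split contributes
its impurity decrease weighted by the fraction of that tree's training
samples reaching the node; contributions are summed per tree, averaged
over trees, and normalized to sum to 1. The "representative tree" is the
member whose own predictions agree most with the ensemble vote on a
reference matrix (lowest index on ties).

The default ensemble size for end users is large (the `train` subcommand
defaults to 500 and accepts any count, e.g. the 10,000 used in published
figures of this kind); tests and the evaluation harness use 25–500 trees,
where ensemble statistics at p = 6–16 features have long stabilized.

## Evaluation harness

Train/test splits are stratified per class with largest-remainder
rounding toward a training size of ⌈fraction · n⌉ — chosen so the
canonical 2/3 split of 47 binary-labelled samples trains on exactly 32 —
with every class keeping at least one sample on each side where possible;
singleton classes go to training with a warning. Within a (fraction,
replicate) cell all algorithms share the same split, making comparisons
paired; per-cell seeds derive deterministically from the master seed via
`SeedSequence`. Default grid: fractions {0.5, 0.6, 2/3, 0.8} × 5
replications. Scores are accuracy and binary F1 with *Erica* positive
(F1 = 0 by convention when precision + recall = 0, warned when vacuous).
Cross-validation uses stratified folds whose sizes differ by at most one;
every sample is tested exactly once. Algorithm failures are recorded per
cell, not raised. The built-in algorithms are the package's own random
forest and single CART tree ("recursive partitioning"); an SVM backed by
scikit-learn joins the comparison when that library is importable, and is
deliberately not re-implemented here. The adjusted Rand index (used to
score cluster recovery against species labels) is implemented in-package
by pair counting and cross-checked against scikit-learn in the tests.

## Synthetic data generator

No per-sample compound table is published for the six Bale Mountains
taxa, so the generator emulates the study design: sample counts 29
*Erica*, 5 *Alchemilla*, 7 *Festuca*, 4 *Helichrysum*, 1 *Kniphofia*,
1 *Lobelia* (47 total, scalable by an integer factor) and mean total
phenol contents of 18, 16, 22, 6, 22 and 51 g kg⁻¹ TOC respectively for
Alchemilla, Erica, Helichrysum, Kniphofia, Lobelia and Festuca.

Per sample: composition ~ Dirichlet(c · mean composition), total ~
log-normal with the species mean and CV, true contents = composition ×
total, recovery ~ Uniform(0.70, 0.95). The *stored* contents are the
post-loss values (true × recovery) with the recovery fraction recorded,
so the correction stage is exercised end to end and is exactly
invertible.

Species mean compositions are synthetic. They are constrained by the
qualitative field picture: Erica alone satisfies both biomarker windows
(coumaryl mean 0.28; benzoic mean 0.085, centered in [0.05, 0.12]);
Festuca is coumaryl-rich (0.33, about one third of its phenols) and
syringyl-rich with low vanillyl and benzoic acids; Helichrysum has the
highest and Erica the lowest *p*-hydroxy share; Kniphofia and Lobelia are
benzoic-rich; Kniphofia is the most even profile. Each group fraction is
spread uniformly over the group's member compounds, with
4-hydroxybenzoic acid allocated once (under *p*-hydroxy).

**Dispersion defaults are a deliberate idealization.** The Dirichlet
precision is 800 and the total-content CV 0.05. At these values the
group-level within-species sd (≈ √(f(1−f)/(c+1)) ≈ 0.01 for f ≈ 0.1)
leaves the rule thresholds more than 3 sd from Erica's means, and Ward
clustering of the 47-sample default dataset recovers the species
partition essentially every seed. Looser, more life-like dispersion
(precision 150–250, CV 0.2–0.3) was examined first: the rule classifier's
recall drops toward 0.86–0.91 and — more fundamentally — cluster recovery
collapses (mean ARI ≈ 0.4), because after Z-scoring, the columns are
dominated by Festuca's large absolute contents and the 29-sample Erica
cloud splits before the centroid-like Kniphofia singleton is isolated.
That noisier regime is the realistic one — field studies of this kind
report exactly such failures of clustering to separate congeneric
material — but this package's synthetic dataset exists to verify the
pipeline's mechanics, so its default must make the reference structure
recoverable. Consequently, passing tests demonstrate correctness of the
computations, **not** that real plant material is this separable; both
parameters are per-species fields in `SpeciesSpec` for anyone wanting the
harder regime.

Known limitations of the generator: within-group compound-level
unevenness is not modelled (fractions are uniform across group members),
so per-species diversity indices cluster high (≈ 2.4–2.76) and do not
reproduce published orderings in which *Helichrysum* is the least even
taxon; compound-level covariances beyond the Dirichlet's are absent; no
instrument noise or detection limits.

## Numerical conventions

- CSV output keeps 12 significant digits; read∘write is the identity to
  1e-9.
- Compound column names match case-insensitively after dash/underscore
  normalization and a synonym table covering the spelling variants of
  3,5-dimethoxy-4-hydroxyacetophenone and friends.
- Splits with no impurity decrease (≤ 1e-15) are rejected; a node with
  fewer than 2·min_leaf_size samples becomes a leaf.
- Degenerate inputs fail loudly: empty profiles for diversity or relative
  abundances, zero vanillyl for proxy ratios, all-identical rows for PCA,
  fewer than two samples for Z-scoring.
- All randomness flows from integer seeds through
  `numpy.random.SeedSequence`; derived seeds stay below 2³¹.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at deliberately modest
sizes: 47–470 synthetic samples, forests of 25–500 trees, a
planted-threshold dataset of n = 1000, and 20-seed replications for the
importance-ranking rate. These sizes are far past the point where the
checked statistics stabilize for 6–16 features, and keep the whole suite
in the tens of seconds.
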