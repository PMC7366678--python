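# Methods

`lungregen` implements the bespoke computational procedures of a
time-resolved single-cell study of lung injury and regeneration
(bleomycin model): whole-organ scRNA-seq sampled at a control day 0 and
several post-injury days with a few replicate mice per time point,
validated against matched tissue bulk RNA-seq and proteomics.  This note
documents each model, its assumptions, the tunable parameters, and the
choices made where the design was genuinely open.

## Temporal differential detection (binomial spline LRT)

**Model.** For one gene in one cell type, let `k_s` be the number of
cells with nonzero UMI count and `n_s` the number of cells of that type
in mouse sample `s`.  The detection rate is modeled as a binomial GLM at
the *sample* level — the effective sample size is the number of mice,
not the number of cells, which protects against pseudoreplication:

    k_s ~ Binomial(n_s, p_s)
    logit(p_s) = beta_0 + o_s + f(t_s)        (full model)
    logit(p_s) = beta_0 + o_s                 (null model)

`o_s` is the log of the sample's mean total UMI per cell (of that cell
type), entering as a fixed-coefficient offset: deeper libraries detect
more genes at equal expression, and standard GLM offset semantics absorb
that.  `f` is a natural cubic spline of time with `df = 2` columns.
Significance is a likelihood-ratio test, `Lambda = 2(l_full − l_null)`
clipped at 0 and referred to chi-square with df equal to the number of
spline columns.  Control (PBS) samples enter at time 0.

**Spline basis.** The basis follows the R `splines::ns` convention:
boundary knots at the observed time extremes, `df − 1` interior knots at
quantiles of the time vector, cubic B-splines with the two
second-derivative-at-boundary constraints removed by a null-space
projection, linear extrapolation beyond the boundaries.  A natural
cubic spline with boundary knots only spans `{1, t}` — one non-intercept
column — so `df = 2` requires one interior knot; any statement that two
non-intercept columns arise without interior knots is geometrically
impossible, and the quantile-knot rule is used (and is configurable).
The returned columns are orthogonalized against the constant via the
Gram matrix of the evaluated basis, which depends only on the multiset
of times, making the basis permutation-equivariant.  The LRT is
invariant to the choice of basis of the spanned space.

**Fitting.** Fits are a batched Newton/IRLS solver written here: the
design matrix is shared across genes, so per-iteration work is one
batched 3x3 (or 1x1) solve per gene; 2000 genes across 28 samples fit in
tens of milliseconds.  Convergence is gradient max-norm < 1e-8 or 100
iterations, with steps damped to ±10 and the linear predictor clipped at
±30 so boundary fits (all-zero or all-one detection) stay finite.
Non-convergent or separated genes are refitted with a weak ridge
(1e-6) on non-intercept coefficients and flagged; their p-values are
retained but marked.  `statsmodels` GLM serves as an independent oracle
in the tests (coefficient agreement to 1e-6), never as the
implementation.

**Ambient masking.** Droplet data carries ambient RNA from lysed cells,
which produces spurious "everywhere-regulated" genes.  For a supplied
candidate ambient gene list, p-values are set to 1 in every cell type
where the gene is not simultaneously a positive marker of that type
(marker adjusted p < 0.1 and positive average log fold change); masking
precedes multiple-testing correction and is idempotent.  Ambient genes
are an input here: the inference of the list itself (from empty-droplet
profiles) is out of scope, and the synthetic generator plants the list
as ground truth.

**Multiple testing.** Benjamini–Hochberg within each cell type's test
family (the family choice is not dictated by the procedure; a global
family is available by flag).  A gene is called injury-regulated when
FDR < 0.1 in at least one cell type.

**Calibration.** Under a simulated null (constant detection probability,
28 samples over 7 time points, 30 cells per sample), empirical type-I
error at alpha = 0.05 is ≈ 0.05 and BH at FDR 0.1 yields an expected
false-discovery proportion ≤ 0.1; planted logit-scale detection shifts
of amplitude 2 are recovered for ≥ 80 % of planted genes, with power
monotone in the shift over {0.5, 1, 2}.  These are the study sizes used
throughout the tests and the acceptance script.

## Preprocessing

Barcode filtering reproduces the droplet workflow rules: per sample the
top 1200 barcodes by total UMI are kept (the expected ~1000 cells plus
headroom, applied *before* other filters), then barcodes with < 200
detected genes are dropped; cells with > 10 % mitochondrial counts
(prefix `mt-`, configurable) or ≥ 5000 total UMI (likely doublets;
3000 for sorted-cell designs) are removed.  All filters are idempotent.

Normalization is `ln(1 + count / cell_total × 10⁴)`; the scale factor is
the convention of the workflow being reproduced (not stated by it
explicitly).  Marker discovery is one-vs-rest Wilcoxon rank-sum on the
normalized values, restricted to genes detected in > 10 % of the
cluster's cells and with |avg log FC| ≥ 0.25, where avg log FC is the
difference of mean normalized (natural-log) expression, in minus rest;
BH within cluster.  The rank-sum test is exact when both groups have
≤ 25 cells and the pooled values are tie-free, otherwise the normal
approximation with tie correction; both branches are checked against
hand-written oracles (exhaustive enumeration, tie-corrected z).

## Bulk deconvolution (marker-set KS enrichment)

A cell type whose frequency rises between conditions drags its marker
genes' bulk fold changes upward.  Per cell type, markers with positive
log FC and adjusted p < 0.25 are compared against all other genes'
fold changes with a two-sided two-sample Kolmogorov–Smirnov test;
p-values are floored at 1e-50.  Direction is read from the mean marker
fold change (the volcano x-axis); sidedness is not dictated by the
procedure and two-sided is used.  When fold changes are not supplied,
they are computed as log2 ratios of (CPM + 1) condition means.

The calibration null holds composition exactly fixed between conditions
(no mouse-to-mouse composition jitter): with random per-mouse
composition variability the KS correctly flags the resulting real
frequency differences, which is signal, not miscalibration.

## Receptor–ligand communication networks

Given marker sets per cell type and a ligand–receptor catalog, a
directed edge A→B collects the catalog pairs whose ligand is a marker of
A and receptor a marker of B; weight = pair count; self-edges are
allowed.  The phrase "shared a pair between them" is direction-ambiguous
in the source procedure, so the undirected union is the default summary
and the directed view is kept internally.  Edge dynamics annotate each
edge with the fraction of supporting pairs whose ligand (in the source)
or receptor (in the target) is injury-regulated at temporal FDR < 0.1
(threshold configurable).  Focal connectomes sum both directions between
one state and each partner.  All counts are checked against exhaustive
double-loop oracles and planted catalog truths, exactly.

## Transitional-state orthogonality (in silico doublets)

Pure pseudo-bulks sum 600 randomly drawn cells per cluster, five
replicates; "doublets" sum 300 cells from each of two parents.  All
samples are jointly normalized and subjected to PCA; in the top-2 PC
space each sample's relative off-line distance rho is its perpendicular
distance to the *segment* joining the parent centroids divided by the
centroid distance (the segment, not the infinite line, so states beyond
either parent also register).  A true mixture has small rho; a state
with its own program maps off-axis.

Normalization: the default is log2(CPM + 1), matching the PCA view of
the original analysis (precision weights are omitted; at five samples
per group they do not change the geometry).  One caveat is intrinsic to
log space: a *count-space* mixture is not an affine combination after a
concave transform, so even noiseless doublets sit slightly off the
log-space segment (Jensen curvature, ~0.1–0.25 of the axis when parents
differ strongly).  With a genuinely orthogonal query state present the
top PCs align with the parent axis and the query program, the curvature
direction drops out, and doublets score rho ≈ 0.07 vs ≈ 0.8 for the
query.  For exact mixture geometry `normalization="cpm"` is provided:
in linear CPM space a count mixture is an exact convex combination and
noiseless doublets have rho = 0 to machine precision.  Both views are
tested.

## Splice-ratio induction test

Per cell, `r = log2((u + 1) / (s + 1))` for a gene's unspliced and
spliced counts (one added to both to avoid division by zero); groups are
compared with the two-sided Wilcoxon rank-sum described above.  A
transcriptionally inducing gene carries an elevated unspliced fraction,
so baseline days (0 and late recovery) test lower than induction days.

## Signature scoring and assignment

Bulk-derived signatures (gene, log FC, optional p) are scored per cell
as the Pearson correlation between the signature's log fold changes over
its top-500 genes (ranked by p-value, ties by |log FC| — the ranking key
is not dictated; intersected with the cell universe) and the cell's
gene-standardized expression.  Cells take the best-scoring label only
when it beats the runner-up by strictly more than 0.05; ties and narrow
margins are "unassigned".  Module scores are mean expression of a gene
set minus the mean of expression-bin-matched control genes (25 bins, 50
controls per set gene, seeded sampling), so high-expression sets are not
trivially enriched.

## Multi-omic integration

RNA modalities are put on voom-style log2 CPM
(`log2((count + 0.5)/(total + 1) × 1e6)`); proteomics-like profiles
enter as log intensities.  Profiles are merged on the exact-match shared
gene set and quantile normalized: each sample's values are replaced by
the cross-sample mean order statistic at its rank, ties receiving the
average of the spanned values; sorted columns are exactly equal
afterwards (on tie-free data) and within-sample ranks are preserved.
PCA is column-centered SVD with a deterministic sign convention
(largest-|loading| element positive).  On the simulated three-modality
triplet the top components separate modalities and one of the top three
separates conditions (point-biserial |r| > 0.9), reproducing the
structure the integration is meant to reveal.

Fold changes measured with error on both axes are compared by Deming
regression with error-variance ratio lambda (default 1 = orthogonal
regression; configurable):

    slope = (s_yy − λ s_xx + sqrt((s_yy − λ s_xx)² + 4 λ s_xy²)) / (2 s_xy)

At λ = 1 this equals the total-least-squares slope (checked against an
SVD oracle); with symmetric noise it recovers a true slope of 1 where
ordinary least squares attenuates below 0.95.

## Synthetic data generator

The generator emulates the study's data structure, not its biology:

* **Design**: control day 0 plus days 3, 7, 10, 14, 21, 28; 4 replicate
  mice per time point (28 samples); ~1000 cells per mouse; 10–30 cell
  types.  Tests and the acceptance script use smaller gene/cell counts
  per scenario; the per-scenario sizes are stated in the test docstrings
  and are the package's own choices.
* **Expression**: per-type multinomial profiles share a gamma baseline
  with lognormal type-specific deviations (`type_divergence`, default
  0.7 — between-type profile correlations comparable to distinct lung
  lineages) and planted markers elevated `marker_fold` (default 10×).
  Counts are gamma-Poisson (negative binomial, `dispersion` default 0.3)
  around the profile scaled by a lognormal library size
  (`mean_umi_per_cell` default 1500).
* **Ambient RNA**: a fixed multinomial background concentrated on a
  planted ambient gene set is mixed into every cell
  (`ambient_fraction`, default 0.1), reproducing the
  cell-type-ubiquitous false signal the masking rule exists for.
* **Temporal genes**: detection is gated by an explicit Bernoulli on the
  logit scale (`temporal_effect`, default amplitude 2, along a smooth
  injury bump), so the planted quantity is exactly what the detection
  model estimates.  A lighter generator draws sample-level binomial
  detection summaries directly for calibration/power studies.
* **Frequencies**: smooth softmax trajectories with a random subset of
  injury-responsive types carrying logit-scale bumps (transient
  expansions such as M2 macrophages or myofibroblasts); planted
  per-sample truth is recorded and recovered to < 0.02 at 5000
  cells/sample.
* **Matched bulk triplet**: three modality matrices share a planted
  condition effect on a recorded gene set with modality-specific
  offsets and noise; RNA modalities are Poisson counts, the
  proteomics-like matrix is Gaussian log intensities.
* **Catalog**: ligand–receptor pairs planted between marker sets with
  recorded per-edge counts, plus non-marker decoys that span nothing.

Everything is driven by `numpy.random.default_rng` under a single seed;
two runs are bit-identical.

**What passing tests do not show.** The generator has no batch effects,
no doublet barcodes inside droplets, no mitochondrial content structure,
no correlated gene programs beyond markers/temporal genes, and its
temporal genes follow smooth unimodal curves.  Recovery results
therefore demonstrate correctness of the procedures under the assumed
data structure, not performance on real tissue data.

## Pipeline

`lungregen run --config config.yaml` chains
simulate → preprocess → temporal-de → deconvolve → communicate →
doublet-test → score → integrate.  One global seed is expanded into
per-stage substreams (SeedSequence spawning), so a stage rerun in
isolation reproduces its in-pipeline output; the run report records
seeds, applied thresholds, row counts and SHA-256 checksums of every
artifact, and two runs under one seed are checksum-identical.  Unknown
config keys are rejected.  Exit codes: 0 ok, 1 validation error, 2
runtime error.

## Known limitations

* Chi-square reference for the LRT is asymptotic in the number of
  samples (28 here); calibration is verified empirically at that size,
  smaller designs may be conservative or liberal.
* The KS deconvolution detects distributional difference of marker fold
  changes, which includes variance effects, and gives no absolute
  proportion estimates.
* rho thresholds for "orthogonal" are validated only on synthetic
  constructions; the log-space mixture curvature discussed above is an
  inherent property of the normalization, not removable by tuning.
* Marker discovery assumes labels are given; embedding, clustering and
  annotation are outside the package.
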