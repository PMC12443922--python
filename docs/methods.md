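# Methods

This note documents the models and numerical choices behind
`geomxpurity`, in the order the pipeline runs them, together with what the
synthetic cohort does and does not emulate.

## Synthetic cohort

The generator (`geomxpurity.synthetic.simulate_cohort`) draws a cohort of
`n_patients = 30` patients; a `paired_fraction = 0.9` subset contributes
both a primary and a recurrent tumor, and two thirds of patients are
labelled treated (their recurrence received therapy). Each tumor yields
`aois_per_tumor = 3` ROIs, each contributing one SOX2+ and one IBA1+ AOI —
roughly 340 AOIs per cohort.

Expression is built from disjoint planted gene modules over a shared
baseline. Each gene has a baseline log2 level drawn from N(5, 1.5²);
a `background_fraction = 0.3` of genes is unexpressed and sits at the
background level shared with the negative probes (so the two-SD
negative-probe filter has a meaningful target). Cell-type programs elevate
their module genes by `module_elevation = 2` log2 units: each tumor's
malignant program expresses one dominant malignant state (of MES/AC/OPC/
NPC) plus the cell-cycle modules; the TAM program expresses the TAM module
and per-tumor random weights on four myeloid programs; the oligodendrocyte
program its own module. A random 30% of patients carry a
patient-intrinsic interferon elevation across settings, mirroring the
observation that interferon activity tracks patients rather than
treatment. A SOX2+ AOI's mean expression is
`purity · malignant + (1 − purity) · (0.7 oligo + 0.3 TAM)` with purity
drawn from `purity_grid`; IBA1+ AOIs are a fixed 0.1/0.9 oligo/TAM
mixture. The hallmark dosage (default 1.5× on chromosome 7, 0.5× on
chromosome 10) multiplies *every* gene on those chromosomes in the
malignant program only — broad events are what moving-average CNV
inference detects — and the planted signature modules are deliberately
placed off chromosomes 7 and 10 so cell-type composition cannot be
mistaken for a hallmark event in the ground truth.

Counts are negative-binomial (Gamma–Poisson) with dispersion
`nb_dispersion = 0.1` around `library size × relative expression`, library
sizes lognormal with σ = 0.4 around 10⁵, and a per-batch location/scale
distortion applied on the log2 scale (two batches by default). The panel
size default is 18 000 genes with 139 negative probes, the scale of a
whole-transcriptome GeoMx panel; chromosome-level CNV scores average
~500 retained genes each, which is what makes hallmark calling reliable at
the default ±0.15 thresholds.

What the generator does **not** emulate: spatial coordinates, probe-level
effects, gene–gene correlation beyond module structure, segmentation
spill-over between adjacent AOIs, and genes whose cell-type programs
overlap. Passing planted-truth tests therefore demonstrates the
*algorithms* recover the structure they model, not that real GeoMx data
satisfy these assumptions.

## Gene filter, normalization, batch correction

Negative-probe statistics are pooled over probes and AOIs to one
background mean m and SD s (a single global limit of detection). A gene is
retained iff `mean > m + k·s` **or** `variance > (m + k·s)²` with `k = 2`;
comparing the variance against the squared threshold keeps the two rules
unit-consistent. The filter runs on raw counts, before normalization, and
provenance flags record the order.

Quantile normalization is the classic algorithm: each column is mapped
onto the across-column mean of the order statistics, ties receiving the
mean of the reference values their positions span. It is exactly
idempotent on tie-free data; with ties the output multisets agree up to
tie-averaging. Normalized values are log2(x + 1); the pseudo-count-1, base-2
transform is required downstream (log-ratio CNV tracks, Z-scores).

Batch correction is parametric empirical-Bayes location/scale adjustment:
per gene, data are standardized against a design of batch indicators plus
protected biological covariates (arm, setting; a covariate confounded with
batch is dropped with a warning); per-batch gene-wise means and variances
are shrunk toward batch-level normal / inverse-gamma priors with
method-of-moments hyperparameters and iterative conditional updates to a
1e-8 tolerance. Two deliberate choices:

* all variance estimates are floored at 1e-12 so the degenerate
  (noise-free) case — a pure constant shift between batches — is corrected
  exactly rather than producing 0/0;
* after adjustment each gene's grand mean is restored exactly. Shrunk
  batch offsets do not generally average to zero, so textbook ComBat can
  shift a gene's overall level; the restoration makes correction purely a
  between-batch operation.

Because correction estimates its adjustments from the data, per-gene batch
F-statistics after correction sit *below* the null median (the planted
signal plus part of the noise is removed); the acceptance checks assert
this deflation rather than a two-sided match to the null.

## Expression-inferred CNV

For each query (SOX2+) AOI, per-gene log-ratio = query log2 expression −
mean reference log2 expression, the reference being the IBA1+ compartment
(the available non-malignant population, matching the reference-cell
design of expression-CNV tools). When batch labels are given, the
reference mean is computed within the query's experimental run, so any
residual run-level gene bias cancels in the ratio. Ratios are centered by
the AOI's genome-wide median **before** clipping to ±3 — centering first
preserves invariance to a constant offset of the query AOI — then smoothed
by a centered 101-gene moving average within each chromosome (the window
shrinks at chromosome edges; no smoothing crosses a boundary), and
re-centered. Chromosomes with fewer than 3 genes are dropped; a window
larger than the smallest analyzed chromosome is an error.

The per-chromosome score is the mean smoothed log-ratio;
`chr7_gain = score7 > 0.15` and `chr10_loss = score10 < −0.15` (strict
inequalities, thresholds configurable). A 2-group Ward clustering on the
(chr7, chr10) score pairs is reported alongside the threshold calls,
because the corresponding step of the original workflow was
analyst-supervised: the artifact exposes both signals rather than hiding a
heuristic. Window, clip and thresholds are free parameters of the method;
the defaults are validated by planted-truth recovery in the test suite.

## Purity filter

Signature scores entering the filter are re-standardized (Z) across the
evaluated population, so thresholds are in population-SD units and a
population of identical scores maps to all-zero Z. A SOX2+ AOI is excluded
iff it has **no** hallmark call AND (oligodendrocyte Z > 1 OR TAM Z > 1)
AND max malignant-state Z < 0. The malignant criterion takes the maximum
over state signatures because malignant states are alternatives — a tumor
cell need express only one. CNV evidence always dominates; no
hallmark-positive AOI can be excluded. IBA1+ AOIs are kept iff TAM Z ≥ 0
(boundary inclusive). A tumor whose SOX2+ AOIs are all excluded is
reported excluded, with counts per arm and setting. The exact decision
boundary in the motivating workflow was analyst-driven; both thresholds
are configuration, and the defaults (1.0 / 0.0) are validated against
planted truth (sensitivity ≈ 0.9–0.95 for purity-0 AOIs, specificity 1.0
for malignant AOIs in the default cohort).

## Signature scores

A signature score is the mean over the signature's present genes of the
per-gene Z-score computed across an explicit population — the population
actually being compared (e.g. surviving recurrent SOX2+ AOIs), not the
whole dataset. Zero-variance genes contribute 0 with a warning; a
signature with under half its genes present warns; an empty intersection
is an error. Tumor-level scores are unweighted means over the tumor's
surviving AOIs (Z-scores are computed at AOI level first, then averaged;
the alternative order is not used and the provenance records this).
Published signature gene lists are supplied as GMT inputs with a YAML role
sidecar, never embedded in the package; synthetic tests use planted
modules.

## Differential expression

Pseudobulk counts are raw-count sums over each tumor's surviving AOIs of
one segment. The two-condition test is a negative-binomial Wald GLM per
gene: median-of-ratios size factors (geometric-mean reference over genes
positive in all samples; a positive-count fallback applies below 10 such
genes, with a warning); a log-link GLM `intercept + condition` with the
log size factor as offset, fitted by IRLS vectorized across genes;
gene-wise dispersion by maximizing the Cox–Reid-adjusted profile
likelihood on a 31-point log-spaced grid (1e-4 … 10) with parabolic
refinement; a lowess mean-dispersion trend in log-log space; and shrinkage
of log-dispersion toward the trend with weights (residual df) : (prior
weight = 10). No outlier replacement and no independent filtering are
performed, for determinism.

Wald p-values use a **t reference with residual degrees of freedom**
(n − 2) rather than a normal reference: with six tumors per arm the normal
reference is measurably anticonservative (null p < 0.05 fraction ≈ 0.065
and sporadic false discoveries after FDR), while the t reference restores
calibration (≈ 0.036, with zero q < 0.05 genes in 19/20 null cohorts).
This is the package's small-sample choice and is recorded here rather than
hidden. BH correction is applied across tested genes; all-zero genes are
excluded and reported.

## Mixed models and contrasts

The group-comparison model is `y = group + (1 | patient)` with cell-means
coding. The variance ratio λ = σ²_patient/σ²_residual is profiled out of
the REML criterion and its score equation is solved by bracketed
root-finding on the analytic profile gradient (Woodbury block forms; the
envelope theorem removes the β dependence). This locates the optimum to
machine precision — the balanced paired design reproduces the classical
paired-t statistic to ~1e-15 — and the boundary λ = 0 falls back to OLS
with a note. Degrees of freedom are containment
(n − rank([X Z])), chosen because they are fully specifiable without
numerical Hessians; for the paired two-group design they equal the paired-t
df. Estimated marginal means are the fitted cell means (no covariates);
all pairwise contrasts are Tukey-adjusted via the studentized-range
distribution with the containment df; with two cells the adjustment is the
identity. Constant responses yield zero variance components and unit
p-values rather than errors.

## Exact rank tests

The signed-rank test drops zero differences, mid-ranks tied absolute
differences, and for n ≤ 25 enumerates the null of W⁺ over all 2ⁿ sign
assignments by polynomial (dynamic-programming) convolution on doubled
ranks — exact even with ties; two-sided p = 2·min(P(W ≤ w), P(W ≥ w))
capped at 1. Seven pairs all moving one way give p = 2/128 = 0.015625.
Larger n uses the tie-corrected normal approximation without continuity
correction. The rank-sum test enumerates the rank-sum distribution by the
standard subset-sum recursion when m + n ≤ 20 without ties, and otherwise
uses the tie-corrected normal approximation.

## IHC positivity

A cell is included iff area ≥ 20 µm² (cells strictly smaller are removed,
so the boundary is kept) and positive iff mean DAB OD strictly exceeds
0.3 — the strict-threshold convention is adopted because no boundary rule
is standard, and it is documented here. "Area" is whatever the upstream
image software exported (nucleus or expanded-cell area); the module makes
no assumption. ROI percentages are positives over included cells; tumor
values are unweighted means over ROI percentages (so a cell-rich ROI does
not dominate its tumor). Group comparisons use the exact tests above and
report medians and IQRs.

## Problem sizes and determinism

Default test and acceptance runs use the full 18 000-gene panel
(~340 AOIs, seconds per stage); null-calibration suites use 2 000-gene
pseudobulk cohorts over 20 seeds. Every stochastic component draws from a
single `numpy` Generator seeded from its config, and identical
configuration gives bit-identical outputs. The pipeline writes plain TSV
intermediates and a JSON manifest with a SHA-256 hash per output, so
deterministic stages can be verified by hash equality across reruns.

## Known limitations

* The CNV module detects broad (chromosome-scale) events only; no HMM
  subclone states and no focal-amplification detection.
* ComBat is implemented in its parametric form only.
* The DE module supports exactly two conditions with an intercept design;
  no continuous covariates.
* The mixed model supports one random intercept (patient) and a single
  categorical fixed factor of at most four cells — exactly the designs the
  pipeline needs.
* The IHC module consumes per-cell feature tables; nucleus detection,
  cell expansion and artifact exclusion belong to upstream image software.
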