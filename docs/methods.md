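# Methods

This note documents the models, defaults and design choices behind the
silkgland pipeline and its synthetic data generator: what is simulated, how
each inference stage works, and where conventions had to be fixed.

## The synthetic gland and fiber

The generator emulates a silk gland whose tail/sac epithelium carries eight
cell types — three in zone A (`ZoneA_MaSp1`, `ZoneA_MaSp2`, `ZoneA_SpiCE`),
one in zone B (`ZoneB_MaSp3`), one in zone C (`ZoneC_SpiCE`), one shared
(`ZoneABC`) and two duct types — and a three-layer fiber whose layers derive
from the zones (A→core, B→middle, C→outer). All labels are retained as a
`GlandTruth` object so downstream inferences can be scored exactly.

**Gene programs.** Of 2,000 genes, each cell type owns 30 marker genes with
a log2 effect of 3.0 over a unit baseline; 60 genes are head-specific, 60
belong to other gland types, 100 are near-silent (baseline 0.001, to
exercise the TPM prefilter) and the rest are flat background. Marker genes
additionally carry a shared gland-wide elevation (log2 2.5 in every gland
cell type) and a body "leak" (log2 1.0 in whole-body samples). Both terms
are properties of the emulated biology rather than tuning knobs: whole-body
samples physically contain the gland, and silk genes dominate gland
transcriptomes as a group, which is what makes the first principal component
of the gland-vs-body comparison a gland-identity axis (in the real analysis
it explains ~77% of the variance). With a weak shared program the synthetic
step-2 PCA instead picks up within-gland part contrasts and the sign filter
misbehaves in ways the real data does not.

**Counts.** All count assays are negative binomial (gamma–Poisson) with one
dispersion per assay (default 0.1 everywhere); sequencing and
spectral-count assays are overdispersed but no quantitative noise model is
available for this system, so these defaults are stand-ins, not estimates. Bulk tissues are mixtures of cell-type programs: tail averages
the three zone-A positional classes, sac mixes A-distal/B/C (0.4/0.3/0.3),
duct the two duct types; five replicates per tissue, mean 50 counts per
baseline gene. Cells (3,000 over 5 samples) draw from their type's program
with log-normal depth (sd 0.3). Spatial spots (6 sections × 13 regions × 11
spots ≈ 858) draw from mixture-weighted programs per positional class; the
zone-A mixtures encode the proximo-distal gradient (ZoneA_MaSp2 0.60 →
0.30 → 0.10 across proximal/middle/distal, ZoneA_MaSp1 rising 0.15 → 0.50).
Eleven tail cross sections span perimeters 300–1500 px so both split
thresholds (500/1000 px) are exercised.

**Fiber proteomics.** Eighteen silk proteins (MaSp1a–c, MaSp2b/c/e/f,
MaSp3a/b, MaSp4, AmSp-like1/2, SpiCE-LMa1–6) carry layer-dependent logistic
extractability in urea molarity, p = logistic((c − m)/s), with midpoints
1.5 M (outer), 3.5 M (middle), 6.0 M (core) and slope 0.7. Spectral counts
are multinomial (10,000 spectra per sample, 3 replicates) over
abundance × extractability, with log-normal per-replicate abundance jitter
(sd 0.05). Formic-acid-dissolved controls replace the layer term with a
protein-specific solubility factor (log-normal, sd 0.3). Gland samples add
contaminant proteins lacking signal peptides; a benchmark mode replaces
them with 200 contaminants in four groups of 50, each violating exactly one
identification criterion.

Default abundance shares are core 64% / middle 25% / outer 11%. This
deliberately differs from the printed dissolved-fiber composition
(MaSp1 46 / MaSp2 20 / MaSp3 30 / MaSp4 1%): with the logistic midpoints
above, a 30% middle share makes the middle layer's *relative* abundance at
2 M far exceed its 8 M value (outer proteins are too rare to dominate the
2 M supernatant), which would misclassify it as 2M-enriched. Requiring the
middle layer's expected relative abundance to be equal at 2 M and 8 M —
the regime in which it peaks at 4 M, as observed — fixes the outer share at
≈ 0.17 × core, giving the defaults used. The generator's job here is to
reproduce the qualitative enrichment pattern (outer↑2M, middle peak-4M,
core↑8M), and this is the abundance regime in which the stated midpoints do
that.

**Histology.** Vesicle objects draw (hematoxylin, eosin) around zone means
(A: 0.80/0.35, B: 0.50/0.60, C: 0.25/0.80; sd 0.05); lumen-layer objects
I/II/III draw from the means of zones A/B/C. Zone A has 80 vesicle objects
with associated cross-section perimeters; with the gradient flag (default
on) their hematoxylin mean decreases by 0.15 across the perimeter range,
emulating the proximo-distal staining gradient.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: batch effects and ambient contamination in the
single-cell assay, spatial autocorrelation beyond region membership,
peptide-level identification biases (shared peptides between near-identical
spidroins, length-dependent detectability beyond the NSAF correction),
zero-inflation beyond NB, and any image-level structure (intensities are
drawn directly, not measured from images).

## Inference stages

**TPM / VST.** TPM is the usual length-rate normalization; genes need
TPM > 4 in ≥ 1 sample to enter the filter. The variance-flattening
transform is median-of-ratios size factors followed by log2(x/sf + 1) — a
deliberately simple stand-in for a parametric VST that preserves the rank
and variance-flattening behaviour the filter depends on. The DE step is a
Welch t-test on these values with BH adjustment and a size-factor-normalized
fold change (pseudocount 0.5), thresholded at adjusted P < 0.001 and
FC > 4, capped at 100 per part (ties broken by |log2FC|, then gene id).

**Step-3 loadings and the distance cutoff.** PCA is covariance-mode on the
transformed values; a gene's loading on a component is defined as
cov(gene, unit-variance component score) = eigenvector × √eigenvalue.
Under this convention an uninformative gene's two-component loading norm is
its noise sd times √R², with R² ~ Beta(1, (n−3)/2) across the sample-rank
components. The pipeline default cutoff 0.33 is the ≈ 99th percentile of
that null at the default conditions (NB dispersion 0.1 → log2-scale noise
sd ≈ √0.1/ln 2 ≈ 0.456; Beta(1,6) 99th pct ≈ 0.536; 0.456 × √0.536 ≈ 0.33).
The cutoff is convention-bound: a different loading scaling or noise level
needs a retuned value, which is why it is an explicit parameter. A
correlation-mode convention was rejected because with ~15 samples every
gene's squared correlations over the sample-rank components sum to 1, so
noise genes land at |corr| ≈ 0.27 per component and no cutoff separates.

**Axis orientation.** Two-component PCA/PLS subspaces are determined only
up to in-plane rotation and reflection, while the quadrant labelling rules
(PCA: tail PC1<0 ∧ PC2≥0, sac PC1≥0 ∧ PC2≥0, duct PC2<0; PLS-DA: tail
LV1<0, sac LV1≥0 ∧ LV2≤0, duct LV1≥0 ∧ LV2>0) presuppose a canonical class
geometry. Gene labelling therefore aligns the plane explicitly: for the
step-3 PCA the duct sample centroid is rotated to point straight down and
PC1 reflected if tail sits right of sac; for PLS-DA the bisector of the sac
and duct centroid directions is rotated onto +LV1 with duct above sac. The
PLS model itself keeps the raw fit (score columns exactly orthogonal);
rotation applies to a copy used only for labelling.

**Q².** Stratified cross-validation (7 folds requested, reduced with a
warning to the smallest class size — 5 with the default replication); per
fold, a fresh two-component PLS fit predicts the held-out one-hot class
matrix; Q² = 1 − ΣPRESS/ΣTSS with TSS against the training-fold mean.

**Single cell.** Pearson residuals use a fixed NB dispersion θ = 100
(replacing per-gene regularized estimation; the synthetic data have no
batch structure, so integration is omitted and a batch flag reserved),
clipped at ±√n_cells. Clustering is k-means on 30 PCs; k="auto" maximizes
mean silhouette over k ∈ [4, 16] on a seeded 1,000-cell subsample —
deterministic, dependency-light, and adequate for well-separated types.
QC boundaries follow the strict readings ("fewer than 300", "less than
500", "more than 500 cells"). Cluster-part assignment: hypergeometric
enrichment of the top-100 cluster markers in each part's PLS-DA gene list
against the gene-set universe, BH across the three parts within a cluster;
ties or non-significance give "none".

**Deconvolution.** Signatures are per-type means of depth-normalized
single-cell counts over the filtered gene set (strict log2FC > 2; ≥ 200
counts and ≥ 50 spots, inclusive). Spots are scaled to the median spot
depth and fit by NNLS; coefficients are renormalized to the simplex; an
all-zero solution falls back to uniform proportions and is flagged. The
spatial prior of model-based deconvolution methods is out of scope; a
smoothing flag is reserved. The test-suite oracle is an exhaustive
simplex-grid search (step 0.01) with the optimal nonnegative scale computed
analytically per candidate.

**Urea classification.** Percent of total spectra is recomputed over the
identified proteins only (restricted-set renormalization; a flag allows the
all-protein alternative, which the source analysis leaves ambiguous). The
2 M vs 8 M contrast is a two-sided Welch t-test — "unpaired" leaves the
variance assumption open and Welch is the safer reading — BH-adjusted
across the tested proteins (a flag disables adjustment for literal
replication, since the original number of simultaneous tests is unstated).
peak-4M requires the 4 M mean to exceed both others by a configurable
margin (default 0). The dissolved control feeds only the
consistency/comparison report; removing it changes no layer assignment
(asserted by test). Sample similarity uses Pearson r on relative-abundance
vectors and average-linkage clustering on 1 − r (no linkage is named in the
source; average is the usual default for correlation distances).

**Histology matching.** (H, E) standardized jointly; zone centroids from
vesicle objects; each lumen object assigned to its nearest centroid; layer
→ zone by majority vote with ties unmapped.

**Motif counting.** Poly-alanine counts maximal runs of ≥ 4 A's (run length
unstated in the source; configurable). GGX and GPGXX are counted
non-overlapping, scanning left to right, with the longer motif taking
precedence at shared positions — no convention is stated, so the package
fixes this one and validates it against a brute-force scanner.

## Problem sizes and determinism

Default sizes (2,000 genes; 5 replicates × 6 tissues; 3,000 cells; ~858
spots; 18 + contaminant proteins at 10,000 spectra × 30 samples; 80/30/30
vesicle and 3 × 30 lumen objects) are a desk-scale echo of the study's
dimensions, chosen so the full pipeline runs in well under a minute. Every
simulator takes an explicit seed and derives one RNG stream per assay from
(seed, assay tag), so assays can be regenerated independently; a missing
seed is an error, never silent nondeterminism.

## Known limitations

The VST/DE stand-ins are not DESeq2; absolute p-values differ even where
the thresholding behaviour matches. The distance cutoff and the
peak-4M rule depend on documented conventions. The per-protein layer model
assumes one dominant zone of origin; genuinely multi-zone proteins surface
as "mixed"/inconsistent rather than fractional assignments. The middle
layer's 4 M peak is a knife-edge property (its 2 M and 8 M relative
abundances are equal in expectation), so a small fraction of simulations
classify one middle protein as enriched at 2 or 8 M — the consistency flag
exists precisely to expose such cases.
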