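# Methods

This note documents the models and procedures implemented in the package,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. Empirical statements below refer to
quantities the test suite and `scripts/acceptance.py` compute.

## Nucleosome occupancy from Strand-seq fragments

A Strand-seq library of one cell consists of mono-nucleosomal paired-end
fragments; the fragment is the full insert interval, 140–180 bp, so that both
nucleosome boundaries come from the sequencing itself and no assumption about
nucleosomal DNA length is needed. Nucleosome occupancy (NO) at a base pair is
the number of fragments covering it; tracks report the *mean* per-bp coverage
in fixed bins (default 10 bp), with no peak calling or smoothing. QC removes
records with MAPQ < 10, duplicates and supplementary alignments; fragments
overlapping blacklisted artifact regions by ≥ 1 bp are dropped. All
coordinates are 0-based half-open (BED convention).

Strand letters follow one fixed convention — W (Watson) is the reverse genome
strand, C (Crick) the forward strand; only the distinction is meaningful.
Per cell and chromosome the template-strand state is called from the Watson
read fraction: WW at ≥ 0.8, CC at ≤ 0.2, mixed otherwise, with at least 20
fragments required for a call (all configurable; these cutoffs are this
package's choice, a plateau region in which calls on simulated data are
insensitive to the exact value). Mixed chromosomes are labelled WC vs CW
using haplotype tags when present; downstream logic only uses mixed-vs-pure.

Anchor-averaged profiles (e.g. around bound CTCF motifs) average per-bp
coverage across sites after flipping minus-strand anchors, then scale the
profile so the bin at −2,000 bp from the site center equals 1 — the standard
convention for such plots, which makes libraries of different depth
comparable.

## Gene-body counts and normalization

The feature space for cell typing and differential inference is the
genes × cells matrix of fragments overlapping the gene body (TSS to
transcription termination site) by ≥ 1 bp; a fragment spanning two genes
counts in both. Normalization composes three steps, each skippable:
copy-number (count × 2/CN, gene→segment by majority overlap, ties to the
lower-coordinate segment; CN 0 with nonzero counts floored at 0.5 and
logged), library size to reads per million (denominator: all retained
fragments of the cell, not only in-gene fragments), and log2 with pseudocount
1. Batch adjustment is location-only on the log scale (per gene, each batch
re-centered to the grand mean); a full count-model batch correction is out of
scope, and the interface accepts externally corrected matrices.

## Cell typing (PLS-DA)

The classifier is a NIPALS PLS2 fit of standardized gene-body NO features on
dummy-coded class labels. Components are extracted with deterministic
initialization (the response column of maximal residual variance), so fits
are reproducible given input order. Feature selection keeps features with
VIP > 1 on an initial full fit and refits; VIP is
√(G · Σ_a w²_ga SS_a / Σ_a SS_a) with SS_a the response variance captured by
component a, which gives Σ_g VIP² = G. Prediction projects standardized new
data through the regression coefficients; the hard label is the arg-max class
score, and performance is one-vs-rest AUC, macro-averaged. Training
standardization parameters are reused at prediction time — no leakage.

## Two-step differential gene activity

**Step 1 (NE filter).** Genes unlikely to be expressed add noise, so a
classifier estimates P(not expressed) per gene and clone from features of the
clone pseudobulk: the gene body resampled to 150 equal bins of mean NO, 150
matching GC-content bins, and log gene length. The classifier is a seeded,
standardized, L2-regularized logistic regression behind a fit/predict_proba
API, so other estimators (e.g. a convolutional network) can be substituted
without changing the contract. A gene is removed iff P(NE) ≥ 0.9 in *every*
clone (inclusive bound); training labels come from matched expression data or
simulator truth.

**SCNA masking.** Genes whose copy number differs between the two compared
clones over ≥ 1 bp of the gene body are masked, since dosage alone would
confound occupancy differences.

**Step 2 (default, NB-GLM).** Cells are replicates; per gene the model is
log μ_j = log s_j + β₀ + β·1[clone 2] with negative-binomial variance
μ + αμ². Size factors s_j are median-of-ratios (median over all-positive
genes of count/geometric-mean). Dispersion α is per-gene method-of-moments on
size-factor-normalized counts with the variance pooled within groups, floored
at 0 — deliberately simple, with calibration verified by simulation (type-I
error at nominal 0.05 within its binomial confidence band on negative-
binomial null data; the suite checks this at 200 genes × 100 cells). No
empirical-Bayes shrinkage toward a mean–dispersion trend is applied; with
tens of cells per clone the per-gene estimate is adequate and the estimator
stays transparent. Fitting is IRLS (tolerance 1e-8, ≤ 100 iterations;
non-convergence or an all-zero group yields a flagged NA). The Wald statistic
β̂/SE is referred to the normal; log2FC = β̂/ln 2; the differential gene
activity score is sign(FC) × (−log₁₀ p); BH FDR, 10% threshold throughout.

**Step 2 (alternative, PLS-DA).** For subclones below 10% clonal frequency
the count test loses power, so the alternative mode fits PLS-DA to the two
clone labels on the normalized matrix and assigns each gene a VIP with a
permutation p-value: p = (1 + #{perm VIP ≥ observed})/(n_perm + 1) under
label shuffling (all distinct assignments are enumerated when fewer than
n_perm exist). Mode dispatch is automatic at the 10% CF boundary and
overridable.

## Haplotype-specific analyses

Only chromosomes in a mixed (WC/CW) state contribute: there each phased read
maps unambiguously to a homolog. Per-unit (gene, window, CRE) counts are kept
per cell and haplotype, with zero rows for informative cells without
coverage.

- **Gene bodies:** two-sided Wilcoxon rank-sum comparing per-cell H1 vs H2
  counts normalized by haplotype copy number (unpaired across cells; at least
  5 informative cells). The exact distribution is used at small n (checked
  against full enumeration over C(8,4) arrangements). Effect is
  log2((mean H1 + 1)/(mean H2 + 1)); swapping haplotypes negates it and
  preserves p exactly.
- **Breakpoint scan:** genes overlapping ±1 Mb of any SV breakpoint are
  selected and BH is re-applied within the scan set of each SV.
- **Sliding windows:** default 50 kb windows at 10 kb steps (the window size
  is this package's choice; no canonical value exists). Pooled (n_H1, n_H2)
  per window are scored with the binomial likelihood-ratio statistic against
  p₀ (χ²₁ analytic p) and a permutation-adjusted p from shuffling the
  haplotype labels of all phased fragments in the region, which preserves
  per-window totals. Fold change is the exact count ratio with the
  pseudocount only guarding zeros, so FC(40,10) = 4 and FC → 1/FC under label
  swap.
- **CREs:** two-sided exact binomial test of n_H1 of n_H1+n_H2 against
  p₀ = CN_H1/(CN_H1+CN_H2), BH at 10% FDR.
- **TADs:** per TAD (≥ 3 windows; window assigned by midpoint), a two-sample
  KS test of window log fold changes inside vs outside flags fused or
  dysregulated domains as outliers.

## Gene sets

Over-representation is the upper-tail hypergeometric test (identical to the
one-sided Fisher exact test on the corresponding 2×2 table), BH at 10% FDR;
curated TF-target lists are user-supplied GMT files. Pathway-level NO is the
per-cell mean of median-of-ratios-normalized NO over the variable members of
a set; "lowly variable" genes are removed, by default those below the 80th
percentile of across-cell standard deviation over all genes (an absolute
threshold mode is available, since "s.d. < 80%" admits both readings). The
activity transform reports (−1) × Z across cells — occupancy and activity are
inversely related, so higher transformed scores mean higher inferred pathway
activity. Pathway differences between SV and non-SV cells use a linear mixed
model (SV status fixed, batch random intercept), both nested models fitted by
maximum likelihood so the likelihood-ratio statistic is valid against χ²₁;
with a single batch the test reduces to the ordinary linear-model LRT, and
the engine used is recorded per pathway.

## The synthetic-data generator

The generator emulates the features the inference relies on: cells are
assigned to clones multinomially by clonal frequency; each (cell, chromosome,
haplotype) draws a template strand, giving WW/CC/WC/CW states with the
expected 1:1 pure:mixed ratio; fragments (uniform 140–180 bp) are sampled
from piecewise-constant per-haplotype rates — silent genes at
`no_depletion_factor` (default 2.0) times the rate of an average expressed
gene, expressed genes down-weighted continuously with a lognormal expression
level so gene-body NO and expression are negatively rank-correlated;
heterozygous deletions zero one haplotype's rate, duplications double it;
clone-level activity shifts and per-haplotype factors scale gene rates.
Fragment starts sit on a nucleosome lattice (repeat 190 bp) with 20 bp
Gaussian jitter, which reproduces phased oscillation near anchors
qualitatively. Library sizes are lognormal per cell (σ = 0.15) with optional
multiplicative batch effects. All haplotype tags are kept by default (the
truth tables always retain them); `phased_fraction` can be lowered to ~0.5 to
emulate realistic phasing rates. Default scale — 1–2 chromosomes of 1–2 Mb,
tens to hundreds of genes, 40–100 cells at 4,000–8,000 fragments per cell —
keeps every inference path well-powered while the whole suite runs in well
under a minute; these sizes are the package's chosen study conditions for its
tests and acceptance script.

What the simulator does *not* emulate: real sequence content (GC is a
simulated per-kb value), mappability artifacts, variable nucleosome repeat
lengths, chromatin domain structure, doublets, and the heavy-tailed
cell-quality variation of real libraries. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to every artifact of real Strand-seq data.

## Numerical choices and known limitations

- BH adjustment ignores NaN p-values and is verified against the brute-force
  definition q_(i) = min_{j≥i} p_(j)·m/j.
- Identical H1/H2 samples short-circuit to p = 1 in the rank-sum test (the
  tie-corrected normal approximation is undefined there); the asymptotic
  branch omits the continuity correction so that balanced data give exactly
  p = 1.
- The NB IRLS clips the linear predictor at ±30 to avoid overflow; singular
  weighted designs yield flagged NAs rather than exceptions.
- **Composition bias.** Median-of-ratios size factors assume most genes are
  unchanged. When a sizable fraction of genes shifts in one direction (10%
  of genes at 2-fold in the acceptance simulation), the per-cell ratio
  medians are dragged in opposite directions in the two clones, leaving a
  residual global log2FC of order −0.1 on null genes. At high per-gene depth
  this residue is statistically detectable, inflating the count of
  FDR-significant genes even though score *ranking* (and hence the AUC
  benchmark) is unaffected. This is shared by all global-scaling
  normalizations; interpreting small uniform fold changes in the significant
  set as composition residue, or using the PLS-DA mode, is advised when many
  genes are expected to change.
- PLS-DA permutation p-values have a floor of 1/(n_perm+1); reaching q < 0.1
  across G genes requires n_perm ≳ 10·G/(expected hits).
- The mixed-model LRT treats the SV fixed effect with a χ²₁ reference; no
  boundary correction is needed because the variance components are identical
  under both hypotheses.
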