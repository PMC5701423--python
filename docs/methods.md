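# Methods

This note documents the statistical procedures, the synthetic-data
generator that the test suite exercises them on, the numerical choices,
and the known limitations.

## Preprocessing

β = M/(U + M + 100) is computed elementwise from the methylated and
unmethylated signal matrices; the +100 offset keeps low-intensity
probes away from 0/0 and bounds β below 1. Missing intensities
propagate to missing β and are never imputed — probes with any missing
value are dropped at the first QC step. The QC cascade runs in a fixed
order (missing values, SNP-overlapping probes, X/Y probes, detection
failures), and a probe is counted at the first rule it trips; without
that convention the per-step removal counts of overlapping categories
would be ill-defined. The detection rule removes a probe when its
detection p exceeds `detection_alpha` (default 0.05) in at least
`detection_sample_fraction` (default 0.75) of samples. M-values are
log2(β′/(1−β′)) with β′ clamped to [ε, 1−ε], ε = 1e-6; the transform is
strictly monotone and invertible inside the clamp range.

## Differential methylation

Probes are tested with the unpaired two-sided Wilcoxon rank-sum test.
The test is named, not its pairing; the unpaired form is used even
though samples are patient-matched, and this is a deliberate,
documented reading (the paired signed-rank alternative would change
probe ranks, not the calling logic). The exact null distribution is
used when the combined sample size is ≤ 12 and the data are tie-free;
otherwise the tie-corrected normal approximation with continuity
correction. Identical pooled values return p = 1. BH q-values are
computed across exactly the QC-retained probe set. A probe is called at
q < 0.05 and |Δβ| ≥ 0.2, with Δβ the difference of arithmetic group
means. Gene aggregation uses the any-probe rule; a gene's direction
comes from its max-|Δβ| called probe, and genes with calls in both
directions carry a `mixed` flag and are excluded from starburst
integration.

## Genomic context

CpG-island annotation is interval arithmetic against a sorted BED set
(0-based half-open): inside an island → Island; within 2 kb of the
nearest island edge → shore; the next 2 kb → shelf; beyond → open sea.
North is the lower-coordinate side. On the south side the half-open
convention makes the first base past an island distance 0 and already
S_Shore; the labels still partition every position and are symmetric
under reflection about an island. The 2 kb widths are the conventional
450K definitions and are configurable. Gene-region classification is
strand-aware: TSS200 is 1–200 bp upstream of the TSS, TSS1500 is
201–1500 bp, and containment labels follow the precedence
TSS200 > TSS1500 > 5′UTR > first exon > 3′UTR > body. "Promoter" means
gene context in {TSS1500, TSS200, 5′UTR, first exon}.

Region summaries report counts plus integer percentages allocated by
largest remainder, so shares over a partition always sum to 100.
Region-level group comparison reduces each sample to its mean β over a
region's probes and applies the rank-sum test to the per-sample means,
BH-corrected across regions; the underlying test for this comparison is
a package choice.

## Expression and integration

Expression input is assumed log2-scale (microarray convention). The
per-gene paired t statistic is mean(d)/(sd(d)/√n) on tumor−normal pair
differences with n−1 df; all-zero differences give p = 1, constant
nonzero differences are flagged degenerate (p undefined) and excluded
from BH. Fold change is the antilog of the mean paired log2 difference,
and |FC| > 2 means FC > 2 or FC < 0.5.

Integration intersects DM genes with DE genes and classifies each into
one of four quadrants from the two direction labels. The fourfold
refinement keeps inverse-quadrant genes with |log2FC| ≥ log2(4). The
per-gene methylation–expression correlation is Spearman's rank
correlation (average ranks for ties) between the representative
probe's β and expression over the shared samples; the representative
probe is the gene's max-|Δβ| called probe, consistent with
aggregation. The quadrant-vs-context association uses the chi-square
test of independence without continuity correction for tables larger
than 2×2, falling back to Fisher's exact test for 2×2 tables with any
expected count below 5.

## Biomarker ROC

AUC is the Mann–Whitney concordance (#(pos > neg) + ½#(ties)) /
(n_pos·n_neg), computed via midranks. Marker orientation is taken from
the discovery direction — hypermethylated markers score tumor-high,
hypomethylated tumor-low — so a marker evaluated in its own direction
has AUC ≥ 0.5 by construction. The 95% CI is a percentile bootstrap
with resampling stratified by class (every replicate keeps both
classes), 1000 iterations by default, deterministic under a fixed
seed; the percentile variant is the simplest bootstrap consistent with
the procedure being emulated. The optimal cutoff maximizes Youden's
J = sensitivity + specificity − 1 over cutoffs placed midway between
adjacent distinct scores, with ties broken toward higher specificity.

## Subtyping and stratified correlation

Tumors are clustered on the M-values of the called DMPs (or the
island-only subset). Each probe row is centered across tumors before
distances are computed: sample–sample correlation on raw M-values is
dominated by the shared probe-mean profile, which hides subgroup
structure and produces chained, singleton-heavy dendrograms;
row-centering is the standard heatmap practice and makes the planted
subgroups recoverable. Distance is 1 − Pearson correlation, linkage is
average (both configurable; neither is prescribed by the emulated
workflow). The k = 2 cut is relabeled so Cluster 2 has the higher mean
M-value, making "Cluster 2 is hypermethylated" assertable on every
run. Clinical stratification reduces each stratum to its per-probe
mean-β profile and reports the Pearson correlation between the two
profiles, separately within tumors and normals; this mean-profile
reading is the most defensible interpretation of an underdetermined
analysis and is flagged as such.

## Synthetic data

The generator emulates the statistical structure of a 24-pair
tumor/normal 450K study at 20,000 probes — 1/24 of the real array for
desk-scale runtime, with the 24-pair design and a 12-pair expression
subset kept at full size.

* **Context layout.** Island probes are 31% of the array; shores
  11.5% per side, shelves 5% per side, open sea 36%. Islands are 1 kb
  intervals spaced 20 kb apart, and each probe's coordinate is drawn
  inside the zone its label implies, so de novo classification
  round-trips. Gene context is drawn conditional on island context
  (islands at promoters, open sea in gene bodies), which produces the
  TSS-low / body-high methylation pattern without a separate mechanism.
* **β distributions.** Per-context two-component Beta mixtures:
  islands 0.9·Beta(2,18) + 0.1·Beta(10,4) (single low peak), shelves
  0.1·Beta(2,18) + 0.9·Beta(12,4) (single high peak, mode ≈ 0.79),
  shores an even mixture (bimodal), open sea mostly methylated. The
  emulated study states only the qualitative modes (< 0.2 and > 0.6);
  the shape parameters are calibrated to those statements once and not
  revisited.
* **Artifacts.** Flag rates default to the real array's removal
  proportions (14,511 / 89,808 / 10,245 / 14 out of 485,577 for
  missing, SNP, X/Y and detection failure). Flags are mutually
  exclusive by assignment order (missing > SNP > X/Y > detection), so
  the cascade's sequential counts are unambiguous. At 20,000 probes the
  detection-failure class is expected under one probe — the rate is
  kept faithful rather than inflated.
* **Planted signal.** 5% of clean probes are differential, 77%
  hypermethylated, with tumor means shifted by Δβ = 0.3; baselines are
  kept in [0.05, 0.90 − Δβ] (hyper) or [0.05 + Δβ, 0.90] (hypo) so
  noise rarely clips and recovery of the planted shift is unbiased to
  within ±0.02 at large n. Hyper probes are drawn island-weighted and
  hypo probes shelf/open-sea-weighted, mirroring the observed context
  asymmetry. Tumor/normal β of a pair share a probe-level random
  effect (sd 0.02) to mimic patient matching, plus independent
  N(0, 0.05) noise, clipped to (0, 0.975]. Intensities are back-solved
  at fixed total M + U = 5000 so β = M/(U+M+100) holds exactly.
* **Subgroups.** 14 of 24 tumors form a hypermethylated subgroup with
  an extra +0.15 β on 30% of the planted DMPs — the planted analog of
  the two observed tumor subclusters (10 vs 14).
* **Expression.** Gene baselines are Uniform(6, 12) log2 units with a
  per-pair random effect (sd 0.3) and N(0, 0.5) noise. 10% of genes
  (among DMP-bearing genes) are inversely coupled: their tumor
  expression shifts by −(log2FC/Δβ)·(planted β shift) with
  log2FC = 2.5; a further 4% shift concordantly, populating the
  non-inverse quadrants. Coupling acts through group means, so the
  per-sample inverse correlation arises from the group separation.
* **Determinism.** All randomness flows from one root seed through
  named substreams per stage; identical config + seed reproduces
  byte-identical output files.

What the generator does **not** emulate: raw IDAT chemistry, dye bias,
batch effects, probe cross-hybridization, spatially autocorrelated
(regional) differential methylation, or biologically structured
expression networks. Passing tests therefore demonstrate the
correctness of the bookkeeping and the statistical machinery under a
clean planted-truth model, not robustness to the technical artifacts of
real arrays.

## Problem sizes used in checks

The shipped checks run the default study (20,000 probes × 48 samples)
across five seeds for recovery and subtyping, 10,000 probes for the
null control, and 20 seeds at n = 20 + 20 for bootstrap-CI coverage;
brute-force oracles (rank-sum enumeration at combined n ≤ 10, AUC pair
counting, BH step-up, closed-form t CDF at df ∈ {1, 2}) cross-check the
statistics on hundreds of random small inputs.

## Known limitations

* Probe-wise calling only; no region (DMR) model.
* The unpaired rank-sum choice discards pairing information.
* A probe mapping to several genes keeps the first manifest gene.
* The percentile bootstrap can undercover for AUCs near 1 at small n.
* Stratified correlation compares only two strata per factor.
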