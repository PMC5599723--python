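# Methods

This note documents the statistical procedures implemented in `femtime`,
the conventions chosen where the design was genuinely open, and what the
synthetic study generator does and does not emulate.

## The feminization statistic

For a gene with replicate-averaged FPKM `s` in sham-treated males, `f` in
control females and `c` after a given duration of continuous GH (cGH)
infusion,

    % feminization = 100 · (c − s) / (f − s).

The sign convention makes positive values "movement toward the female
level" for both male- and female-biased genes; values above 100 (overshoot)
and below 0 are kept uncapped internally. The denominator is guarded by a
floor `ε = 0.25` FPKM (configurable): genes with `|f − s| ≤ ε` get NA
feminization and are flagged rather than dropped silently, because the
ratio is numerically meaningless for genes with no usable sex difference.
Feminization is computed on condition means, matching pooled-FPKM usage; a
per-replicate mode is available through the same function since it
broadcasts elementwise.

## Differential expression stand-in

Count-based negative-binomial testing is deliberately out of scope. The
built-in contrast test is **Welch's t on log2(FPKM+1) across replicates**,
Benjamini–Hochberg corrected per contrast — deterministic, dependency-light
and adequate for the lognormal replicate noise the generator produces.
Zero-variance replicate sets (the noiseless simulation limit) yield p = 1
when the means coincide and p = 0 otherwise. Externally computed adjusted
p-values are accepted verbatim wherever a contrast is consumed, so the
classifier can sit downstream of any dedicated DE tool.

Thresholds (all configurable, defaults): sex-biased p_adj < 0.01 with
FPKM > 1 in either sex; stringent sex-biased additionally >2-fold in every
available male-reference-vs-female contrast; stringent sex-independent
p_adj > 0.1 and fold < 1.2; responsive p_adj < 0.05 and ≥20% feminization.
The fold change uses a 0.1 pseudo-FPKM floor so barely expressed genes
cannot produce unbounded ratios. Y-chromosome genes are flagged and
excluded from the sex-biased classes when chromosome labels are supplied.

## Response clustering

**Model-profile screen.** Profiles are integer paths over the time grid
(sham = 0, then each cGH time point), steps bounded by c = 10 units, m = 8
profiles by default. The bank always contains the flat profile and the
monotone-up staircase; the rest are chosen by greedy max-min selection
under correlation distance d = 1 − r from the exhaustively enumerated path
space (or a uniform sample of 20,000 paths when the space exceeds 200,000).
Genes are assigned to their maximally correlated profile (ties to the
lowest profile id; zero-variance trajectories to the flat profile, whose
correlation with everything is defined as 0). Per-profile significance is
an empirical FDR: assignment counts are compared with counts under
independent within-gene permutations of the time axis (default 1,000
permutations, +1-corrected p, BH across profiles).

**Gene selection.** Stage 1 keeps genes whose best-profile correlation is
≥0.7 and whose best profile trends upward (positive net feminization).
Stage 2 rescues genes that are strongly induced (maximal fold induction
≥4) but feminize weakly (<20%) — the behaviour of highly female-specific
genes whose female level is far above anything cGH achieves.

**Clustering.** Complete-linkage agglomeration on Euclidean distances of
the per-timepoint feminization vectors, separately per sex, cut at k = 5.
Feminization values entering the distance are clipped to [−50, 150] to
bound the leverage of overshoot outliers (overshoot is a saturation
phenomenon, not a graded signal). Genes with any NA feminization are
excluded from clustering. Cluster labels are renumbered by onset: cluster 1
has the earliest mean-trajectory crossing of 50% feminization, ties broken
toward higher final feminization, so labels are a deterministic function of
the data and k.

A caveat observed on synthetic data: with heteroscedastic feminization
noise (saturated early-responders are noisier in feminization units than
weak late-responders), complete linkage can occasionally split a noisy
saturated cluster while merging two quiet late clusters. This is a property
of the linkage criterion, not of the label ordering.

## Regulatory domains and peak mapping

Each gene's basal domain spans TSS − 5 kb to TSS + 1 kb in transcription
orientation (TSS of a minus-strand gene is its rightmost coordinate). Each
side extends to the nearest other gene's basal boundary, capped at 1 Mb
beyond the basal edge and clipped at chromosome bounds; when two basal
domains overlap, extension on the blocked side is zero, never negative. The
1 Mb cap is measured from the basal edge by default; measuring from the TSS
is available (`cap_from="tss"`) since both readings of "up to a maximum of
1,000 kb in one direction" are defensible. A peak targets every gene whose
extended domain contains the peak midpoint `floor((start+end)/2)`;
whole-peak-overlap and nearest-TSS-within-10-kb modes exist behind flags.
Target sets are deduplicated across peak classes: male-enriched targets
drop genes also targeted by female-enriched peaks and vice versa;
sex-independent targets drop genes targeted by either.

## Enrichment

The enrichment score of a 2×2 table is the sample odds ratio
ES = (a·d)/(b·c); significance is the two-sided Fisher exact probability
under the point-probability criterion (sum of hypergeometric probabilities
of all fixed-margin tables no more probable than the observed one). For
table totals ≤ 1,000 the p-value is computed by exact integer enumeration,
which is bit-stable against an independent exact-rational oracle; larger
tables delegate to `scipy.stats.fisher_exact`, with which the exact path
agrees to ~1e-9. Zero cells report ES = +∞ (b·c = 0) or 0 (a·d = 0); an
optional Haldane +0.5 correction applies to the score only, never the
p-value. No multiple-testing correction is applied across enrichment
panels by default (raw Fisher p-values are reported); BH is available.

## Region arithmetic

Per gene: `collapsed_exon` is the union of exons over all isoforms;
`intronic_only` is the union of isoform introns minus the collapsed exons;
`exonic_only` is the collapsed exons minus the union of introns. All
coordinates are 0-based half-open internally; GTF is converted at the I/O
boundary (1-based inclusive) by exact inverse transforms. Reads are single
intervals (no spliced alignment — a documented simplification relative to
real RNA-seq); a read counts once for every (gene, region class) whose
intervals it overlaps by ≥1 bp, classes assessed independently, so a
junction-spanning read counts in both exonic-only and intronic-only. The
intronic/exonic comparison keeps genes with ≥24 intronic-only reads summed
over the two compared conditions (the threshold is a convention — the
filter's existence, not its value, is prescribed), applies a pseudocount of
1 before log2 fold changes, reports the Pearson r across retained genes,
and flags genes with a >2-fold difference between intronic and exonic fold
change (|Δlog2| > 1) as discordant.

## Chromatin states

Feature densities (DHS, H3K27ac, H3K4me1, H3K4me3, H3K36me3, H3K27me3,
H3K9me3) in 2-kb TSS and TES windows are log2(x+1)-transformed (densities
are heavy-tailed), averaged over the two windows, and z-scored per feature
across the gene universe within each sex. Binarizing at the per-feature
grand mean (high ⇔ z > 0) feeds the rule cascade: **active** = DHS ∧
H3K27ac ∧ H3K4me1 high; **poised** = H3K4me1 ∧ H3K27me3 high with H3K27ac
low; **inactive** = H3K27me3 high with H3K4me1 and H3K27ac low; otherwise
unclassified. The rules are mutually exclusive by construction. The
grand-mean threshold was chosen over a positive z cutoff because, for a
bimodal feature whose high mode covers a fraction p of genes, the high
mode sits at z = √((1−p)/p): a fixed positive cutoff lands inside the high
cluster once p > ~0.55 (H3K4me1 is high in both active and poised genes),
whereas the mean splits the modes for any p in roughly [0.2, 0.8]. Genes
shorter than 5 kb are excluded (their TSS window would overlap the TES
window), as are genes lacking feature data. "More active in female" uses
the ordering active > poised > unclassified > inactive; placing
unclassified between poised and inactive is a convention.

## Zonation

Zonation bias = (zone1 − zone9)/mean(zones 1–9) on 9-zone profiles ordered
pericentral → periportal; positive = pericentral. The printed form of this
formula is ambiguously bracketed; the implemented reading is the only one
that yields a dimensionless signed bias (scale-invariant,
reversal-antisymmetric). Differential-zonation q-values are consumed as
input (q < 0.2 = significantly zonated); deriving them from single-cell
data is out of scope. Group comparisons use the two-sided Wilcoxon
rank-sum test: exact null distribution for group sizes ≤ 20, normal
approximation with continuity correction above, mid-ranks for ties. The
PC/PP ratio mean(zones 1–3)/mean(zones 7–9) is a display ordering only;
zero-denominator profiles are flagged NA and sorted last.

## Synthetic study generator

The generator's defaults are the study conditions. Genes are assigned to
sex classes (25% male-biased, 25% female-biased, 50% sex-independent by
default) and, within each sex, to response clusters with mixture weights
proportional to the observed cluster sizes. Condition means follow the
observed per-cluster mean-feminization trajectories at 10 h / 1 d / 4 d /
7 d / 14 d, with saturated (">100") entries encoded as 105 — the largest
overshoot that keeps cGH means positive for any planted sex ratio up to
20-fold. Planted sex ratios are log-uniform on [2.5, 16], baseline FPKM
log-uniform on [2, 128], replicate noise lognormal with σ = 0.15 in log2
units and 3 replicates per condition. With noise 0, downstream feminization
equals the planted trajectory exactly at every time point.

Gene models are laid on an even grid (so spans never overlap or nest) with
2–8 exons and 1–3 isoforms derived by internal-exon skipping. Peaks are
planted by independent per-gene Bernoulli targeting: background genes at
rate 0.3, foreground genes at the rate whose odds are `target_enrichment`
times the background odds, one 200-bp peak centred inside each targeted
gene's basal domain. This makes the planted odds ratio exact in
expectation for the gene-level 2×2 recovery, and because extensions stop
at basal boundaries, planted targeting survives midpoint mapping exactly.
Chromatin features are drawn around state-conditional log2 modes separated
by ≥5 units (≥4 noise SDs at the default σ = 0.5); zonation profiles are
linear in zone index, v_i = c·(1 + b·(5−i)/8), whose bias is exactly the
planted b, with q-values below 0.2 precisely for genes planted as zonated.

What the generator does **not** emulate: read-level sequence (no FASTQ),
spliced reads, fragment-length/GC bias, count overdispersion beyond the
lognormal FPKM noise, pooling structure of replicate libraries (replicates
are exchangeable), correlated noise across time points, and single-cell
zonation reconstruction. Passing tests therefore demonstrate correctness
of the statistical machinery on its stated model, not robustness to every
artefact of real RNA-seq.

## Problem sizes and determinism

Test and demo simulations use 25–400 genes; the cluster-recovery check
uses 200 genes per sex in five planted clusters (noise σ = 0.15, 3
replicates), null calibrations use 500-gene null runs with 200
permutations and 500 rank-sum simulations, and enrichment recovery uses
200 replicate peak simulations over 360 genes. All randomness flows
through `numpy.random.default_rng` seeded from configuration; identical
config + seed reproduces every output byte-for-byte after serialization.
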