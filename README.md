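# femtime

Time-course analysis of growth-hormone-induced **feminization of male mouse
liver gene expression**, packaged as a tested, reusable pipeline.

Hepatic gene expression is sexually dimorphic, driven by the pattern of
pituitary growth hormone (GH) secretion: pulsatile in males, near-continuous
in females. Infusing male mice with continuous GH (cGH) overrides the male
pattern and progressively *feminizes* the liver transcriptome — male-biased
genes are repressed and female-biased genes induced, in distinct temporal
waves that track transcription-factor hierarchies (STAT5, BCL6, CUX2) and
the genes' basal chromatin states. `femtime` implements the statistics of
that analysis for anyone studying hormone-driven, time-resolved
transcriptional reprogramming:

* **Percent feminization.** For each gene and infusion time point

  ```
  % feminization = 100 · (FPKM_cGH − FPKM_sham) / (FPKM_female − FPKM_sham)
  ```

  0% = still at the untreated-male level, 100% = at the female level.
* **Sex-bias classification** with stringency tiers (adjusted p < 0.01 and
  FPKM > 1; *stringent* adds a >2-fold sex ratio; *stringent
  sex-independent* requires p > 0.1 and fold < 1.2) and responsiveness
  flags (p < 0.05 and ≥20% feminization at a time point).
* **Response clustering**: screening against a bank of integer model
  profiles (bounded step, assignment by maximal Pearson correlation,
  permutation FDR), then complete-linkage hierarchical clustering of
  feminization vectors into early → late response clusters per sex.
* **Regulatory domains**: basal domain 5 kb upstream / 1 kb downstream of
  the TSS, extended to the nearest gene's basal domain up to 1 Mb;
  peak-to-gene assignment by peak midpoint.
* **Enrichment**: odds-ratio enrichment scores ES = (a·d)/(b·c) on gene-set
  2×2 tables with exact two-sided Fisher tests.
* **Exon/intron region arithmetic**: collapsed-exon, exonic-only and
  intronic-only counting regions per gene, for separating transcriptional
  (nascent, intronic) from post-transcriptional (mature, exonic) responses.
* **Chromatin states**: rule-based active / poised / inactive calls per
  gene and sex from DHS + histone-mark densities at TSS/TES windows.
* **Liver zonation**: zonation bias = (zone1 − zone9)/mean(zones 1–9) on
  9-zone profiles, with rank-sum comparisons between gene groups.
* **A ground-truthed synthetic study generator** producing every input the
  pipeline consumes (expression tables, gene models, peaks, chromatin
  features, zonation profiles) with planted classes, clusters, states and
  enrichments, so every stage is testable without external data.

## Worked example

```python
>>> from femtime import percent_feminization, enrichment_2x2
>>> round(percent_feminization(9.73, 0.0, 76.3), 1)
12.8
>>> res = enrichment_2x2(29, 24, 10, 36)
>>> print(f"ES = {res.es:.2f}, p = {res.p:.5f}, {res.direction}")
ES = 4.35, p = 0.00098, enriched
```

The first number: a highly female-specific gene induced 919-fold by cGH to
an FPKM of 9.73 has still only travelled 12.8% of the way to its female
level of 76.3 — strongly induced yet barely feminized. The second: among
cGH-responsive female-biased genes, 29 of the 53 early responders but only
10 of 46 later responders sit in an active chromatin state in male liver, a
4.35-fold enrichment (two-sided Fisher exact p ≈ 0.001) — genes whose
chromatin is already open respond to persistent GH sooner.

The full pipeline runs on a generated demo study:

```bash
femtime simulate --outdir demo --seed 7
femtime run --indir demo --outdir demo_out
```

which reports, for the default 300-gene simulation (from
`demo_out/report.json` and `demo_out/enrichment.tsv`):

```
classify:   n_genes=300  n_stringent_sex_biased=146  n_responsive=138
clustering: n_male_clustered=66  n_female_clustered=60
enrichment: male_enriched_targets_vs_male_biased    ES=2.42  p=0.0061
            female_enriched_targets_vs_female_biased ES=3.07  p=0.0003
```

i.e. the classifier recovers the planted sex-biased genes, the clustering
stage partitions the responsive ones into five waves per sex, and the
peak-target enrichments recover the planted association between sex-biased
binding sites and same-sex-biased genes.

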