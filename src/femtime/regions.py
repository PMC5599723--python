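"""Exon/intron counting-region construction and read counting.

For each gene three disjoint-interval region sets are derived from its
isoform structures:

* ``collapsed_exon`` — the union of exons over all isoforms;
* ``exonic_only``    — collapsed exons minus any base that is intronic in
  some isoform;
* ``intronic_only``  — the union of introns over all isoforms minus any
  base that is exonic in some isoform.

Intronic-only signal tracks nascent transcription, exonic-only signal
mature mRNA; comparing fold changes between the two distinguishes
transcriptional from post-transcriptional regulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genemodels import GeneModel
from .intervals import GenomicInterval, Span, merge_spans, subtract_spans

REGION_CLASSES = ("collapsed_exon", "exonic_only", "intronic_only")

#: minimum intronic-only reads summed across the compared samples for a
#: gene to be considered reliably quantifiable at the intron level
MIN_INTRONIC_READS = 24


def build_region_sets(gene: GeneModel) -> Dict[str, List[Span]]:
    """The three counting-region classes for one gene, as merged span lists."""
    collapsed = gene.all_exons()
    introns = gene.all_introns()
    return {
        "collapsed_exon": collapsed,
        "exonic_only": subtract_spans(collapsed, introns),
        "intronic_only": subtract_spans(introns, collapsed),
    }


def region_sets_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Long-format table of region intervals for a gene collection."""
    rows = []
    for gene in genes:
        for cls, spans in build_region_sets(gene).items():
            for s, e in spans:
                rows.append((gene.gene_id, gene.chrom, cls, s, e, gene.strand))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "region_class", "start", "end", "strand"]
    )


def count_reads(
    genes: Sequence[GeneModel],
    reads: Iterable[GenomicInterval],
) -> pd.DataFrame:
    """Count reads overlapping each gene's region classes by >= 1 bp.

    A read counts once per (gene, class) however many intervals of that
    region set it touches; a junction-spanning read is counted in every
    class it overlaps (classes are assessed independently).
    """
    trees: Dict[str, IntervalTree] = {}
    counts: Dict[Tuple[str, str], int] = {}
    for gene in genes:
        for cls, spans in build_region_sets(gene).items():
            counts[(gene.gene_id, cls)] = 0
            tree = trees.setdefault(gene.chrom, IntervalTree())
            for s, e in spans:
                tree.addi(s, e, (gene.gene_id, cls))
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        hit = {iv.data for iv in tree.overlap(read.start, read.end)}
        for key in hit:
            counts[key] += 1
    rows = [(g, c, n) for (g, c), n in counts.items()]
    return pd.DataFrame(rows, columns=["gene_id", "region_class", "count"])


def compare_intronic_exonic(
    counts_ref: pd.DataFrame,
    counts_treat: pd.DataFrame,
    min_intronic: int = MIN_INTRONIC_READS,
    pseudocount: float = 1.0,
) -> Tuple[pd.DataFrame, float]:
    """Exonic vs intronic log2 fold changes between two conditions.

    Both inputs are count frames from :func:`count_reads`. Genes are kept
    when their intronic-only reads summed over the two conditions reach
    ``min_intronic``. Returns the per-gene comparison frame (log2 fold
    changes, their difference and a discordance flag for a >2-fold
    difference) and the Pearson r across retained genes.
    """

    def pivot(df: pd.DataFrame) -> pd.DataFrame:
        return df.pivot_table(
            index="gene_id", columns="region_class", values="count", aggfunc="sum"
        ).fillna(0)

    ref = pivot(counts_ref)
    treat = pivot(counts_treat)
    genes = ref.index.intersection(treat.index)
    ref, treat = ref.loc[genes], treat.loc[genes]
    intr_total = ref.get("intronic_only", 0) + treat.get("intronic_only", 0)
    keep = genes[np.asarray(intr_total) >= min_intronic]
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} genes pass the intronic-read filter; "
            "correlation undefined"
        )
    lfc = {}
    for cls in ("exonic_only", "intronic_only"):
        lfc[cls] = np.log2(
            (treat.loc[keep, cls] + pseudocount) / (ref.loc[keep, cls] + pseudocount)
        )
    out = pd.DataFrame(
        {
            "log2_fc_exonic": lfc["exonic_only"],
            "log2_fc_intronic": lfc["intronic_only"],
        },
        index=keep,
    )
    out["delta"] = out["log2_fc_intronic"] - out["log2_fc_exonic"]
    out["discordant"] = out["delta"].abs() > 1.0
    if out["log2_fc_exonic"].std() == 0 or out["log2_fc_intronic"].std() == 0:
        r = 1.0 if np.allclose(out["log2_fc_exonic"], out["log2_fc_intronic"]) else np.nan
    else:
        r = float(
            stats.pearsonr(out["log2_fc_exonic"], out["log2_fc_intronic"])[0]
        )
    return out, r
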