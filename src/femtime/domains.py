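"""Basal-plus-extension regulatory domains and peak-to-gene mapping.

Each gene seeds a basal regulatory domain from 5 kb upstream to 1 kb
downstream of its TSS (in transcription orientation). The domain is then
extended on each side to the nearest other gene's basal-domain boundary,
up to a maximum of 1 Mb beyond the basal edge, and clipped at chromosome
bounds. A peak targets a gene when its midpoint falls inside the gene's
extended domain (a peak may target several genes; overlapping domains are
expected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genemodels import GeneModel

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


def _basal(tss: int, strand: str, up: int, down: int) -> Tuple[int, int]:
    if strand == "+":
        return tss - up, tss + down
    return tss - down, tss + up


def build_domains(
    genes: Sequence[GeneModel] | pd.DataFrame,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    basal_upstream: int = BASAL_UPSTREAM,
    basal_downstream: int = BASAL_DOWNSTREAM,
    max_extension: int = MAX_EXTENSION,
    cap_from: str = "basal",
) -> pd.DataFrame:
    """Regulatory domains for a gene collection.

    ``genes`` is either a GeneModel sequence or a TSS table with columns
    gene_id, chrom, tss, strand. ``cap_from`` selects whether the 1 Mb cap
    is measured from the basal-domain edge (default) or from the TSS.
    Returns a frame with basal and extended coordinates per gene.
    """
    if isinstance(genes, pd.DataFrame):
        tss_tab = genes[["gene_id", "chrom", "tss", "strand"]].copy()
    else:
        tss_tab = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "chrom": [g.chrom for g in genes],
                "tss": [g.tss for g in genes],
                "strand": [g.strand for g in genes],
            }
        )
    if cap_from not in ("basal", "tss"):
        raise ValueError("cap_from must be 'basal' or 'tss'")
    rows = []
    for chrom, sub in tss_tab.groupby("chrom", sort=False):
        tss = sub["tss"].to_numpy(dtype=np.int64)
        basal = np.array(
            [
                _basal(t, s, basal_upstream, basal_downstream)
                for t, s in zip(tss, sub["strand"])
            ],
            dtype=np.int64,
        )
        bs, be = basal[:, 0], basal[:, 1]
        n = len(sub)
        order = np.argsort(bs, kind="stable")
        bss, bes, tsss = bs[order], be[order], tss[order]
        # nearest basal boundary: running max of basal ends among genes
        # starting to the left, running min of basal starts to the right
        left_end = np.empty(n, dtype=np.int64)
        right_start = np.empty(n, dtype=np.int64)
        left_end[0] = np.iinfo(np.int64).min
        left_end[1:] = np.maximum.accumulate(bes)[:-1]
        right_start[-1] = np.iinfo(np.int64).max
        right_start[:-1] = np.minimum.accumulate(bss[::-1])[::-1][1:]
        if cap_from == "basal":
            cap_left, cap_right = bss - max_extension, bes + max_extension
        else:
            cap_left, cap_right = tsss - max_extension, tsss + max_extension
        # a neighbour's basal overlapping our own gives zero extension
        ext_s_o = np.minimum(np.maximum(cap_left, np.minimum(left_end, bss)), bss)
        ext_e_o = np.maximum(np.minimum(cap_right, np.maximum(right_start, bes)), bes)
        ext_s = np.empty(n, dtype=np.int64)
        ext_e = np.empty(n, dtype=np.int64)
        ext_s[order] = ext_s_o
        ext_e[order] = ext_e_o
        ext_s = np.maximum(ext_s, 0)
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"no chromosome length for {chrom}")
            ext_e = np.minimum(ext_e, int(chrom_sizes[chrom]))
        for j, (_, row) in enumerate(sub.iterrows()):
            rows.append(
                (
                    row["gene_id"],
                    chrom,
                    row["strand"],
                    int(bs[j]),
                    int(be[j]),
                    int(ext_s[j]),
                    int(ext_e[j]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "strand",
            "basal_start",
            "basal_end",
            "ext_start",
            "ext_end",
        ],
    ).set_index("gene_id")


def map_peaks(
    peaks: pd.DataFrame,
    domains: pd.DataFrame,
    mode: str = "midpoint",
    nearest_window: int = 10_000,
) -> pd.DataFrame:
    """Associate peaks with target genes.

    ``peaks`` needs columns peak_id, chrom, start, end. Modes:

    * ``midpoint`` — a peak targets every gene whose extended domain
      contains the peak midpoint (the GREAT convention);
    * ``overlap``  — any >=1 bp overlap between peak and extended domain;
    * ``nearest``  — the single nearest TSS within ``nearest_window`` bp of
      the peak midpoint.

    Returns long-format (peak_id, gene_id) pairs; peaks targeting no gene
    appear once with gene_id = NaN.
    """
    rows = []
    for chrom, dsub in domains.groupby("chrom", sort=False):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        mid = ((psub["start"].to_numpy() + psub["end"].to_numpy()) // 2).astype(
            np.int64
        )
        if mode in ("midpoint", "overlap"):
            ds = dsub["ext_start"].to_numpy()
            de = dsub["ext_end"].to_numpy()
            for pid, m, ps, pe in zip(psub["peak_id"], mid, psub["start"], psub["end"]):
                if mode == "midpoint":
                    hit = (ds <= m) & (m < de)
                else:
                    hit = (ds < pe) & (ps < de)
                for gid in dsub.index[hit]:
                    rows.append((pid, gid))
        elif mode == "nearest":
            tss = np.where(
                dsub["strand"].to_numpy() == "+",
                dsub["basal_start"].to_numpy() + BASAL_UPSTREAM,
                dsub["basal_end"].to_numpy() - BASAL_UPSTREAM,
            )
            for pid, m in zip(psub["peak_id"], mid):
                dist = np.abs(tss - m)
                i = int(np.argmin(dist))
                if dist[i] <= nearest_window:
                    rows.append((pid, dsub.index[i]))
        else:
            raise ValueError(f"unknown mapping mode: {mode}")
    mapped = pd.DataFrame(rows, columns=["peak_id", "gene_id"])
    unassigned = set(peaks["peak_id"]) - set(mapped["peak_id"])
    if unassigned:
        mapped = pd.concat(
            [mapped, pd.DataFrame({"peak_id": sorted(unassigned), "gene_id": np.nan})],
            ignore_index=True,
        )
    return mapped


def target_genes(target_map: pd.DataFrame) -> Set[str]:
    return set(target_map["gene_id"].dropna())


def dedupe_targets(targets_by_class: Mapping[str, Set[str]]) -> Dict[str, Set[str]]:
    """Class-exclusive target gene sets.

    Male-enriched targets drop genes also targeted by female-enriched
    peaks and vice versa; sex-independent targets drop genes targeted by
    either sex-enriched class.
    """
    male = set(targets_by_class.get("male_enriched", set()))
    female = set(targets_by_class.get("female_enriched", set()))
    indep = set(targets_by_class.get("sex_independent", set()))
    return {
        "male_enriched": male - female,
        "female_enriched": female - male,
        "sex_independent": indep - male - female,
    }
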