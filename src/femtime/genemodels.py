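"""Isoform-resolved gene models with GTF and BED12 round-trip I/O.

Internally everything is 0-based half-open; GTF lines are written and read
as 1-based inclusive, BED12 as 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .intervals import Span, merge_spans


@dataclass
class Isoform:
    isoform_id: str
    exons: List[Span]

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"isoform {self.isoform_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        for s, e in exons:
            if s < 0 or s >= e:
                raise ValueError(f"isoform {self.isoform_id}: bad exon [{s},{e})")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> List[Span]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if e1 < s2
        ]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    isoforms: List[Isoform]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id}: needs >=1 isoform")

    @property
    def start(self) -> int:
        return min(iso.start for iso in self.isoforms)

    @property
    def end(self) -> int:
        return max(iso.end for iso in self.isoforms)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """5'-most position in transcription orientation (coordinate of the
        first transcribed base for ``+`` genes; for ``-`` genes the half-open
        end, i.e. one past the first transcribed base)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def all_exons(self) -> List[Span]:
        return merge_spans(s for iso in self.isoforms for s in iso.exons)

    def all_introns(self) -> List[Span]:
        return merge_spans(s for iso in self.isoforms for s in iso.introns)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for iso in gene.isoforms:
                for s, e in iso.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{iso.isoform_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "femtime",
                                "exon",
                                str(s + 1),  # to 1-based inclusive
                                str(e),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def read_gtf(path) -> List[GeneModel]:
    """Minimal GTF reader: collects ``exon`` features by gene/transcript."""
    genes: Dict[str, Dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            parsed = dict(_ATTR_RE.findall(attrs))
            try:
                gene_id = parsed["gene_id"]
                tx_id = parsed["transcript_id"]
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing attribute {exc}") from exc
            s, e = int(start) - 1, int(end)  # to 0-based half-open
            if s < 0 or s >= e:
                raise ValueError(f"{path}:{lineno}: bad coordinates {start}..{end}")
            g = genes.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": {}})
            g["tx"].setdefault(tx_id, []).append((s, e))
    out = []
    for gene_id, g in genes.items():
        isoforms = [Isoform(tx_id, exons) for tx_id, exons in g["tx"].items()]
        out.append(GeneModel(gene_id, g["chrom"], g["strand"], isoforms))
    return out


def write_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for iso in gene.isoforms:
                s0 = iso.start
                sizes = ",".join(str(e - s) for s, e in iso.exons)
                starts = ",".join(str(s - s0) for s, _ in iso.exons)
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            str(s0),
                            str(iso.end),
                            f"{gene.gene_id}|{iso.isoform_id}",
                            "0",
                            gene.strand,
                            str(s0),
                            str(iso.end),
                            "0",
                            str(len(iso.exons)),
                            sizes + ",",
                            starts + ",",
                        ]
                    )
                    + "\n"
                )


def read_bed12(path) -> List[GeneModel]:
    genes: Dict[str, Dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, _end, name, _score, strand = fields[:6]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            s0 = int(start)
            if s0 < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            exons = [(s0 + o, s0 + o + sz) for o, sz in zip(offsets, sizes)]
            gene_id, _, tx_id = name.partition("|")
            tx_id = tx_id or name
            g = genes.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": {}})
            g["tx"][tx_id] = exons
    return [
        GeneModel(gid, g["chrom"], g["strand"],
                  [Isoform(t, ex) for t, ex in g["tx"].items()])
        for gid, g in genes.items()
    ]
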