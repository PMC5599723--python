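"""Shared tabular/BED readers and writers with line-numbered errors."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd

from .intervals import GenomicInterval

EXPRESSION_COLUMNS = ("gene_id", "condition", "replicate", "fpkm")


def read_expression_tsv(path) -> pd.DataFrame:
    """Long-format expression table: gene_id, condition, replicate, fpkm[, count]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    if (df["fpkm"] < 0).any():
        bad = df.index[df["fpkm"] < 0][0]
        raise ValueError(f"{path}: negative FPKM at data row {bad + 1}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_bed(path, min_fields: int = 3) -> pd.DataFrame:
    """BED reader returning chrom/start/end plus name/score/strand if present."""
    rows = []
    names = ["chrom", "start", "end", "name", "score", "strand"]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ValueError(f"{path}:{lineno}: expected >={min_fields} BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            row = dict(zip(names, fields[:6]))
            row["start"], row["end"] = start, end
            rows.append(row)
    return pd.DataFrame(rows)


def read_peaks_bed(path, peak_class: Optional[str] = None) -> pd.DataFrame:
    df = read_bed(path, min_fields=3)
    if "name" not in df.columns or df["name"].isna().any():
        df["name"] = [f"peak_{i}" for i in range(len(df))]
    df = df.rename(columns={"name": "peak_id"})
    if peak_class is not None:
        df["peak_class"] = peak_class
    return df[["peak_id", "chrom", "start", "end"]
              + (["peak_class"] if peak_class else [])]


def reads_from_bed(path) -> List[GenomicInterval]:
    df = read_bed(path, min_fields=3)
    strands = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        GenomicInterval(c, s, e, st if st in ("+", "-") else ".")
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strands)
    ]


def read_chrom_sizes(path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            out[fields[0]] = int(fields[1])
    return out


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
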