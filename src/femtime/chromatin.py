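"""Rule-based per-gene chromatin-state calls (active / poised / inactive).

States are called per sex from normalized read densities of seven
chromatin features (DHS plus six histone marks) in 2-kb windows centred on
the TSS and TES. Densities are log2(x+1)-transformed, averaged over the
two windows, z-scored per feature across the gene universe and binarized;
the rule cascade is:

* active   — DHS, H3K27ac and H3K4me1 all high;
* poised   — H3K4me1 and H3K27me3 high, H3K27ac low (activating and
  repressive marks together but no enhancer acetylation);
* inactive — H3K27me3 high with H3K4me1 and H3K27ac low;
* unclassified otherwise.

The binarization threshold defaults to the per-feature grand mean
(z > 0): for a bimodal feature this split is robust to the mixture
proportion of high- and low-density genes, which a positive cutoff is not
once the high mode is in the majority.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FEATURES = (
    "dhs",
    "h3k27ac",
    "h3k4me1",
    "h3k4me3",
    "h3k36me3",
    "h3k27me3",
    "h3k9me3",
)
STATE_RANK = {"active": 3, "poised": 2, "unclassified": 1, "inactive": 0}
Z_HIGH = 0.0
MIN_GENE_LENGTH = 5_000


def feature_zscores(features: pd.DataFrame) -> pd.DataFrame:
    """Aggregate TSS/TES windows and z-score each feature across genes.

    ``features`` is long-format with columns gene_id, sex, window and the
    seven feature density columns. Returns one row per (gene, sex) with
    z-scored features; z-scoring is done within sex. A zero-variance
    feature maps to z = 0.
    """
    missing = [f for f in FEATURES if f not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    agg = (
        features.assign(
            **{f: np.log2(features[f].astype(float) + 1.0) for f in FEATURES}
        )
        .groupby(["gene_id", "sex"])[list(FEATURES)]
        .mean()
        .reset_index()
    )
    out = []
    for sex, sub in agg.groupby("sex", sort=False):
        z = sub[list(FEATURES)].copy()
        sd = z.std(ddof=0)
        mu = z.mean()
        for f in FEATURES:
            z[f] = 0.0 if sd[f] == 0 else (z[f] - mu[f]) / sd[f]
        z.insert(0, "sex", sex)
        z.insert(0, "gene_id", sub["gene_id"].to_numpy())
        out.append(z)
    return pd.concat(out, ignore_index=True)


def call_state(z: Mapping[str, float], z_high: float = Z_HIGH) -> str:
    """State call for one gene/sex from z-scored features (high = z > z_high)."""
    hi = {f: z[f] > z_high for f in FEATURES}
    if hi["dhs"] and hi["h3k27ac"] and hi["h3k4me1"]:
        return "active"
    if hi["h3k4me1"] and hi["h3k27me3"] and not hi["h3k27ac"]:
        return "poised"
    if hi["h3k27me3"] and not hi["h3k4me1"] and not hi["h3k27ac"]:
        return "inactive"
    return "unclassified"


def call_states(features: pd.DataFrame, z_high: float = Z_HIGH) -> pd.DataFrame:
    """State calls for every (gene, sex) in a feature table."""
    z = feature_zscores(features)
    z["state"] = [
        call_state(row, z_high) for row in z[list(FEATURES)].to_dict("records")
    ]
    return z[["gene_id", "sex", "state"]]


def state_transitions(calls: pd.DataFrame) -> pd.DataFrame:
    """Male-to-female state transition per gene.

    ``calls`` has columns gene_id, sex, state with sex in {male, female}.
    Genes present in one sex only are dropped. ``more_active_in_female``
    uses the ordering active > poised > unclassified > inactive.
    """
    wide = calls.pivot_table(
        index="gene_id", columns="sex", values="state", aggfunc="first"
    )
    if "male" not in wide.columns or "female" not in wide.columns:
        raise ValueError("calls must cover both sexes")
    wide = wide.dropna(subset=["male", "female"])
    out = pd.DataFrame(
        {
            "state_male": wide["male"],
            "state_female": wide["female"],
        }
    )
    out["changed"] = out["state_male"] != out["state_female"]
    out["more_active_in_female"] = [
        STATE_RANK[f] > STATE_RANK[m]
        for m, f in zip(out["state_male"], out["state_female"])
    ]
    return out


def transition_summary(transitions: pd.DataFrame) -> pd.DataFrame:
    return (
        transitions.groupby(["state_male", "state_female"])
        .size()
        .rename("n_genes")
        .reset_index()
    )


def eligible_genes(
    gene_lengths: Mapping[str, int],
    features: Optional[pd.DataFrame] = None,
    min_length: int = MIN_GENE_LENGTH,
) -> set:
    """Genes long enough for non-overlapping TSS/TES windows, with data.

    Genes shorter than ``min_length`` (whose TSS-proximal window would
    overlap the TES window) are removed, as are genes absent from the
    feature table when one is given.
    """
    keep = {g for g, ln in gene_lengths.items() if ln >= min_length}
    if features is not None:
        keep &= set(features["gene_id"])
    return keep
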