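"""Liver zonation-bias statistics on 9-zone expression profiles.

Zones are numbered 1 (pericentral, nearest the central vein) through 9
(periportal). The zonation bias of a profile v is

    bias = (v1 - v9) / mean(v1..v9)

so positive values indicate pericentral and negative values periportal
preference; the statistic is scale-invariant and reversing a profile
negates it exactly. Genes count as significantly zonated when their
differential-zonation q-value (consumed as input) is below 0.2.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

N_ZONES = 9
Q_CUTOFF = 0.2
ZONE_COLUMNS = tuple(f"zone_{i}" for i in range(1, N_ZONES + 1))
#: largest per-group size for which the rank-sum test is run exactly
EXACT_LIMIT = 20


def zonation_bias(zone_values) -> float:
    """(zone1 - zone9) / mean over the nine zones; NaN for an all-zero profile."""
    v = np.asarray(zone_values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[1] != N_ZONES:
        raise ValueError(f"expected {N_ZONES} zones, got {v.shape[1]}")
    m = v.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (v[:, 0] - v[:, -1]) / m
    out = np.where(m > 0, out, np.nan)
    return float(out[0]) if out.shape[0] == 1 and np.ndim(zone_values) == 1 else out


def pc_pp_ratio(zone_values) -> float:
    """Pericentral/periportal display ratio: mean(zones 1-3)/mean(zones 7-9).

    NaN (sorted last in display orderings) when the periportal mean is 0.
    """
    v = np.asarray(zone_values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[1] != N_ZONES:
        raise ValueError(f"expected {N_ZONES} zones, got {v.shape[1]}")
    pc = v[:, :3].mean(axis=1)
    pp = v[:, 6:].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pp > 0, pc / pp, np.nan)
    return float(out[0]) if out.shape[0] == 1 and np.ndim(zone_values) == 1 else out


def bias_table(profiles: pd.DataFrame, q_cutoff: float = Q_CUTOFF) -> pd.DataFrame:
    """Per-gene bias, PC/PP ratio and significance flag from a zonation table.

    ``profiles`` needs columns gene_id, zone_1..zone_9 and q_value.
    """
    v = profiles[list(ZONE_COLUMNS)].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "gene_id": profiles["gene_id"],
            "zonation_bias": zonation_bias(v),
            "pc_pp_ratio": pc_pp_ratio(v),
            "q_value": profiles["q_value"],
        }
    )
    out["significantly_zonated"] = out["q_value"] < q_cutoff
    return out


def compare_zonation(
    bias_a: Sequence[float],
    bias_b: Sequence[float],
    exact_limit: int = EXACT_LIMIT,
) -> Dict[str, float]:
    """Two-sided Wilcoxon rank-sum comparison of two bias-value groups.

    Groups should already be restricted to significantly zonated genes.
    The exact null distribution is used for group sizes up to
    ``exact_limit``; larger groups use the normal approximation with
    continuity correction. Ties are mid-ranked.
    """
    a = np.asarray(bias_a, dtype=float)
    b = np.asarray(bias_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 genes")
    method = "exact" if max(len(a), len(b)) <= exact_limit else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "method": method,
    }
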