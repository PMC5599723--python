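"""Odds-ratio enrichment scores and Fisher exact tests on 2x2 gene-set tables.

The enrichment score for a table ``[[a, b], [c, d]]`` is the sample odds
ratio (a/b)/(c/d). Significance is the two-sided Fisher exact probability:
the sum of hypergeometric point probabilities of all tables with the same
margins that are no more probable than the observed one.

For small tables (total <= ``exact_limit``) the p-value is computed by
exact integer enumeration, which makes it bit-reproducible against an
independent enumeration oracle; larger tables delegate to
:func:`scipy.stats.fisher_exact`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Set

import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "enrichment_2x2",
    "fisher_exact_two_sided",
    "target_set_enrichment",
    "cluster_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 table with its enrichment score and Fisher exact p-value.

    a = foreground with property, b = foreground without,
    c = comparison with property, d = comparison without.
    """

    a: int
    b: int
    c: int
    d: int
    es: float
    p: float
    direction: str

    def as_dict(self) -> Dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "es": self.es, "p": self.p, "direction": self.direction,
        }


def fisher_exact_two_sided(a: int, b: int, c: int, d: int,
                           exact_limit: int = 1000) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all fixed-margin tables whose
    point probability does not exceed the observed one. Exact integer
    arithmetic for totals <= exact_limit.
    """
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero 2x2 table")
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    if n > exact_limit:
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    # weight_k is proportional to the hypergeometric pmf at a = k
    weights = [math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / math.comb(n, c1)


def enrichment_2x2(a: int, b: int, c: int, d: int,
                   haldane: bool = False) -> EnrichmentResult:
    """Enrichment score (a*d)/(b*c) with two-sided Fisher exact p.

    Zero cells: es = +inf when b*c = 0 with a*d > 0, 0.0 when a*d = 0 with
    b*c > 0, and nan when both products vanish — unless ``haldane`` adds
    0.5 to every cell for the score (the p-value always uses raw counts).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("negative cell in 2x2 table")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table")
    if haldane:
        es = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    elif b * c > 0:
        es = (a * d) / (b * c)
    elif a * d > 0:
        es = math.inf
    else:
        es = math.nan
    p = fisher_exact_two_sided(a, b, c, d)
    direction = "enriched" if es > 1 else "depleted"
    return EnrichmentResult(a, b, c, d, es, p, direction)


def target_set_enrichment(targets: Set[str], foreground: Set[str],
                          background: Set[str],
                          haldane: bool = False) -> EnrichmentResult:
    """Enrichment of a peak-target gene set for foreground vs background genes.

    Foreground is typically a sex-biased gene set, background the stringent
    sex-independent genes; the two must be disjoint.
    """
    if not foreground or not background:
        raise ValueError("empty foreground or background gene set")
    if foreground & background:
        raise ValueError("foreground and background overlap")
    a = len(foreground & targets)
    b = len(foreground - targets)
    c = len(background & targets)
    d = len(background - targets)
    return enrichment_2x2(a, b, c, d, haldane=haldane)


def cluster_enrichment(property_genes: Set[str],
                       cluster_assignments: Mapping[str, object],
                       cluster_label,
                       haldane: bool = False) -> EnrichmentResult:
    """Enrichment of one response cluster for a gene property.

    ``cluster_assignments`` maps each responsive same-sex gene to its
    cluster label; the comparison group is every assigned gene not in the
    named cluster. ``cluster_label`` may be a single label or an iterable
    of labels pooled into one foreground (e.g. the early clusters 1+2).
    """
    if isinstance(cluster_label, (str, int)):
        labels = {cluster_label}
    else:
        labels = set(cluster_label)
    fg = {g for g, lab in cluster_assignments.items() if lab in labels}
    cmp_ = {g for g, lab in cluster_assignments.items() if lab not in labels}
    if not fg:
        raise ValueError(f"empty cluster {cluster_label!r}")
    a = len(fg & property_genes)
    b = len(fg - property_genes)
    c = len(cmp_ & property_genes)
    d = len(cmp_ - property_genes)
    return enrichment_2x2(a, b, c, d, haldane=haldane)


def results_frame(named_results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for name, res in named_results.items():
        row = {"comparison": name}
        row.update(res.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
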