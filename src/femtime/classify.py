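"""Sex-bias classification and percent-feminization statistics.

The central statistic expresses a treated-male expression level as the
fraction of the distance travelled from the untreated-male level toward
the female level:

    % feminization = 100 * (FPKM_cGH - FPKM_sham) / (FPKM_female - FPKM_sham)

0% means the gene still sits at the male level, 100% that it has reached
the female level; values can exceed 100 (overshoot) or be negative.

The differential test used throughout is a stand-in for a count-based
negative-binomial test: Welch's t on log2(FPKM + 1) across replicates with
Benjamini-Hochberg correction per contrast. Externally supplied adjusted
p-values are accepted verbatim wherever a contrast is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FEMALE = "female"
SHAM_MALE = "sham_male"
UNTREATED_MALE = "untreated_male"
TIMEPOINTS = ("cgh_10h", "cgh_1d", "cgh_4d", "cgh_7d", "cgh_14d")
CONDITIONS = (FEMALE, SHAM_MALE) + TIMEPOINTS

#: default FPKM floor on the feminization denominator |female - sham|
DENOM_EPS = 0.25
#: pseudo-FPKM floor used when forming sex fold changes
FOLD_FLOOR = 0.1


def percent_feminization(fpkm_cgh, fpkm_sham, fpkm_female, eps: float = DENOM_EPS):
    """Percent feminization; NaN where the denominator magnitude is <= eps.

    Accepts scalars or array-likes (broadcast elementwise). The statistic is
    invariant to rescaling all three inputs by a common positive factor.
    """
    cgh = np.asarray(fpkm_cgh, dtype=float)
    sham = np.asarray(fpkm_sham, dtype=float)
    fem = np.asarray(fpkm_female, dtype=float)
    denom = fem - sham
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (cgh - sham) / denom
    out = np.where(np.abs(denom) <= eps, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def _condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Gene x condition matrix of replicate-averaged FPKM."""
    return table.pivot_table(
        index="gene_id", columns="condition", values="fpkm", aggfunc="mean"
    )


def _replicate_matrix(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    sub = table[table["condition"] == condition]
    return sub.pivot_table(index="gene_id", columns="replicate", values="fpkm")


def differential_test(table: pd.DataFrame, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Welch's t on log2(FPKM+1) per gene between two conditions, BH-corrected.

    Returns a frame indexed by gene_id with columns p, p_adj, log2_fc
    (mean-based, cond_a over cond_b with the pseudo-FPKM floor).
    """
    a = _replicate_matrix(table, cond_a)
    b = _replicate_matrix(table, cond_b)
    if a.empty or b.empty:
        raise ValueError(f"missing condition: {cond_a if a.empty else cond_b}")
    genes = a.index.intersection(b.index)
    la = np.log2(a.loc[genes].to_numpy(dtype=float) + 1.0)
    lb = np.log2(b.loc[genes].to_numpy(dtype=float) + 1.0)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # noiseless replicates trip scipy's precision-loss warning; the NaN
        # p-values it produces are resolved just below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    # zero-variance pairs (e.g. a noiseless simulation) yield NaN: identical
    # means are maximally unsurprising, different means maximally surprising
    mean_a = np.nanmean(la, axis=1)
    mean_b = np.nanmean(lb, axis=1)
    nanmask = ~np.isfinite(p)
    p[nanmask] = np.where(np.isclose(mean_a[nanmask], mean_b[nanmask]), 1.0, 0.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    fa = np.maximum(np.nanmean(a.loc[genes].to_numpy(dtype=float), axis=1), FOLD_FLOOR)
    fb = np.maximum(np.nanmean(b.loc[genes].to_numpy(dtype=float), axis=1), FOLD_FLOOR)
    return pd.DataFrame(
        {"p": p, "p_adj": p_adj, "log2_fc": np.log2(fa / fb)}, index=genes
    )


def classify_sex_bias(
    table: pd.DataFrame,
    padj: Optional[pd.Series] = None,
    chrom: Optional[Mapping[str, str]] = None,
    p_biased: float = 0.01,
    p_indep: float = 0.1,
    fold_stringent: float = 2.0,
    fold_indep: float = 1.2,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene's sex bias from an expression table.

    Gates and thresholds: liver-expressed requires mean FPKM > ``min_fpkm``
    in either sex; sex-biased requires adjusted p < ``p_biased``; the
    stringent sex-biased subset additionally requires a > ``fold_stringent``
    male/female fold difference in every available male-reference contrast
    (untreated and/or sham males); stringent sex-independent requires
    adjusted p > ``p_indep`` and fold < ``fold_indep``. Y-chromosome genes
    are flagged and excluded from the sex-biased classes when chromosome
    labels are supplied.
    """
    means = _condition_means(table)
    if FEMALE not in means.columns or SHAM_MALE not in means.columns:
        raise ValueError("expression table must contain female and sham_male")
    if padj is None:
        padj = differential_test(table, SHAM_MALE, FEMALE)["p_adj"]
    genes = means.index
    padj = padj.reindex(genes)

    fem_mean = means[FEMALE].fillna(0.0)
    male_refs = [c for c in (UNTREATED_MALE, SHAM_MALE) if c in means.columns]
    ref_means = {c: means[c].fillna(0.0) for c in male_refs}
    primary_male = ref_means[SHAM_MALE if SHAM_MALE in ref_means else male_refs[0]]

    fem_f = np.maximum(fem_mean, FOLD_FLOOR)
    log2_ratio = np.log2(np.maximum(primary_male, FOLD_FLOOR) / fem_f)
    folds = pd.DataFrame(
        {
            c: np.maximum(
                np.maximum(m, FOLD_FLOOR) / fem_f, fem_f / np.maximum(m, FOLD_FLOOR)
            )
            for c, m in ref_means.items()
        }
    )
    min_fold = folds.min(axis=1)

    expressed = (primary_male > min_fpkm) | (fem_mean > min_fpkm)
    if chrom is not None:
        excluded_y = genes.to_series().map(
            lambda g: str(chrom.get(g, "")).lower() in ("chry", "y")
        )
    else:
        excluded_y = pd.Series(False, index=genes)

    significant = expressed & (padj < p_biased)
    stringent = significant & (min_fold > fold_stringent) & ~excluded_y
    biased = significant & ~stringent & ~excluded_y
    indep = expressed & (padj > p_indep) & (min_fold < fold_indep)

    cls = pd.Series("other", index=genes)
    cls[indep] = "stringent_sex_independent"
    cls[biased] = "sex_biased"
    cls[stringent] = "stringent_sex_biased"

    direction = pd.Series("none", index=genes)
    direction[significant & (log2_ratio > 0)] = "male"
    direction[significant & (log2_ratio < 0)] = "female"

    return pd.DataFrame(
        {
            "log2_sex_ratio": log2_ratio,
            "p_adj": padj,
            "class": cls,
            "direction": direction,
            "excluded_y": excluded_y,
            "expressed": expressed,
        },
        index=genes,
    )


def feminization_profiles(
    table: pd.DataFrame,
    padj_by_timepoint: Optional[Mapping[str, pd.Series]] = None,
    timepoints: Sequence[str] = TIMEPOINTS,
    eps: float = DENOM_EPS,
    p_responsive: float = 0.05,
    min_feminization: float = 20.0,
) -> pd.DataFrame:
    """Per-gene feminization trajectory with per-timepoint responsiveness.

    Feminization is computed on replicate-averaged FPKM. A timepoint is
    responsive when its cGH-vs-sham contrast reaches adjusted
    p < ``p_responsive`` and feminization >= ``min_feminization``; a gene is
    responsive when any timepoint is, and fully feminized when its maximal
    feminization reaches 100%.
    """
    means = _condition_means(table)
    for c in (FEMALE, SHAM_MALE):
        if c not in means.columns:
            raise ValueError(f"missing condition: {c}")
    present = [t for t in timepoints if t in means.columns]
    sham = means[SHAM_MALE].to_numpy(dtype=float)
    fem = means[FEMALE].to_numpy(dtype=float)
    out = pd.DataFrame(index=means.index)
    for t in present:
        out[f"fem_{t}"] = percent_feminization(
            means[t].to_numpy(dtype=float), sham, fem, eps=eps
        )
    for t in present:
        if padj_by_timepoint is not None and t in padj_by_timepoint:
            pa = padj_by_timepoint[t].reindex(means.index)
        else:
            pa = differential_test(table, t, SHAM_MALE)["p_adj"].reindex(means.index)
        out[f"padj_{t}"] = pa
        out[f"responsive_{t}"] = (pa < p_responsive) & (
            out[f"fem_{t}"] >= min_feminization
        )
    fem_cols = [f"fem_{t}" for t in present]
    out["undefined_fem"] = out[fem_cols].isna().any(axis=1)
    out["max_feminization"] = out[fem_cols].max(axis=1)
    arr = out[fem_cols].to_numpy(dtype=float)
    all_na = np.isnan(arr).all(axis=1)
    argmax = np.nanargmax(np.where(np.isnan(arr), -np.inf, arr), axis=1)
    out["max_timepoint"] = [
        None if na else present[i] for i, na in zip(argmax, all_na)
    ]
    out["responsive"] = out[[f"responsive_{t}" for t in present]].any(axis=1)
    out["fully_feminized"] = out["max_feminization"] >= 100.0
    return out


def flag_responsive(
    feminization: pd.DataFrame,
    padj: pd.DataFrame,
    p_responsive: float = 0.05,
    min_feminization: float = 20.0,
) -> pd.DataFrame:
    """Responsiveness flags from precomputed feminization and p_adj matrices.

    Both frames are gene x timepoint with identical column order.
    """
    resp = (padj < p_responsive) & (feminization >= min_feminization)
    out = resp.copy()
    out.columns = [f"responsive_{c}" for c in resp.columns]
    out["responsive"] = resp.any(axis=1)
    out["max_feminization"] = feminization.max(axis=1)
    out["fully_feminized"] = out["max_feminization"] >= 100.0
    return out
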