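"""Model-profile screening and time-response clustering of feminization curves.

A bank of integer-valued model profiles (temporal templates starting at 0
with bounded per-step change, after the short time-series expression miner
approach) is built independently of the data by greedy max-min selection
under correlation distance. Each gene's feminization trajectory is
assigned to the profile it correlates with best; per-profile significance
is an empirical FDR from within-gene timepoint permutations. Genes passing
the profile screen are then partitioned by complete-linkage hierarchical
clustering of their feminization vectors, separately per sex, and cluster
labels are renumbered by response onset time (cluster 1 = earliest to
reach 50% feminization).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

MAX_STEP = 10
N_PROFILES = 8
MIN_CORRELATION = 0.7
#: enumerate the candidate path space exhaustively up to this size
MAX_ENUMERATION = 200_000
SAMPLE_POOL = 20_000
FEM_CLIP = (-50.0, 150.0)


@dataclass(frozen=True)
class ModelProfile:
    profile_id: int
    values: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.values[0] != 0:
            raise ValueError("model profiles start at 0")


def _standardize(x: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit norm; zero-variance rows become 0."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, x / norm, 0.0)
    return out


def correlation_matrix(vectors: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation of each vector with each profile.

    Pairs involving a zero-variance series get correlation 0 (distance 1).
    """
    return _standardize(vectors) @ _standardize(profiles).T


def generate_model_profiles(
    n_timepoints: int,
    max_step: int = MAX_STEP,
    n_profiles: int = N_PROFILES,
    seed: int = 0,
    max_enumeration: int = MAX_ENUMERATION,
    sample_pool: int = SAMPLE_POOL,
) -> List[ModelProfile]:
    """Build a bank of model profiles by greedy max-min selection.

    Candidates are integer paths of length ``n_timepoints`` starting at 0
    with per-step changes in [-max_step, max_step]; the space is enumerated
    exhaustively when it has at most ``max_enumeration`` paths and sampled
    uniformly otherwise. The flat profile and the monotone-up staircase are
    always included; remaining profiles maximize the minimum correlation
    distance d = 1 - Pearson to the already-selected set.
    """
    if n_profiles < 2 or max_step < 1 or n_timepoints < 3:
        raise ValueError("need n_profiles >= 2, max_step >= 1, n_timepoints >= 3")
    steps = np.arange(-max_step, max_step + 1)
    n_paths = len(steps) ** (n_timepoints - 1)
    rng = np.random.default_rng(seed)
    if n_paths <= max_enumeration:
        deltas = np.array(list(itertools.product(steps, repeat=n_timepoints - 1)))
    else:
        deltas = rng.choice(steps, size=(sample_pool, n_timepoints - 1))
        deltas = np.unique(deltas, axis=0)
    paths = np.concatenate(
        [np.zeros((len(deltas), 1), dtype=int), np.cumsum(deltas, axis=1)], axis=1
    )
    flat = np.zeros(n_timepoints, dtype=int)
    stair = np.arange(n_timepoints) * max_step
    seeds = np.stack([flat, stair])
    # drop candidates equal to a seed
    keep = ~(paths[:, None, :] == seeds[None, :, :]).all(axis=2).any(axis=1)
    paths = paths[keep]
    if n_profiles > len(paths) + 2:
        raise ValueError("n_profiles exceeds the number of distinct candidates")
    selected = [flat, stair]
    if n_profiles > 2:
        cand_std = _standardize(paths)
        min_dist = np.full(len(paths), np.inf)
        for s in selected:
            corr = cand_std @ _standardize(s[None, :])[0]
            min_dist = np.minimum(min_dist, 1.0 - corr)
        for _ in range(n_profiles - 2):
            i = int(np.argmax(min_dist))
            selected.append(paths[i])
            corr = cand_std @ cand_std[i]
            min_dist = np.minimum(min_dist, 1.0 - corr)
            min_dist[i] = -np.inf
    return [
        ModelProfile(j, tuple(int(v) for v in p)) for j, p in enumerate(selected)
    ]


def assign_genes(
    profiles: Sequence[ModelProfile],
    vectors: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each gene to its best-correlated model profile.

    ``vectors`` is gene x timepoint. Ties break toward the lowest profile
    id; a zero-variance gene vector has correlation 0 with everything and
    therefore lands on the flat profile (id 0) by the tie-break. Profile
    significance: observed assignment counts are compared with counts from
    permuting each gene's timepoint order independently; empirical
    p-values are BH-corrected across profiles into FDRs.

    Returns (per-gene assignments, per-profile summary).
    """
    prof_mat = np.array([p.values for p in profiles], dtype=float)
    x = vectors.to_numpy(dtype=float)
    corr = correlation_matrix(x, prof_mat)
    best = np.argmax(corr, axis=1)  # argmax takes the first (lowest id) on ties
    best_corr = corr[np.arange(len(x)), best]
    assignments = pd.DataFrame(
        {
            "profile_id": [profiles[i].profile_id for i in best],
            "correlation": best_corr,
        },
        index=vectors.index,
    )

    m = len(profiles)
    obs_counts = np.bincount(best, minlength=m)
    rng = np.random.default_rng(seed)
    x_std = _standardize(x)
    prof_std = _standardize(prof_mat)
    exceed = np.zeros(m, dtype=int)
    t = x.shape[1]
    for _ in range(n_permutations):
        perm = np.argsort(rng.random((len(x), t)), axis=1)
        xp = np.take_along_axis(x_std, perm, axis=1)
        pb = np.argmax(xp @ prof_std.T, axis=1)
        exceed += np.bincount(pb, minlength=m) >= obs_counts
    pvals = (1 + exceed) / (n_permutations + 1)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    summary = pd.DataFrame(
        {
            "profile_id": [p.profile_id for p in profiles],
            "n_assigned": obs_counts,
            "p": pvals,
            "fdr": fdr,
        }
    )
    return assignments, summary


def select_for_clustering(
    profiles: Sequence[ModelProfile],
    assignments: pd.DataFrame,
    min_correlation: float = MIN_CORRELATION,
    max_fold_induction: Optional[pd.Series] = None,
    max_feminization: Optional[pd.Series] = None,
    fold_rescue: float = 4.0,
) -> pd.Index:
    """Two-stage gene screen ahead of clustering.

    Stage 1 keeps genes whose best-profile correlation reaches
    ``min_correlation`` and whose best profile has a net positive
    feminization trend (final value above its starting 0). Stage 2 rescues
    strongly induced genes that feminize weakly: maximal fold induction
    >= ``fold_rescue`` but maximal feminization < 20%.
    """
    trend = {p.profile_id: p.values[-1] > 0 for p in profiles}
    stage1 = assignments.index[
        (assignments["correlation"] >= min_correlation)
        & assignments["profile_id"].map(trend)
    ]
    selected = set(stage1)
    if max_fold_induction is not None and max_feminization is not None:
        rescue = max_fold_induction.index[
            (max_fold_induction >= fold_rescue)
            & (max_feminization.reindex(max_fold_induction.index) < 20.0)
        ]
        selected |= set(rescue)
    return assignments.index[assignments.index.isin(selected)]


def _onset_index(mean_traj: np.ndarray, threshold: float = 50.0) -> int:
    above = np.nonzero(mean_traj >= threshold)[0]
    return int(above[0]) if len(above) else len(mean_traj)


def cluster_feminization(
    vectors: pd.DataFrame,
    k: int = 5,
    clip: Tuple[float, float] = FEM_CLIP,
    metric: str = "euclidean",
) -> pd.Series:
    """Complete-linkage clustering of feminization vectors into k clusters.

    Rows with any NA feminization are excluded (returned label -1 marks
    exclusion is not used: excluded genes are simply absent from the
    result). Values are clipped to ``clip`` to bound outlier leverage
    before computing distances. Cluster labels 1..k are ordered by onset
    time (mean trajectory's first timepoint at >= 50% feminization,
    earliest first; ties by higher final feminization).
    """
    vec = vectors.dropna()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(vec):
        raise ValueError(f"k={k} exceeds {len(vec)} genes")
    x = np.clip(vec.to_numpy(dtype=float), clip[0], clip[1])
    if k == 1 or len(vec) == 1:
        return pd.Series(1, index=vec.index, name="cluster")
    link = hierarchy.linkage(x, method="complete", metric=metric)
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw),
        key=lambda c: (
            _onset_index(x[raw == c].mean(axis=0)),
            -float(x[raw == c].mean(axis=0)[-1]),
        ),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=vec.index, name="cluster")
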