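"""Synthetic study generator with known ground truth.

Emulates the design of a continuous-GH-infusion liver time course: a
gene-by-condition-by-replicate FPKM table over {control female, sham male,
cGH 10 h / 1 d / 4 d / 7 d / 14 d}, isoform-resolved gene models on a
synthetic chromosome, transcription-factor/DHS peak sets planted inside or
outside target-gene regulatory domains at a controlled odds ratio,
state-conditional chromatin-feature densities, and 9-zone zonation
profiles with a planted pericentral/periportal bias.

Replicate noise is lognormal in FPKM (normal in log2), the standard
abundance-noise stand-in that keeps FPKM positive. Condition means follow
planted per-cluster feminization trajectories, so with noise_sd = 0 every
downstream feminization value reproduces the planted curve exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classify import FEMALE, SHAM_MALE, TIMEPOINTS
from .genemodels import GeneModel, Isoform, write_gtf
from .chromatin import FEATURES

#: mean percent feminization per response cluster at each timepoint
#: (10 h, 1 d, 4 d, 7 d, 14 d); saturated responses (">100") encoded as 105
CLUSTER_TRAJECTORIES: Dict[str, Dict[str, Tuple[float, ...]]] = {
    "male": {
        "1": (61, 88, 105, 105, 105),
        "2": (6, 60, 105, 99, 105),
        "3": (40, 41, 105, 105, 105),
        "4": (0, 2, 92, 89, 105),
        "5": (0, 0, 65, 60, 79),
        "NR": (0, 0, 0, 0, 0),
    },
    "female": {
        "1": (39, 105, 105, 105, 105),
        "2": (13, 22, 105, 105, 105),
        "3": (8, 14, 35, 82, 105),
        "4": (8, 3, 26, 30, 64),
        "5": (4, 1, 5, 4, 16),
        "NR": (0, 0, 0, 0, 0),
    },
}

#: default cluster mixture (proportional to observed cluster sizes)
CLUSTER_FRACTIONS: Dict[str, Dict[str, float]] = {
    "male": {"1": 15 / 103, "2": 39 / 103, "3": 19 / 103, "4": 13 / 103,
             "5": 7 / 103, "NR": 10 / 103},
    "female": {"1": 26 / 132, "2": 37 / 132, "3": 18 / 132, "4": 26 / 132,
               "5": 13 / 132, "NR": 12 / 132},
}

STATE_FEATURE_MEANS: Dict[str, Dict[str, float]] = {
    # log2 read-density modes per chromatin state; activating marks high in
    # the active state, H3K4me1+H3K27me3 without H3K27ac in poised,
    # repressive marks dominating in inactive
    "active": dict(dhs=8, h3k27ac=8, h3k4me1=8, h3k4me3=8, h3k36me3=7,
                   h3k27me3=1, h3k9me3=1),
    "poised": dict(dhs=3, h3k27ac=1, h3k4me1=8, h3k4me3=4, h3k36me3=3,
                   h3k27me3=8, h3k9me3=3),
    "inactive": dict(dhs=1, h3k27ac=1, h3k4me1=1, h3k4me3=1, h3k36me3=1,
                     h3k27me3=8, h3k9me3=8),
}

_COUNT_DEPTH = 50.0  # nominal FPKM -> count scaling for the counts column


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator."""

    n_genes: int = 300
    class_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "male_biased": 0.25,
            "female_biased": 0.25,
            "sex_independent": 0.5,
        }
    )
    cluster_fractions: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {s: dict(d) for s, d in CLUSTER_FRACTIONS.items()}
    )
    cluster_trajectories: Dict[str, Dict[str, Tuple[float, ...]]] = field(
        default_factory=lambda: {s: dict(d) for s, d in CLUSTER_TRAJECTORIES.items()}
    )
    timepoints: Tuple[str, ...] = TIMEPOINTS
    n_replicates: int = 3
    noise_sd: float = 0.15
    sex_ratio_range: Tuple[float, float] = (2.5, 16.0)
    base_fpkm_range: Tuple[float, float] = (2.0, 128.0)
    seed: int = 0
    genome_length: int = 120_000_000
    n_chromosomes: int = 1
    n_y_genes: int = 0
    n_peaks: int = 0
    target_enrichment: float = 5.0
    background_target_rate: float = 0.3
    feature_noise_sd: float = 0.5
    zonation_noise_sd: float = 0.1
    zonated_fraction: float = 0.54

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("counts must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        for sex, frac in self.cluster_fractions.items():
            if abs(sum(frac.values()) - 1.0) > 1e-9:
                raise ValueError(f"cluster_fractions[{sex}] must sum to 1")
        if self.target_enrichment <= 0:
            raise ValueError("target_enrichment must be positive")
        if not 0 < self.background_target_rate < 1:
            raise ValueError("background_target_rate must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted per-gene truth and peak-target flags."""

    genes: pd.DataFrame  # indexed by gene_id
    peak_targets: Dict[str, Set[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="records"),
            "peak_targets": {k: sorted(v) for k, v in self.peak_targets.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _allocate(n: int, fractions: Mapping[str, float]) -> List[str]:
    """Deterministic largest-remainder allocation of n items to categories."""
    keys = list(fractions)
    raw = np.array([fractions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    out: List[str] = []
    for k, b in zip(keys, base):
        out.extend([k] * b)
    return out


def simulate_expression(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Expression table plus ground truth for every planted gene.

    Each gene gets a sex class, a response cluster (sex-biased genes only),
    chromatin states per sex and a zonation bias; condition means follow
    the planted cluster trajectory and replicates add lognormal noise.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    classes = np.array(_allocate(n, config.class_fractions))
    rng.shuffle(classes)

    log_lo, log_hi = np.log2(config.base_fpkm_range)
    base = 2.0 ** rng.uniform(log_lo, log_hi, size=n)
    flo, fhi = np.log2(config.sex_ratio_range)
    fold = 2.0 ** rng.uniform(flo, fhi, size=n)

    sham = np.where(classes == "male_biased", base * fold, base)
    female = np.where(classes == "female_biased", base * fold, base)

    clusters = np.array(["NA"] * n, dtype=object)
    for sex, cls in (("male", "male_biased"), ("female", "female_biased")):
        idx = np.nonzero(classes == cls)[0]
        labels = _allocate(len(idx), config.cluster_fractions[sex])
        rng.shuffle(idx)
        for i, lab in zip(idx, labels):
            clusters[i] = f"{sex[0].upper()}{lab}" if lab != "NR" else f"{sex[0].upper()}NR"

    t_idx = {t: j for j, t in enumerate(config.timepoints)}
    fem_frac = np.zeros((n, len(config.timepoints)))
    for i in range(n):
        if classes[i] == "sex_independent":
            continue
        sex = "male" if classes[i] == "male_biased" else "female"
        lab = clusters[i][1:]
        traj = config.cluster_trajectories[sex][lab]
        fem_frac[i] = np.asarray(traj, dtype=float) / 100.0

    cond_means = {FEMALE: female, SHAM_MALE: sham}
    for t, j in t_idx.items():
        cond_means[t] = sham + fem_frac[:, j] * (female - sham)

    rows = []
    for cond, mean in cond_means.items():
        for rep in range(1, config.n_replicates + 1):
            noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=n) \
                if config.noise_sd > 0 else np.ones(n)
            fpkm = mean * noise
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "condition": cond,
                        "replicate": rep,
                        "fpkm": fpkm,
                        "count": np.rint(fpkm * _COUNT_DEPTH).astype(int),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)

    state_choices = np.array(["active", "poised", "inactive"])
    state_probs = np.array([0.4, 0.3, 0.3])
    state_male = rng.choice(state_choices, size=n, p=state_probs)
    upgrade = {"inactive": "poised", "poised": "active", "active": "active"}
    state_female = state_male.copy()
    fb = classes == "female_biased"
    flip = fb & (rng.random(n) < 0.4)
    state_female[flip] = [upgrade[s] for s in state_male[flip]]

    zonated = rng.random(n) < config.zonated_fraction
    zbias = np.where(
        zonated,
        rng.uniform(0.3, 1.8, size=n) * rng.choice([-1.0, 1.0], size=n),
        0.0,
    )

    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "sex_class": classes,
                "cluster": clusters,
                "planted_fold": np.where(classes == "sex_independent", 1.0, fold),
                "sham_mean": sham,
                "female_mean": female,
                "state_male": state_male,
                "state_female": state_female,
                "zonated": zonated,
                "zonation_bias": zbias,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return table, truth


def simulate_gene_models(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    gene_ids: Optional[Sequence[str]] = None,
) -> List[GeneModel]:
    """Non-nested multi-isoform gene models on synthetic chromosomes.

    Genes are laid out on an even grid so that spans (6-30 kb) never
    overlap; each gene gets 2-8 exons and 1-3 isoforms derived by skipping
    internal exons. The last ``n_y_genes`` genes are placed on chrY.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_genes
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n)]
    n_auto = n - config.n_y_genes
    per_chrom = -(-n_auto // config.n_chromosomes)  # ceil
    spacing = config.genome_length // max(per_chrom, 1)
    if spacing < 40_000:
        raise ValueError(
            f"genome_length {config.genome_length} too small for "
            f"{per_chrom} genes per chromosome"
        )
    genes: List[GeneModel] = []
    for i, gene_id in enumerate(gene_ids):
        if i < n_auto:
            chrom = f"chr{i // per_chrom + 1}"
            slot = i % per_chrom
        else:
            chrom = "chrY"
            slot = i - n_auto
        offset = slot * spacing + 10_000
        span = int(rng.integers(6_000, 30_001))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        cuts = np.sort(rng.choice(np.arange(1, 2 * n_exons), 2 * n_exons - 2,
                                  replace=False))
        bounds = np.concatenate(([0], cuts, [2 * n_exons])) / (2 * n_exons)
        pos = offset + np.round(bounds * span).astype(int)
        exons: List[Tuple[int, int]] = []
        for j in range(n_exons):
            s, e = int(pos[2 * j]), int(pos[2 * j + 1])
            if exons and s < exons[-1][1]:
                s = exons[-1][1]
            e = max(e, s + 50)
            exons.append((s, e))
        isoforms = [Isoform(f"{gene_id}.1", exons)]
        n_iso = int(rng.integers(1, 4))
        internal = list(range(1, len(exons) - 1))
        for v in range(2, n_iso + 1):
            if not internal:
                break
            drop = set(
                rng.choice(internal, size=min(len(internal),
                                              int(rng.integers(1, 3))),
                           replace=False)
            )
            alt = [e for k, e in enumerate(exons) if k not in drop]
            if len(alt) >= 2:
                isoforms.append(Isoform(f"{gene_id}.{v}", alt))
        genes.append(GeneModel(gene_id, chrom, strand, isoforms))
    return genes


def simulate_peaks(
    config: SimulationConfig,
    domains: pd.DataFrame,
    foreground_genes: Set[str],
    rng: Optional[np.random.Generator] = None,
    peak_class: str = "peak",
) -> Tuple[pd.DataFrame, Set[str]]:
    """Peaks planted inside gene basal domains at a controlled odds ratio.

    Every gene is independently targeted: background genes at rate
    ``background_target_rate`` p0, foreground genes at the rate whose odds
    are ``target_enrichment`` times the background odds — so the expected
    gene-level 2x2 odds ratio equals the planted value. A targeted gene
    receives one 200-bp peak centred inside its basal domain (basal
    domains of distinct genes never overlap on the generator's gene grid,
    so planted targeting survives midpoint mapping exactly).
    ``config.n_peaks`` additional unanchored decoy peaks are appended
    beyond the last domain when space allows.
    """
    if domains.empty:
        raise ValueError("empty domain set")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    p0 = config.background_target_rate
    odds_fg = config.target_enrichment * p0 / (1 - p0)
    p1 = odds_fg / (1 + odds_fg)
    rows = []
    targeted: Set[str] = set()
    for gene_id, row in domains.iterrows():
        p = p1 if gene_id in foreground_genes else p0
        if rng.random() < p:
            targeted.add(gene_id)
            lo, hi = int(row["basal_start"]) + 100, int(row["basal_end"]) - 100
            c = int(rng.integers(max(lo, 0), hi))
            rows.append((f"{peak_class}_{gene_id}", row["chrom"], c - 100, c + 100))
    last_end = int(domains["ext_end"].max())
    for j in range(config.n_peaks):
        start = last_end + 10_000 + j * 1_000
        if start + 200 <= config.genome_length:
            rows.append((f"{peak_class}_decoy_{j}", domains["chrom"].iloc[0],
                         start, start + 200))
    peaks = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
    peaks["peak_class"] = peak_class
    return peaks, targeted


def simulate_chromatin_features(
    truth: GroundTruth,
    noise_sd: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """State-conditional feature densities at TSS and TES windows per sex.

    Densities are 2**(state mode + N(0, noise_sd)) per feature and window;
    the high/low log2 modes are >= 5 units apart, i.e. >= 4 noise SDs at
    the default noise, so the rule-based caller separates states cleanly.
    """
    rng = np.random.default_rng(seed + 3) if rng is None else rng
    rows = []
    for gene_id, g in truth.genes.iterrows():
        for sex, state in (("male", g["state_male"]), ("female", g["state_female"])):
            mu = STATE_FEATURE_MEANS[state]
            for window in ("TSS", "TES"):
                noise = rng.normal(0.0, noise_sd, size=len(FEATURES)) \
                    if noise_sd > 0 else np.zeros(len(FEATURES))
                row = {"gene_id": gene_id, "sex": sex, "window": window}
                for f, eps in zip(FEATURES, noise):
                    row[f] = 2.0 ** (mu[f] + eps)
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_zonation(
    truth: GroundTruth,
    noise_sd: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """9-zone profiles with the planted zone-1-vs-zone-9 contrast.

    The noiseless profile is linear in zone index, v_i = c*(1 + b*(5-i)/8),
    whose zonation bias is exactly the planted b; q-values fall below 0.2
    exactly for genes planted as zonated.
    """
    rng = np.random.default_rng(seed + 4) if rng is None else rng
    zones = np.arange(1, 10)
    rows = []
    for gene_id, g in truth.genes.iterrows():
        b = float(g["zonation_bias"])
        c = 2.0 ** rng.uniform(1.0, 5.0)
        v = c * (1.0 + b * (5.0 - zones) / 8.0)
        if noise_sd > 0:
            v = v * 2.0 ** rng.normal(0.0, noise_sd, size=9)
        q = rng.uniform(0.001, 0.15) if g["zonated"] else rng.uniform(0.3, 0.95)
        row = {"gene_id": gene_id, "q_value": q}
        row.update({f"zone_{i}": v[i - 1] for i in zones})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_all(config: SimulationConfig, outdir: Optional[Path] = None) -> Dict:
    """Run the full generator and optionally write a ready-to-run directory."""
    from .domains import build_domains  # deferred: avoids import cycle

    rng = np.random.default_rng(config.seed)
    table, truth = simulate_expression(config, rng)
    genes = simulate_gene_models(config, rng, gene_ids=list(truth.genes.index))
    chrom_of = {g.gene_id: g.chrom for g in genes}
    truth.genes["chrom"] = truth.genes.index.map(chrom_of)
    domains = build_domains(genes)
    stringent = truth.genes["planted_fold"] > 2
    fg_sets = {
        "male_enriched": set(truth.genes.index[(truth.genes["sex_class"] == "male_biased") & stringent]),
        "female_enriched": set(truth.genes.index[(truth.genes["sex_class"] == "female_biased") & stringent]),
    }
    peak_frames = []
    for cls, fg in fg_sets.items():
        pk, targeted = simulate_peaks(config, domains, fg, rng, peak_class=cls)
        truth.peak_targets[cls] = targeted
        peak_frames.append(pk)
    indep_cfg_or = config.target_enrichment
    config_indep = config
    # sex-independent peaks carry no planted enrichment
    import dataclasses as _dc

    config_indep = _dc.replace(config, target_enrichment=1.0)
    pk, targeted = simulate_peaks(
        config_indep, domains, set(), rng, peak_class="sex_independent"
    )
    truth.peak_targets["sex_independent"] = targeted
    peak_frames.append(pk)
    peaks = pd.concat(peak_frames, ignore_index=True)
    features = simulate_chromatin_features(truth, config.feature_noise_sd, rng)
    zonation = simulate_zonation(truth, config.zonation_noise_sd, rng)

    bundle = {
        "expression": table,
        "truth": truth,
        "gene_models": genes,
        "domains": domains,
        "peaks": peaks,
        "chromatin_features": features,
        "zonation": zonation,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        write_gtf(genes, outdir / "genes.gtf")
        for cls, sub in peaks.groupby("peak_class"):
            sub[["chrom", "start", "end", "peak_id"]].assign(
                score=0, strand="."
            ).to_csv(outdir / f"peaks_{cls}.bed", sep="\t", index=False, header=False)
        features.to_csv(outdir / "chromatin_features.tsv", sep="\t", index=False)
        zonation.to_csv(outdir / "zonation.tsv", sep="\t", index=False)
        truth.to_json(outdir / "ground_truth.json")
    return bundle
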