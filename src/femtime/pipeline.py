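"""End-to-end orchestration of the feminization time-course analysis.

``run_all`` drives the stages in study order — sex-bias classification,
feminization profiling, response clustering, regulatory-domain mapping,
target enrichment, chromatin states and zonation — on a directory of
inputs as produced by the synthetic generator, writing per-stage TSVs, a
combined JSON report and a reproducibility manifest. Every threshold
comes from :class:`PipelineConfig`, whose defaults are the study's
printed values.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import chromatin as _chromatin
from . import clustering as _clustering
from . import domains as _domains
from . import enrichment as _enrichment
from . import io as _io
from . import zonation as _zonation
from .genemodels import read_gtf

logger = logging.getLogger("femtime")


@dataclass
class PipelineConfig:
    indir: str = "."
    outdir: str = "femtime_out"
    seed: int = 0
    p_adj_biased: float = 0.01
    p_adj_responsive: float = 0.05
    p_adj_independent: float = 0.1
    fold_stringent: float = 2.0
    fold_independent: float = 1.2
    min_feminization: float = 20.0
    q_cutoff: float = 0.2
    min_correlation: float = 0.7
    n_profiles: int = 8
    max_step: int = 10
    k_clusters: int = 5
    basal_upstream: int = 5_000
    basal_downstream: int = 1_000
    max_extension: int = 1_000_000
    denom_eps: float = 0.25
    n_permutations: int = 200
    z_high: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_adj_biased", "p_adj_responsive", "p_adj_independent",
            "fold_stringent", "fold_independent", "min_feminization",
            "q_cutoff", "min_correlation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_adj_biased", "p_adj_responsive", "p_adj_independent",
                     "q_cutoff", "min_correlation"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_all(config: PipelineConfig) -> Dict:
    """Execute the pipeline on ``config.indir``; returns the report dict."""
    indir = Path(config.indir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config": dataclasses.asdict(config), "stages": {}}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    expr_path = indir / "expression.tsv"
    gtf_path = indir / "genes.gtf"
    for p in (expr_path, gtf_path):
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline input: {p}")

    # manifest before any output is declared final
    manifest = {
        "config": dataclasses.asdict(config),
        "inputs": {
            p.name: _io.file_checksum(p)
            for p in sorted(indir.iterdir())
            if p.is_file()
        },
        "seed": config.seed,
    }
    _io.write_json(manifest, outdir / "manifest.json")

    table = _io.read_expression_tsv(expr_path)
    genes = read_gtf(gtf_path)
    chrom_of = {g.gene_id: g.chrom for g in genes}
    lengths = {g.gene_id: g.length for g in genes}

    # --- classification and feminization -------------------------------
    s = stage("classify")
    calls = _classify.classify_sex_bias(
        table,
        chrom=chrom_of,
        p_biased=config.p_adj_biased,
        p_indep=config.p_adj_independent,
        fold_stringent=config.fold_stringent,
        fold_indep=config.fold_independent,
    )
    profiles_df = _classify.feminization_profiles(
        table,
        eps=config.denom_eps,
        p_responsive=config.p_adj_responsive,
        min_feminization=config.min_feminization,
    )
    _io.write_tsv(calls, outdir / "sex_bias_calls.tsv", index=True)
    _io.write_tsv(profiles_df, outdir / "feminization.tsv", index=True)
    s["n_genes"] = len(calls)
    s["n_stringent_sex_biased"] = int((calls["class"] == "stringent_sex_biased").sum())
    s["n_stringent_sex_independent"] = int(
        (calls["class"] == "stringent_sex_independent").sum()
    )
    s["n_responsive"] = int(profiles_df["responsive"].sum())

    # --- response clustering -------------------------------------------
    s = stage("response_clustering")
    timepoints = [t for t in _classify.TIMEPOINTS
                  if f"fem_{t}" in profiles_df.columns]
    fem_mat = profiles_df[[f"fem_{t}" for t in timepoints]]
    fem_mat.columns = timepoints
    model_profiles = _clustering.generate_model_profiles(
        len(timepoints) + 1,
        max_step=config.max_step,
        n_profiles=config.n_profiles,
        seed=config.seed,
    )
    clusters_by_sex = {}
    for sex, direction in (("male", "male"), ("female", "female")):
        sel = calls.index[
            (calls["class"] == "stringent_sex_biased")
            & (calls["direction"] == direction)
        ]
        sub = fem_mat.reindex(sel).dropna()
        stage_key = f"n_{sex}_clustered"
        if len(sub) < config.k_clusters:
            s[stage_key] = 0
            continue
        # model profiles include the baseline timepoint (value 0 at sham)
        vec = np.concatenate(
            [np.zeros((len(sub), 1)), sub.to_numpy(dtype=float) / 10.0], axis=1
        )
        vec_df = pd.DataFrame(vec, index=sub.index)
        assignments, _summary = _clustering.assign_genes(
            model_profiles, vec_df, n_permutations=config.n_permutations,
            seed=config.seed,
        )
        responsive = profiles_df.loc[sub.index, "responsive"]
        keep = _clustering.select_for_clustering(
            model_profiles, assignments, min_correlation=config.min_correlation
        )
        keep = keep[responsive.reindex(keep).fillna(False)]
        if len(keep) < config.k_clusters:
            s[stage_key] = 0
            continue
        labels = _clustering.cluster_feminization(
            sub.loc[keep], k=config.k_clusters
        )
        clusters_by_sex[sex] = labels
        s[stage_key] = int(len(labels))
    if clusters_by_sex:
        all_labels = pd.concat(
            [
                lab.rename("cluster").to_frame().assign(sex=sex)
                for sex, lab in clusters_by_sex.items()
            ]
        )
        _io.write_tsv(all_labels, outdir / "response_clusters.tsv", index=True)

    # --- regulatory domains and enrichment ------------------------------
    s = stage("regulatory_domains")
    domains = _domains.build_domains(
        genes,
        basal_upstream=config.basal_upstream,
        basal_downstream=config.basal_downstream,
        max_extension=config.max_extension,
    )
    _io.write_tsv(domains, outdir / "regulatory_domains.tsv", index=True)
    s["n_domains"] = len(domains)

    s = stage("enrichment")
    peak_files = sorted(indir.glob("peaks_*.bed"))
    targets_by_class = {}
    for pf in peak_files:
        cls = pf.stem.replace("peaks_", "")
        peaks = _io.read_peaks_bed(pf, peak_class=cls)
        tmap = _domains.map_peaks(peaks, domains)
        targets_by_class[cls] = _domains.target_genes(tmap)
    exclusive = _domains.dedupe_targets(targets_by_class)
    background = set(calls.index[calls["class"] == "stringent_sex_independent"])
    results = {}
    for cls, direction in (("male_enriched", "male"), ("female_enriched", "female")):
        fg = set(
            calls.index[
                (calls["class"] == "stringent_sex_biased")
                & (calls["direction"] == direction)
            ]
        )
        if not fg or not background or cls not in exclusive:
            continue
        results[f"{cls}_targets_vs_{direction}_biased"] = (
            _enrichment.target_set_enrichment(exclusive[cls], fg, background)
        )
    if results:
        _io.write_tsv(
            _enrichment.results_frame(results), outdir / "enrichment.tsv"
        )
    s["comparisons"] = list(results)

    # --- chromatin states -----------------------------------------------
    s = stage("chromatin_states")
    feat_path = indir / "chromatin_features.tsv"
    transitions = None
    if feat_path.exists():
        features = pd.read_csv(feat_path, sep="\t")
        eligible = _chromatin.eligible_genes(lengths, features)
        features = features[features["gene_id"].isin(eligible)]
        state_calls = _chromatin.call_states(features, z_high=config.z_high)
        transitions = _chromatin.state_transitions(state_calls)
        _io.write_tsv(state_calls, outdir / "chromatin_states.tsv")
        _io.write_tsv(transitions, outdir / "state_transitions.tsv", index=True)
        s["n_called"] = int(len(state_calls))
        s["n_more_active_in_female"] = int(
            transitions["more_active_in_female"].sum()
        )
        # early (clusters 1+2) vs later response against active state in males
        if "female" in clusters_by_sex:
            lab = clusters_by_sex["female"]
            active_male = set(
                state_calls[
                    (state_calls["sex"] == "male")
                    & (state_calls["state"] == "active")
                ]["gene_id"]
            )
            shared = lab.index.intersection(transitions.index)
            if len(shared) and lab.loc[shared].isin([1, 2]).any():
                res = _enrichment.cluster_enrichment(
                    active_male, lab.loc[shared].to_dict(), (1, 2)
                )
                s["early_active_es"] = res.es
                s["early_active_p"] = res.p

    # --- zonation --------------------------------------------------------
    s = stage("zonation")
    zon_path = indir / "zonation.tsv"
    if zon_path.exists():
        zon = pd.read_csv(zon_path, sep="\t")
        bias = _zonation.bias_table(zon, q_cutoff=config.q_cutoff)
        _io.write_tsv(bias, outdir / "zonation_bias.tsv")
        sig = bias[bias["significantly_zonated"]].set_index("gene_id")
        sex_biased = set(calls.index[calls["class"] == "stringent_sex_biased"])
        indep = set(calls.index[calls["class"] == "stringent_sex_independent"])
        a = sig.loc[sig.index.intersection(sex_biased), "zonation_bias"]
        b = sig.loc[sig.index.intersection(indep), "zonation_bias"]
        if len(a) >= 3 and len(b) >= 3:
            s["sex_biased_vs_independent"] = _zonation.compare_zonation(a, b)
        for sex, lab in clusters_by_sex.items():
            early = lab.index[lab.isin([1, 2])]
            late = lab.index[~lab.isin([1, 2])]
            ea = sig.loc[sig.index.intersection(early), "zonation_bias"]
            la = sig.loc[sig.index.intersection(late), "zonation_bias"]
            if len(ea) >= 3 and len(la) >= 3:
                s[f"{sex}_early_vs_late"] = _zonation.compare_zonation(ea, la)

    report["elapsed_s"] = round(time.time() - t0, 3)
    _io.write_json(report, outdir / "report.json")
    return report
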