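import numpy as np
import pandas as pd
import pytest

from femtime.classify import TIMEPOINTS, feminization_profiles
from femtime.domains import build_domains, map_peaks, target_genes
from femtime.enrichment import target_set_enrichment
from femtime.genemodels import read_gtf
from femtime.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_expression,
    simulate_gene_models,
    simulate_peaks,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(class_fractions={"male_biased": 0.7, "female_biased": 0.7}),
            dict(n_replicates=1),
            dict(noise_sd=-0.1),
            dict(n_genes=0),
            dict(target_enrichment=0.0),
            dict(background_target_rate=1.5),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestExpression:
    def test_deterministic_under_seed(self):
        t1, g1 = simulate_expression(SimulationConfig(n_genes=50, seed=9))
        t2, g2 = simulate_expression(SimulationConfig(n_genes=50, seed=9))
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1.genes, g2.genes)

    def test_sex_independent_genes_have_equal_means(self):
        table, truth = simulate_expression(
            SimulationConfig(n_genes=40, seed=4, noise_sd=0.0)
        )
        means = table.pivot_table(index="gene_id", columns="condition",
                                  values="fpkm")
        indep = truth.genes.index[truth.genes["sex_class"] == "sex_independent"]
        assert np.allclose(means.loc[indep, "female"],
                           means.loc[indep, "sham_male"])

    def test_late_cluster_flat_at_10h(self):
        cfg = SimulationConfig(n_genes=120, seed=6, noise_sd=0.0)
        table, truth = simulate_expression(cfg)
        means = table.pivot_table(index="gene_id", columns="condition",
                                  values="fpkm")
        flat10h = truth.genes.index[truth.genes["cluster"].isin(["M4", "M5"])]
        assert len(flat10h) > 0
        assert np.allclose(means.loc[flat10h, "cgh_10h"],
                           means.loc[flat10h, "sham_male"])

    def test_full_feminization_at_planted_saturation(self):
        cfg = SimulationConfig(n_genes=120, seed=8, noise_sd=0.0)
        table, truth = simulate_expression(cfg)
        prof = feminization_profiles(table)
        f1 = truth.genes.index[truth.genes["cluster"] == "F1"]
        assert len(f1) > 0
        # cluster F1 saturates from day 1 onward
        assert (prof.loc[f1, "fem_cgh_1d"] >= 100).all()


class TestGeneModels:
    def test_models_valid_and_non_nested(self):
        cfg = SimulationConfig(n_genes=60, seed=2)
        genes = simulate_gene_models(cfg)
        spans = sorted((g.chrom, g.start, g.end) for g in genes)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            if c1 == c2:
                assert s2 >= e1  # genes never overlap
        for g in genes:
            assert 1 <= len(g.isoforms) <= 3
            assert len(g.isoforms[0].exons) >= 2
            for iso in g.isoforms:
                assert iso.exons == sorted(iso.exons)

    def test_round_trip_through_gtf(self, tmp_path):
        from femtime.genemodels import write_gtf

        genes = simulate_gene_models(SimulationConfig(n_genes=10, seed=5))
        write_gtf(genes, tmp_path / "g.gtf")
        back = {g.gene_id: g for g in read_gtf(tmp_path / "g.gtf")}
        for g in genes:
            assert {i.isoform_id: i.exons for i in back[g.gene_id].isoforms} == {
                i.isoform_id: i.exons for i in g.isoforms
            }

    def test_genome_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_gene_models(
                SimulationConfig(n_genes=1000, genome_length=1_000_000)
            )


class TestPeaks:
    def _setup(self, n_genes=200, seed=0):
        cfg = SimulationConfig(n_genes=n_genes, seed=seed)
        genes = simulate_gene_models(cfg)
        domains = build_domains(genes)
        fg = set(domains.index[: n_genes // 3])
        return cfg, domains, fg

    def test_empty_domains_rejected(self):
        cfg = SimulationConfig(n_genes=10, seed=0)
        with pytest.raises(ValueError, match="empty domain"):
            simulate_peaks(cfg, pd.DataFrame(), set())

    def test_planted_targets_survive_midpoint_mapping_exactly(self):
        cfg, domains, fg = self._setup()
        peaks, planted = simulate_peaks(cfg, domains, fg,
                                        np.random.default_rng(1))
        recovered = target_genes(map_peaks(peaks, domains))
        assert recovered == planted

    def test_null_enrichment_centred_on_1(self):
        import dataclasses

        cfg, domains, fg = self._setup()
        cfg = dataclasses.replace(cfg, target_enrichment=1.0)
        bg = set(domains.index) - fg
        rng = np.random.default_rng(7)
        log_es = []
        for _ in range(60):
            peaks, _ = simulate_peaks(cfg, domains, fg, rng)
            res = target_set_enrichment(
                target_genes(map_peaks(peaks, domains)), fg, bg
            )
            log_es.append(np.log(res.es))
        se = np.std(log_es, ddof=1) / np.sqrt(len(log_es))
        assert abs(np.mean(log_es)) < max(2 * se, 0.1)


class TestBundle:
    def test_simulate_all_writes_complete_directory(self, tmp_path, small_study):
        cfg = SimulationConfig(n_genes=30, seed=17)
        simulate_all(cfg, tmp_path)
        for name in (
            "expression.tsv",
            "genes.gtf",
            "chromatin_features.tsv",
            "zonation.tsv",
            "ground_truth.json",
        ):
            assert (tmp_path / name).exists(), name
        assert any(tmp_path.glob("peaks_*.bed"))

    def test_bundle_is_deterministic(self, tmp_path):
        cfg = SimulationConfig(n_genes=25, seed=31)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_all(cfg, d1)
        simulate_all(SimulationConfig(n_genes=25, seed=31), d2)
        for f in d1.iterdir():
            assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name
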