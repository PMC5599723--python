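import numpy as np
import pandas as pd
import pytest

from femtime.genemodels import GeneModel, Isoform
from femtime.intervals import GenomicInterval
from femtime.regions import (
    build_region_sets,
    compare_intronic_exonic,
    count_reads,
)


def brute_force_regions(gene, hi=20_000):
    """Per-base membership oracle for the three region classes."""
    exonic = np.zeros(hi, dtype=bool)
    intronic = np.zeros(hi, dtype=bool)
    for iso in gene.isoforms:
        for s, e in iso.exons:
            exonic[s:e] = True
        for s, e in iso.introns:
            intronic[s:e] = True
    return {
        "collapsed_exon": exonic,
        "exonic_only": exonic & ~intronic,
        "intronic_only": intronic & ~exonic,
    }


def spans_to_mask(spans, hi=20_000):
    mask = np.zeros(hi, dtype=bool)
    for s, e in spans:
        mask[s:e] = True
    return mask


def random_gene(rng, gene_id="g", max_len=10_000):
    n_iso = rng.integers(1, 4)
    isoforms = []
    for v in range(n_iso):
        n_ex = rng.integers(1, 6)
        cuts = np.sort(rng.choice(np.arange(1, max_len), 2 * n_ex, replace=False))
        exons = [(int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(n_ex)]
        isoforms.append(Isoform(f"{gene_id}.{v}", exons))
    return GeneModel(gene_id, "chr1", "+", isoforms)


class TestBuildRegionSets:
    def test_single_isoform(self, two_exon_gene):
        rs = build_region_sets(two_exon_gene)
        assert rs["collapsed_exon"] == [(100, 200), (300, 400)]
        assert rs["intronic_only"] == [(200, 300)]
        assert rs["exonic_only"] == rs["collapsed_exon"]

    def test_retained_intron_excluded_from_exonic_only(self):
        gene = GeneModel(
            "g",
            "chr1",
            "+",
            [
                Isoform("a", [(0, 100), (200, 300)]),
                Isoform("b", [(0, 300)]),
            ],
        )
        rs = build_region_sets(gene)
        assert rs["collapsed_exon"] == [(0, 300)]
        assert rs["intronic_only"] == []
        assert rs["exonic_only"] == [(0, 100), (200, 300)]

    def test_single_exon_gene_has_no_introns(self):
        gene = GeneModel("g", "chr1", "+", [Isoform("a", [(10, 500)])])
        rs = build_region_sets(gene)
        assert rs["intronic_only"] == []
        counts = count_reads([gene], [GenomicInterval("chr1", 20, 40)])
        by = counts.set_index("region_class")["count"]
        assert by["intronic_only"] == 0 and by["collapsed_exon"] == 1

    def test_matches_per_base_oracle_on_random_genes(self):
        rng = np.random.default_rng(42)
        for i in range(100):
            gene = random_gene(rng, f"g{i}")
            rs = build_region_sets(gene)
            oracle = brute_force_regions(gene)
            for cls in rs:
                assert np.array_equal(spans_to_mask(rs[cls]), oracle[cls]), (
                    f"{gene.gene_id} {cls}"
                )
            # partition/disjointness invariants
            assert not (
                spans_to_mask(rs["exonic_only"]) & spans_to_mask(rs["intronic_only"])
            ).any()
            span = spans_to_mask([(gene.start, gene.end)])
            assert not (spans_to_mask(rs["intronic_only"]) & ~span).any()
            assert (
                spans_to_mask(rs["collapsed_exon"]) | ~spans_to_mask(rs["exonic_only"])
            ).all()


class TestCountReads:
    def test_overlap_rules(self, two_exon_gene):
        reads = [
            GenomicInterval("chr1", 150, 160),  # exonic
            GenomicInterval("chr1", 195, 205),  # spans the exon/intron junction
            GenomicInterval("chr1", 500, 600),  # outside the gene
        ]
        counts = count_reads([two_exon_gene], reads).set_index("region_class")["count"]
        assert counts["collapsed_exon"] == 2
        assert counts["exonic_only"] == 2
        assert counts["intronic_only"] == 1  # the junction read counts here too

    def test_empty_read_set(self, two_exon_gene):
        counts = count_reads([two_exon_gene], [])
        assert (counts["count"] == 0).all()

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(3)
        genes = [random_gene(rng, f"g{i}") for i in range(10)]
        reads = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 11_000, 300), rng.integers(1, 400, 300)
            )
        ]
        got = count_reads(genes, reads).set_index(["gene_id", "region_class"])["count"]
        for gene in genes:
            for cls, spans in build_region_sets(gene).items():
                expect = sum(
                    any(r.start < e and s < r.end for s, e in spans) for r in reads
                )
                assert got[(gene.gene_id, cls)] == expect


class TestIntronicExonicComparison:
    @staticmethod
    def _counts(values):
        rows = []
        for gene, (ex, intr) in values.items():
            rows.append((gene, "exonic_only", ex))
            rows.append((gene, "intronic_only", intr))
            rows.append((gene, "collapsed_exon", ex + intr))
        return pd.DataFrame(rows, columns=["gene_id", "region_class", "count"])

    def test_identical_fold_changes_give_r_1(self):
        ref = self._counts({f"g{i}": (40 * (i + 1), 40 * (i + 1)) for i in range(6)})
        treat = self._counts(
            {f"g{i}": (80 * (i + 1), 80 * (i + 1)) for i in range(6)}
        )
        cmp_, r = compare_intronic_exonic(ref, treat)
        assert r == pytest.approx(1.0)
        assert not cmp_["discordant"].any()

    def test_discordant_gene_flagged(self):
        ref = self._counts({"a": (100, 100), "b": (100, 100), "c": (100, 100)})
        treat = self._counts({"a": (400, 100), "b": (200, 200), "c": (300, 300)})
        cmp_, _ = compare_intronic_exonic(ref, treat)
        assert bool(cmp_.loc["a", "discordant"])  # intronic lags 4-fold
        assert not cmp_.loc["b", "discordant"]

    def test_filter_removes_low_intronic_genes(self):
        ref = self._counts({"lo": (100, 5), "a": (9, 50), "b": (9, 50), "c": (9, 50)})
        treat = self._counts({"lo": (100, 5), "a": (9, 50), "b": (9, 50), "c": (9, 50)})
        cmp_, _ = compare_intronic_exonic(ref, treat)
        assert "lo" not in cmp_.index

    def test_too_few_genes_raises(self):
        ref = self._counts({"a": (10, 50), "b": (10, 2)})
        with pytest.raises(ValueError, match="correlation undefined"):
            compare_intronic_exonic(ref, ref)
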