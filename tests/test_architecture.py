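"""Intergenic gaps, gene metrics, and the nonparametric test battery."""

import numpy as np
import pytest
from scipy import stats

from genarch.architecture import (intergenic_spaces, gene_metrics,
                                  kruskal_wallis, pairwise_wilcoxon,
                                  rank_sum_p, compare_architecture)
from genarch.intervals import IntervalSet
from genarch.simulate import (ArchitectureParams, SpeciesParams,
                              generate_genomes)
from conftest import build_annotation


def gene(gid, seqid, exons, tx_extra=()):
    return {"id": gid, "seqid": seqid,
            "transcripts": [{"id": f"{gid}.t1", "exons": exons}, *tx_extra]}


class TestIntergenicSpaces:
    def test_simple_gap(self):
        ann = build_annotation({"s": 100}, [
            gene("g1", "s", [(10, 40)]), gene("g2", "s", [(60, 80)])])
        assert intergenic_spaces(ann) == [20]

    def test_overlapping_genes_union_first(self):
        ann = build_annotation({"s": 120}, [
            gene("g1", "s", [(10, 40)]), gene("g2", "s", [(30, 70)]),
            gene("g3", "s", [(90, 95)])])
        assert intergenic_spaces(ann) == [20]

    def test_scaffold_end_flanks_excluded(self):
        ann = build_annotation({"s": 1000}, [gene("g1", "s", [(100, 200)])])
        assert intergenic_spaces(ann) == []

    def test_class_filter(self):
        ann = build_annotation(
            {"a": 100, "x": 100},
            [gene("g1", "a", [(0, 10)]), gene("g2", "a", [(20, 30)]),
             gene("g3", "x", [(0, 10)]), gene("g4", "x", [(50, 60)])],
            chrom_class={"a": "autosome", "x": "X"})
        assert intergenic_spaces(ann, "autosome") == [10]
        assert intergenic_spaces(ann, "X") == [40]

    def test_gap_partition_per_scaffold(self):
        """gaps + gene-span union + end flanks tile the scaffold exactly."""
        res = generate_genomes(ArchitectureParams(n_genes=60, n_scaffolds=2,
                                                  seed=9), emit_sequence=False)
        ann = res.species["outcrosser"].annotation
        spans = IntervalSet(ann.gene_spans())
        for seqid, length in ann.seq_lengths.items():
            merged = list(spans.intervals(seqid))
            gaps = [b.start - a.end for a, b in zip(merged, merged[1:])]
            flanks = merged[0].start + (length - merged[-1].end)
            genic = sum(iv.length for iv in merged)
            assert sum(gaps) + genic + flanks == length

    def test_lognormal_median_recovery(self):
        """Generated gaps recover the planted log-normal median within 5%."""
        params = ArchitectureParams(
            n_genes=5000, n_scaffolds=2, fraction_x=0.5,
            intergenic_median_autosome=800.0, intergenic_median_x=800.0,
            species=(SpeciesParams("only"),), seed=77)
        res = generate_genomes(params, emit_sequence=False)
        gaps = intergenic_spaces(res.species["only"].annotation)
        assert len(gaps) > 4000
        assert abs(np.median(gaps) - 800.0) / 800.0 < 0.05


class TestGeneMetrics:
    def test_three_exon_gene(self):
        ann = build_annotation({"s": 1000}, [{
            "id": "g1", "seqid": "s", "transcripts": [{
                "id": "g1.t1",
                "exons": [(0, 100), (150, 300), (360, 560)]}]}])
        (m,) = gene_metrics(ann)
        assert m.exon_sum_bp == 450
        assert m.intron_sum_bp == 110
        assert m.span_bp == 560

    def test_protein_size_from_cds(self):
        ann = build_annotation({"s": 1000}, [{
            "id": "g1", "seqid": "s", "transcripts": [{
                "id": "g1.t1", "exons": [(0, 303)], "cds": [(0, 303)]}]}])
        (m,) = gene_metrics(ann)
        assert m.protein_aa == 100  # 303/3 - 1 (stop codon)

    def test_gene_without_cds_keeps_size_metrics(self):
        ann = build_annotation({"s": 1000}, [gene("g1", "s", [(0, 100)])])
        (m,) = gene_metrics(ann)
        assert m.protein_aa is None
        assert m.span_bp == 100

    def test_ortholog_filter_restricts(self):
        ann = build_annotation({"s": 1000}, [
            gene("g1", "s", [(0, 100)]), gene("g2", "s", [(200, 300)])])
        out = gene_metrics(ann, ortholog_filter={"g2"})
        assert [m.gene_id for m in out] == ["g2"]

    def test_means_match_generator_truth(self):
        params = ArchitectureParams(n_genes=3000, n_scaffolds=2,
                                    species=(SpeciesParams("only"),), seed=5)
        res = generate_genomes(params, emit_sequence=False)
        metrics = gene_metrics(res.species["only"].annotation)
        exon_means = np.mean([m.exon_sum_bp for m in metrics])
        # ~6 exons of mean ~200 bp
        per_exon = np.exp(params.exon_length_meanlog
                          + params.exon_length_sdlog**2 / 2)
        expected = params.exon_count_mean * per_exon
        assert abs(exon_means - expected) / expected < 0.05


class TestKruskalWallis:
    def test_hand_derived_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0
        assert res.degenerate

    def test_matches_scipy_reference(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 40)))
            b = rng.normal(0.3, 1.5, int(rng.integers(5, 40)))
            c = rng.normal(-0.2, 0.7, int(rng.integers(5, 40)))
            mine = kruskal_wallis([a, b, c])
            ref = stats.kruskal(a, b, c)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tie_correction_matches_scipy(self, rng):
        a = rng.integers(0, 5, 30)  # heavy ties
        b = rng.integers(1, 6, 25)
        mine = kruskal_wallis([a, b])
        ref = stats.kruskal(a, b)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_two_group_h_equals_squared_normal_ranksum(self, rng):
        """For two groups, H = z² of the tie-corrected rank-sum statistic."""
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 30)
        h = kruskal_wallis([a, b]).statistic
        n1, n2 = len(a), len(b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        r1 = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2
        sigma2 = n1 * n2 * (n1 + n2 + 1) / 12
        z = (r1 - mu) / np.sqrt(sigma2)
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1], []])


class TestPairwiseWilcoxon:
    def test_three_groups_give_three_pairs_bonferroni_m3(self, rng):
        groups = [rng.normal(i, 1, 20) for i in range(3)]
        results = pairwise_wilcoxon(groups)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_identical_groups_adjusted_to_one(self):
        groups = [[1.0, 2.0, 3.0, 4.0]] * 3
        for r in pairwise_wilcoxon(groups):
            assert r.p_adjusted == 1.0

    def test_empty_group_skipped(self, rng):
        groups = [list(rng.normal(0, 1, 10)), [], list(rng.normal(0, 1, 10))]
        results = pairwise_wilcoxon(groups)
        assert len(results) == 1  # only the non-empty pair

    def test_matches_scipy_reference(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1, 35)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert rank_sum_p(x, y) == pytest.approx(ref.pvalue, abs=1e-12)

    def test_small_samples_use_exact_distribution(self):
        x, y = [1.0, 2.0, 5.0], [3.0, 8.0, 9.0, 10.0]
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert rank_sum_p(x, y) == pytest.approx(ref.pvalue, abs=1e-12)

    def test_adjusted_monotone_in_raw(self, rng):
        groups = [rng.normal(i * 0.3, 1, 15) for i in range(4)]
        results = pairwise_wilcoxon(groups)
        order_raw = np.argsort([r.p_raw for r in results])
        order_adj = np.argsort([r.p_adjusted for r in results])
        assert list(order_raw) == list(order_adj)


class TestCompareArchitecture:
    @staticmethod
    def _two_species(seed, x_scale=1.0):
        params = ArchitectureParams(
            n_genes=400, n_scaffolds=2, fraction_x=0.5,
            species=(SpeciesParams("out"),
                     SpeciesParams("self", gene_loss=0.2,
                                   intron_scale_x=x_scale)),
            seed=seed)
        res = generate_genomes(params, emit_sequence=False)
        return {name: b.annotation for name, b in res.species.items()}

    def test_planted_x_intron_scaling_detected(self):
        anns = self._two_species(31, x_scale=1.8)
        _, tests = compare_architecture(anns)
        gene_span_x_tests = [
            t for t in tests
            if t.method == "kruskal-wallis[gene_span]"
            and t.groups == ("self:autosome", "self:X")]
        assert gene_span_x_tests and gene_span_x_tests[0].p_raw < 0.01

    def test_summary_table_shape(self):
        anns = self._two_species(32)
        summary, _ = compare_architecture(anns)
        # 2 species x 3 metrics x 2 classes
        assert len(summary) == 12
        assert set(summary["metric"]) == {"intergenic_space", "gene_span",
                                          "protein_size"}

    def test_degenerate_one_gene_per_scaffold(self):
        ann = build_annotation(
            {"a": 1000, "x": 1000},
            [gene("g1", "a", [(100, 200)]), gene("g2", "x", [(100, 200)])],
            chrom_class={"a": "autosome", "x": "X"})
        summary, tests = compare_architecture({"sp": ann})
        row = summary[(summary["metric"] == "intergenic_space")
                      & (summary["chrom_class"] == "X")].iloc[0]
        assert row["n"] == 0
        assert not any("intergenic" in t.method for t in tests)
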