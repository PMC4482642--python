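"""Synteny chaining against a brute-force oracle, translocation filtering,
chromosome retention, divergent-region scan and indel size bias."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genarch.synteny import (GenePos, OrthologPair, chain_blocks,
                             filter_single_translocations,
                             chromosome_retention, divergent_regions,
                             indel_size_bias, pairs_from_table)
from genarch.simulate import (ArchitectureParams, SpeciesParams,
                              generate_genomes)
from conftest import build_annotation


def pair(a_start, b_start, a_chr="A1", b_chr="B1", length=1000, gid=None):
    gid = gid or f"g{a_start}"
    return OrthologPair(
        a=GenePos(f"a_{gid}", a_chr, a_start, a_start + length),
        b=GenePos(f"b_{gid}", b_chr, b_start, b_start + length))


def chaining_oracle(pairs, join_distance, both_genomes=True):
    """O(n²) transitive closure of the adjacency relation between
    neighbours in species-A order (independent of chain_blocks' loop)."""
    ordered = sorted(pairs, key=lambda p: (p.a.seqid, p.a.start, p.a.gene_id))
    n = len(ordered)
    adj = np.zeros((n, n), dtype=bool)

    def gap(u, v):
        return max(0, max(u.start, v.start) - min(u.end, v.end))

    for i in range(n - 1):
        u, v = ordered[i], ordered[i + 1]
        ok = (u.a.seqid == v.a.seqid and u.b.seqid == v.b.seqid
              and gap(u.a, v.a) <= join_distance
              and (not both_genomes or gap(u.b, v.b) <= join_distance))
        adj[i, i + 1] = adj[i + 1, i] = ok
    # BFS components
    seen = np.zeros(n, dtype=bool)
    components = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in np.nonzero(adj[j])[0]:
                if not seen[k]:
                    seen[k] = True
                    stack.append(int(k))
        components.append(frozenset(ordered[j].a.gene_id for j in comp))
    return set(components)


class TestChainBlocks:
    def test_hand_trace_split_on_large_gap(self):
        pairs = [pair(1_000, 2_000, gid="g1"),
                 pair(30_000, 35_000, gid="g2"),
                 pair(100_000, 38_000, gid="g3")]
        blocks = chain_blocks(pairs, join_distance=50_000)
        sizes = sorted(b.size for b in blocks)
        assert sizes == [1, 2]  # 70 kb species-A gap splits g3 off

    def test_single_pair_single_block(self):
        blocks = chain_blocks([pair(0, 0)])
        assert len(blocks) == 1 and blocks[0].size == 1

    def test_input_order_irrelevant(self, rng):
        pairs = [pair(int(s), int(t), gid=str(i)) for i, (s, t) in
                 enumerate(zip(rng.integers(0, 10**6, 50),
                               rng.integers(0, 10**6, 50)))]
        fwd = chain_blocks(pairs)
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        rev = chain_blocks(shuffled)
        key = lambda blocks: sorted(
            tuple(sorted(m.a.gene_id for m in b.members)) for b in blocks)
        assert key(fwd) == key(rev)

    def test_partition_property(self, rng):
        pairs = [pair(int(s), int(t), gid=str(i)) for i, (s, t) in
                 enumerate(zip(rng.integers(0, 500_000, 80),
                               rng.integers(0, 500_000, 80)))]
        blocks = chain_blocks(pairs)
        members = [m.a.gene_id for b in blocks for m in b.members]
        assert sorted(members) == sorted(p.a.gene_id for p in pairs)

    @pytest.mark.parametrize("n,join", [(50, 50_000), (200, 20_000)])
    def test_matches_transitive_chaining_oracle(self, rng, n, join):
        chroms_a = ["A1", "A2"]
        chroms_b = ["B1", "B2"]
        pairs = []
        for i in range(n):
            pairs.append(pair(int(rng.integers(0, 2_000_000)),
                              int(rng.integers(0, 2_000_000)),
                              a_chr=str(rng.choice(chroms_a)),
                              b_chr=str(rng.choice(chroms_b)),
                              length=int(rng.integers(200, 5000)),
                              gid=str(i)))
        got = {frozenset(m.a.gene_id for m in b.members)
               for b in chain_blocks(pairs, join_distance=join)}
        assert got == chaining_oracle(pairs, join)

    def test_more_join_distance_never_more_blocks(self, rng):
        pairs = [pair(int(s), int(t), gid=str(i)) for i, (s, t) in
                 enumerate(zip(rng.integers(0, 10**6, 100),
                               rng.integers(0, 10**6, 100)))]
        n_blocks = [len(chain_blocks(pairs, join_distance=d))
                    for d in (1_000, 10_000, 50_000, 200_000)]
        assert n_blocks == sorted(n_blocks, reverse=True)


class TestTranslocationFilter:
    HOMOLOGY = {"A1": "B1", "A2": "B2"}

    def test_same_chromosome_singleton_kept(self):
        blocks = chain_blocks([pair(0, 0, "A1", "B1")])
        kept, removed = filter_single_translocations(blocks, self.HOMOLOGY)
        assert removed == 0 and len(kept) == 1

    def test_cross_chromosome_singleton_removed(self):
        blocks = chain_blocks([pair(0, 0, "A1", "B2")])
        kept, removed = filter_single_translocations(blocks, self.HOMOLOGY)
        assert removed == 1 and kept == []

    def test_multi_gene_cross_chromosome_block_kept_flagged(self):
        blocks = chain_blocks([pair(0, 0, "A1", "B2", gid="g1"),
                               pair(2_000, 2_000, "A1", "B2", gid="g2")])
        kept, removed = filter_single_translocations(blocks, self.HOMOLOGY)
        assert removed == 0
        assert len(kept) == 1 and not kept[0].same_chromosome

    def test_exactly_planted_translocations_removed(self):
        params = ArchitectureParams(
            n_genes=300, n_scaffolds=4,
            intergenic_median_autosome=200_000.0,  # isolate genes
            intergenic_median_x=200_000.0,
            species=(SpeciesParams("a"),
                     SpeciesParams("b", translocation_rate=0.1)),
            seed=13)
        res = generate_genomes(params, emit_sequence=False)
        pairs = pairs_from_table(res.ortholog_table, "a", "b")
        blocks = chain_blocks(pairs, join_distance=50_000)
        kept, removed = filter_single_translocations(blocks)
        planted = {g.split("_", 1)[1]
                   for g in res.truth.translocated_genes["b"]}
        # expected removals: planted genes that chained as singletons
        # (two movers landing adjacently on the same target stay as a block)
        expected = {b.members[0].a.gene_id.split("_", 1)[1]
                    for b in blocks
                    if b.size == 1
                    and b.members[0].a.gene_id.split("_", 1)[1] in planted}
        removed_ids = {m.a.gene_id.split("_", 1)[1]
                       for b in blocks for m in b.members} - {
            m.a.gene_id.split("_", 1)[1] for b in kept for m in b.members}
        assert removed == len(expected)
        assert removed_ids == expected
        assert len(expected) >= 0.8 * len(planted) > 0


class TestChromosomeRetention:
    def test_all_homologous_is_one(self):
        pairs = [pair(i * 10_000, i * 10_000) for i in range(10)]
        frac, breakdown = chromosome_retention(pairs, {"A1": "B1"})
        assert frac == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="pairs"):
            chromosome_retention([])

    def test_unmapped_chromosome_excluded_from_denominator(self):
        pairs = [pair(0, 0, "A1", "B1"), pair(10_000, 0, "A9", "B1")]
        frac, _ = chromosome_retention(pairs, {"A1": "B1"})
        assert frac == 1.0

    def test_translocation_rate_recovered(self):
        params = ArchitectureParams(
            n_genes=2000, n_scaffolds=5,
            species=(SpeciesParams("a"),
                     SpeciesParams("b", translocation_rate=0.05)),
            seed=21)
        res = generate_genomes(params, emit_sequence=False)
        pairs = pairs_from_table(res.ortholog_table, "a", "b")
        frac, _ = chromosome_retention(pairs)
        se = np.sqrt(0.05 * 0.95 / len(pairs))
        assert abs(frac - 0.95) <= 3 * se


class TestDivergentRegions:
    def test_uniform_orthology_no_regions(self):
        params = ArchitectureParams(n_genes=200, n_scaffolds=2, seed=3)
        res = generate_genomes(params, emit_sequence=False)
        ann = res.species["outcrosser"].annotation
        orth = set(res.ortholog_table.loc[
            res.ortholog_table["species"] == "outcrosser", "gene_id"])
        assert divergent_regions(ann, orth, window_bp=50_000,
                                 min_length_bp=100_000,
                                 max_density=0.05) == []

    def test_planted_desert_recovered(self):
        params = ArchitectureParams(
            n_genes=1200, n_scaffolds=2, desert_scaffold=1,
            desert_bp=500_000, seed=8)
        res = generate_genomes(params, emit_sequence=False)
        first = params.species[0].name
        ann = res.species[first].annotation
        orth = set(res.ortholog_table.loc[
            res.ortholog_table["species"] == first, "gene_id"])
        regions = divergent_regions(ann, orth, window_bp=50_000,
                                    min_length_bp=300_000, max_density=0.05)
        plant = res.truth.desert_regions[first]
        hits = [r for r in regions if r.interval.seqid == plant.seqid]
        assert len(hits) == 1
        overlap = (min(hits[0].interval.end, plant.end)
                   - max(hits[0].interval.start, plant.start))
        assert overlap >= 0.9 * plant.length
        assert hits[0].n_orthologous < 0.05 * max(hits[0].n_genes, 1)

    def test_whole_scaffold_ortholog_free(self):
        ann = build_annotation({"s": 400_000}, [
            {"id": f"g{i}", "seqid": "s", "transcripts": [
                {"id": f"g{i}.t1", "exons": [(i * 40_000, i * 40_000 + 500)]}]}
            for i in range(10)])
        (region,) = divergent_regions(ann, orthologous_genes=set(),
                                      window_bp=50_000,
                                      min_length_bp=300_000, max_density=0.1)
        assert (region.interval.start, region.interval.end) == (0, 400_000)
        assert region.n_genes == 10 and region.n_orthologous == 0


class TestIndelSizeBias:
    @staticmethod
    def _blocks(spans_ab):
        blocks = []
        for i, (sa, sb) in enumerate(spans_ab):
            members = [
                OrthologPair(a=GenePos(f"a{i}_1", "A1", 0, 100),
                             b=GenePos(f"b{i}_1", "B1", 0, 100)),
                OrthologPair(a=GenePos(f"a{i}_2", "A1", sa - 100, sa),
                             b=GenePos(f"b{i}_2", "B1", sb - 100, sb)),
            ]
            blocks.append(chain_blocks(members, join_distance=10**9)[0])
        return blocks

    def test_equal_spans_p_one(self):
        blocks = self._blocks([(1000 + i, 1000 + i) for i in range(8)])
        result, table = indel_size_bias(blocks)
        assert result.p_raw == 1.0
        assert (table["log_ratio"] == 0).all()

    def test_doubled_spans_detected(self):
        blocks = self._blocks([(1000 * (i + 1), 2000 * (i + 1))
                               for i in range(8)])
        result, table = indel_size_bias(blocks)
        assert table.attrs["median_ratio"] == pytest.approx(0.5)
        assert result.p_raw < 0.05

    def test_symmetric_noise_type_one_error_controlled(self, rng):
        """Null calibration: with symmetric span noise the signed-rank test
        rejects at most at the nominal rate (binomial slack; the exact
        small-sample p is discrete, hence conservative)."""
        n_reps, alpha = 300, 0.05
        pvals = []
        for _ in range(n_reps):
            spans = [(1000, int(1000 * np.exp(rng.normal(0, 0.3))))
                     for _ in range(12)]
            result, _ = indel_size_bias(self._blocks(
                [(a + i, b + i) for i, (a, b) in enumerate(spans)]))
            pvals.append(result.p_raw)
        reject = np.mean(np.asarray(pvals) < alpha)
        assert reject <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_reps)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            indel_size_bias(self._blocks([(1000, 1100)] * 3))


class TestPairsFromTable:
    def test_many_to_many_reduced_to_longest(self):
        table = pd.DataFrame([
            {"gene_id": "a1", "species": "a", "seqid": "A1",
             "start": 0, "end": 500, "group": "og1"},
            {"gene_id": "a2", "species": "a", "seqid": "A1",
             "start": 600, "end": 2000, "group": "og1"},  # longer, wins
            {"gene_id": "b1", "species": "b", "seqid": "B1",
             "start": 0, "end": 400, "group": "og1"},
        ])
        (p,) = pairs_from_table(table, "a", "b")
        assert p.a.gene_id == "a2" and p.b.gene_id == "b1"
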