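import numpy as np
import pytest

from gapseq import link_scaffolder as ls
from gapseq.io_formats import QualRead, SeqRecord, layout_sequences, revcomp
from gapseq.simdata import fragment_genome, simulate_genome, simulate_long_reads

from helpers import joins_from_layouts

SCALED = ls.LinkParams(k=21, min_links=5, pair_distance=2_000,
                       distance_error=0.02, max_link_ratio=0.1, step=2)


def _read(seq, rid="r"):
    return QualRead(rid, seq, (30,) * len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestExtractPairs:
    PARAMS = ls.LinkParams(k=51, pair_distance=20_000, step=1)

    def test_exact_boundary_one_pair(self, rng):
        read = _read(_random_seq(rng, 20_051))
        assert len(ls.extract_pairs(read, self.PARAMS)) == 1

    def test_one_short_no_pairs(self, rng):
        read = _read(_random_seq(rng, 20_050))
        assert ls.extract_pairs(read, self.PARAMS) == []

    def test_step_floor_arithmetic(self, rng):
        params = ls.LinkParams(k=51, pair_distance=20_000, step=2)
        read = _read(_random_seq(rng, 20_061))
        pairs = ls.extract_pairs(read, params)
        assert [p.offset for p in pairs] == [0, 2, 4, 6, 8, 10]

    def test_kmers_containing_n_are_skipped(self, rng):
        seq = list(_random_seq(rng, 20_051))
        seq[10] = "N"
        assert ls.extract_pairs(_read("".join(seq)), self.PARAMS) == []


class TestIndexUniqueKmers:
    def test_single_contig_all_unique(self):
        idx = ls.index_unique_kmers({"A": "ACGTACGTAA"}, 5)
        # every canonical 5-mer occurring once is indexed
        assert idx.placements and not any("N" in k for k in idx.placements)
        for canon, (cid, pos, orient) in idx.placements.items():
            assert cid == "A" and 0 <= pos <= 5

    def test_shared_kmer_blacklisted(self):
        idx = ls.index_unique_kmers({"A": "AACCGGTTACG", "B": "AACCGGTTTTT"}, 7)
        canon = min("AACCGGT", revcomp("AACCGGT"))
        assert canon in idx.blacklist and canon not in idx.placements

    def test_contig_shorter_than_k_contributes_nothing(self):
        idx = ls.index_unique_kmers({"A": "ACG"}, 5)
        assert idx.placements == {}


def _two_contig_sim(rng, gap=2_000, contig_len=30_000):
    a = _random_seq(rng, contig_len)
    gap_seq = _random_seq(rng, gap)
    b = _random_seq(rng, contig_len)
    genome = a + gap_seq + b
    return {"A": a, "B": b}, genome


class TestBuildLinkGraph:
    def test_spanning_reads_produce_one_supported_edge(self, rng):
        params = ls.LinkParams(k=21, min_links=15, pair_distance=20_000,
                               distance_error=0.02, max_link_ratio=0.1, step=500)
        contigs, genome = _two_contig_sim(rng, gap=2_000, contig_len=30_000)
        index = ls.index_unique_kmers(contigs, params.k)
        reads = []
        for i in range(20):
            start = 5_000 + 100 * i
            reads.append(_read(genome[start:start + 28_000], f"r{i}"))
        pairs = [p for r in reads for p in ls.extract_pairs(r, params)]
        edges = ls.build_link_graph(pairs, index, params,
                                    {c: len(s) for c, s in contigs.items()})
        assert len(edges) == 1
        (edge,) = edges
        assert {edge.end_a, edge.end_b} == {("A", "tail"), ("B", "head")}
        assert edge.support >= 15
        assert abs(edge.gap_median - 2_000) <= params.distance_error * params.pair_distance

    def test_same_contig_pairs_make_no_edge(self, rng):
        params = ls.LinkParams(k=21, pair_distance=2_000, step=50)
        contigs = {"A": _random_seq(rng, 10_000)}
        index = ls.index_unique_kmers(contigs, params.k)
        pairs = ls.extract_pairs(_read(contigs["A"]), params)
        assert pairs
        assert ls.build_link_graph(pairs, index, params, {"A": 10_000}) == []

    def test_implied_gap_never_exceeds_pair_distance(self, rng):
        params = ls.LinkParams(k=21, pair_distance=2_000, step=10)
        contigs, genome = _two_contig_sim(rng, gap=500, contig_len=5_000)
        index = ls.index_unique_kmers(contigs, params.k)
        pairs = [p for i in range(10) for p in
                 ls.extract_pairs(_read(genome[2_000 + i * 30:8_000 + i * 30], f"r{i}"), params)]
        edges = ls.build_link_graph(pairs, index, params,
                                    {c: len(s) for c, s in contigs.items()})
        for edge in edges:
            assert all(g <= params.pair_distance for g in edge.gap_estimates)


def _edge(end_a, end_b, support, gap=100):
    return ls.LinkEdge(end_a, end_b, support, [gap] * support)


class TestLayoutRules:
    CONTIGS = {"A": "A" * 1_000, "B": "C" * 900, "C": "G" * 800}
    PARAMS = ls.LinkParams(k=21, min_links=15, pair_distance=20_000,
                           distance_error=0.02, max_link_ratio=0.1)

    def test_single_strong_edge_joins(self):
        edges = [_edge(("A", "tail"), ("B", "head"), 20)]
        layouts, rejected = ls.layout_scaffolds(edges, self.CONTIGS, self.PARAMS)
        assert joins_from_layouts(layouts) == {frozenset({("A", "tail"), ("B", "head")})}
        assert rejected == []

    def test_link_ratio_blocks_ambiguous_end(self):
        edges = [
            _edge(("A", "tail"), ("B", "head"), 20),
            _edge(("A", "tail"), ("C", "head"), 3),  # 3/20 = 0.15 > 0.1
        ]
        layouts, rejected = ls.layout_scaffolds(edges, self.CONTIGS, self.PARAMS)
        assert joins_from_layouts(layouts) == set()
        assert {r.reason for r in rejected} >= {"link_ratio"}

    def test_min_links_threshold(self):
        edges = [_edge(("A", "tail"), ("B", "head"), 14)]
        layouts, rejected = ls.layout_scaffolds(edges, self.CONTIGS, self.PARAMS)
        assert joins_from_layouts(layouts) == set()
        assert rejected[0].reason == "min_links"

    def test_three_contig_chain(self):
        edges = [
            _edge(("A", "tail"), ("B", "head"), 20),
            _edge(("B", "tail"), ("C", "head"), 18),
        ]
        layouts, _ = ls.layout_scaffolds(edges, self.CONTIGS, self.PARAMS)
        chain = next(l for l in layouts if len(l.parts) == 3)
        assert [p[0] for p in chain.parts] == ["A", "B", "C"]
        assert [p[1] for p in chain.parts] == ["+", "+", "+"]

    def test_gap_is_median_estimate_floored_at_one(self):
        edges = [ls.LinkEdge(("A", "tail"), ("B", "head"), 15, [-50] * 15)]
        layouts, _ = ls.layout_scaffolds(edges, self.CONTIGS, self.PARAMS)
        chain = next(l for l in layouts if len(l.parts) == 2)
        assert chain.parts[0][2] == 1

    def test_cycle_broken_at_weakest_edge(self):
        edges = [
            _edge(("A", "tail"), ("B", "head"), 30),
            _edge(("B", "tail"), ("C", "head"), 25),
            _edge(("C", "tail"), ("A", "head"), 16),
        ]
        layouts, rejected = ls.layout_scaffolds(edges, self.CONTIGS, self.PARAMS)
        assert any(r.reason == "cycle" and r.support == 16 for r in rejected)
        chain = next(l for l in layouts if len(l.parts) == 3)
        assert joins_from_layouts([chain]) == {
            frozenset({("A", "tail"), ("B", "head")}),
            frozenset({("B", "tail"), ("C", "head")}),
        }


@pytest.fixture(scope="module")
def small_sim():
    genome = simulate_genome(1, 200_000, seed=91)
    frag = fragment_genome(genome, 4, min_gap=100, max_gap=400, seed=91,
                           min_contig=20_000, flip_prob=0.5)
    reads = simulate_long_reads(genome, 400, 8_000, 1_500, error_rate=0.02, seed=92)
    return genome, frag, reads


class TestEndToEnd:
    def test_recovers_adjacencies(self, small_sim):
        _, frag, reads = small_sim
        layouts, _, _ = ls.scaffold_assembly(frag.contigs, reads, SCALED)
        truth = {frozenset([a, b]) for a, b, _ in frag.adjacencies}
        made = joins_from_layouts(layouts)
        assert made <= truth  # zero false joins
        assert len(made) / len(truth) >= 0.9

    def test_invariant_under_read_and_contig_order(self, small_sim):
        _, frag, reads = small_sim
        base, _, _ = ls.scaffold_assembly(frag.contigs, reads, SCALED)
        shuffled_contigs = dict(reversed(list(frag.contigs.items())))
        rng = np.random.default_rng(7)
        shuffled_reads = list(reads)
        rng.shuffle(shuffled_reads)
        other, _, _ = ls.scaffold_assembly(shuffled_contigs, shuffled_reads, SCALED)
        assert [(l.scaffold_id, l.parts) for l in base] == [
            (l.scaffold_id, l.parts) for l in other
        ]

    def test_reverse_complementing_reads_leaves_joins_unchanged(self, small_sim):
        _, frag, reads = small_sim
        base, _, _ = ls.scaffold_assembly(frag.contigs, reads, SCALED)
        rc_reads = [QualRead(r.id, revcomp(r.sequence), r.per_base_qualities)
                    for r in reads]
        other, _, _ = ls.scaffold_assembly(frag.contigs, rc_reads, SCALED)
        assert joins_from_layouts(base) == joins_from_layouts(other)

    def test_content_conservation_and_no_duplicate_placement(self, small_sim):
        _, frag, reads = small_sim
        layouts, _, _ = ls.scaffold_assembly(frag.contigs, reads, SCALED)
        placed = [cid for l in layouts for cid in l.component_ids()]
        assert sorted(placed) == sorted(frag.contigs)
        seqs = layout_sequences(layouts, frag.contigs)
        assert sum(len(s) - s.count("N") for s in seqs.values()) == sum(
            len(s) for s in frag.contigs.values()
        )
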