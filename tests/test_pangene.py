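import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    best_feasible_partition_score,
    nw_optimal_identities,
    partition_score,
    planted_component,
    resolve_with_matrix,
)
from panmatrix.formats import GeneAnnotation
from panmatrix.pangene import (
    LiftedGene,
    build_pangenome,
    lift_annotations,
    overlap_components,
    pairwise_identity,
    sense_sequence,
)
from panmatrix.supergenome import AlignmentBlock, BlockEntry, build_supergenome


def lifted(genome, gene, start, stop, strand="+"):
    return LiftedGene(GeneAnnotation(genome, gene, 1, 10, "+"), start, stop, strand)


class TestLift:
    def test_identity_alignment_exact(self):
        blocks = [
            AlignmentBlock(0, (BlockEntry("A", 1, 30, "+", "ACGTACGTAC" * 3),))
        ]
        sg = build_supergenome(blocks)
        [lg] = lift_annotations(sg, [GeneAnnotation("A", "g1", 10, 20, "+", "x")])
        assert (lg.super_start, lg.super_stop, lg.lifted_strand) == (10, 20, "+")

    def test_reverse_block_swaps_endpoints_and_flips_strand(self):
        blocks = [
            AlignmentBlock(
                0,
                (
                    BlockEntry("A", 1, 8, "+", "ACGTACGT"),
                    BlockEntry("B", 1, 8, "-", "ACGTACGT"),
                ),
            )
        ]
        sg = build_supergenome(blocks)
        [lg] = lift_annotations(sg, [GeneAnnotation("B", "g1", 2, 5, "+", "")])
        # genome pos 2..5 on a reverse entry of width 8 -> columns 4..7
        assert (lg.super_start, lg.super_stop) == (4, 7)
        assert lg.lifted_strand == "-"

    def test_unaligned_gene_dropped_with_warning(self, caplog):
        blocks = [AlignmentBlock(0, (BlockEntry("A", 1, 8, "+", "ACGTACGT"),))]
        sg = build_supergenome(blocks)
        with caplog.at_level("WARNING"):
            out = lift_annotations(sg, [GeneAnnotation("A", "g1", 20, 30, "+", "")])
        assert out == []
        assert "no aligned base" in caplog.text

    def test_multiblock_gene_lifted_to_majority_block(self):
        blocks = [
            AlignmentBlock(0, (BlockEntry("A", 1, 10, "+", "ACGTACGTAC"),)),
            AlignmentBlock(1, (BlockEntry("A", 11, 30, "+", "ACGTACGTAC" * 2),)),
        ]
        sg = build_supergenome(blocks)
        # gene covers 3 bases of block 0 and 15 of block 1
        [lg] = lift_annotations(sg, [GeneAnnotation("A", "g1", 8, 25, "+", "")])
        assert (lg.super_start, lg.super_stop) == (11, 25)


class TestOverlapComponents:
    def test_transitive_overlap_examples(self):
        genes = [
            lifted("A", "a", 100, 200),
            lifted("B", "b", 150, 250),
            lifted("C", "c", 300, 400),
        ]
        comps = overlap_components(genes)
        assert [[g.gene_id for g in c] for c in comps] == [["a", "b"], ["c"]]

    def test_abutting_intervals_share_no_column(self):
        comps = overlap_components([lifted("A", "a", 1, 10), lifted("B", "b", 11, 20)])
        assert len(comps) == 2

    def test_chain_is_one_component(self):
        genes = [
            lifted("A", "a", 1, 10),
            lifted("B", "b", 8, 18),
            lifted("C", "c", 16, 26),
        ]
        comps = overlap_components(genes)
        assert len(comps) == 1 and len(comps[0]) == 3

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), min_overlap=st.integers(1, 5))
    def test_matches_union_find_oracle(self, seed, min_overlap):
        """Sweep components equal brute-force pairwise overlap + graph
        connected components."""
        rng = random.Random(seed)
        genes = []
        for k in range(rng.randint(1, 25)):
            s = rng.randint(1, 300)
            genes.append(lifted("G", f"g{k}", s, s + rng.randint(0, 60)))
        comps = overlap_components(genes, min_overlap)
        g = nx.Graph()
        g.add_nodes_from(range(len(genes)))
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                ov = min(a.super_stop, b.super_stop) - max(a.super_start, b.super_start) + 1
                if ov >= min_overlap:
                    g.add_edge(i, j)
        want = {frozenset(genes[i].gene_id for i in c) for c in nx.connected_components(g)}
        got = {frozenset(x.gene_id for x in c) for c in comps}
        assert got == want


class TestPairwiseIdentity:
    def test_identical_and_disjoint(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_single_deletion(self):
        score, idents = nw_optimal_identities("ACGTACGT", "ACGACGT")
        assert pairwise_identity("ACGTACGT", "ACGACGT") in idents
        assert idents == {7 / 8}

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.text(alphabet="ACGT", min_size=1, max_size=9),
        b=st.text(alphabet="ACGT", min_size=1, max_size=9),
    )
    def test_matches_exhaustive_dp_oracle(self, a, b):
        """Identity equals matches/length of an optimal alignment found by an
        independent exhaustive DP (any co-optimal alignment is acceptable)."""
        _, idents = nw_optimal_identities(a, b)
        assert pairwise_identity(a, b) in idents

    def test_symmetric(self):
        rng = random.Random(0)
        for _ in range(10):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)


class TestResolveComponent:
    def test_conflict_free_component_merges_fully(self):
        genes, sim, _ = planted_component(random.Random(123))
        # force a single conflict-free group of 3
        genes = [lifted(g, f"x{g}", 1, 10) for g in ("A", "B", "C")]
        sim = [[0.9] * 3 for _ in range(3)]
        assert resolve_with_matrix(genes, sim) == [frozenset({0, 1, 2})]

    def test_same_genome_conflict_separated(self):
        # two genes of one genome, each similar to a disjoint partner
        genes = [
            lifted("A", "a1", 1, 10),
            lifted("B", "b1", 2, 11),
            lifted("A", "a2", 3, 12),
            lifted("C", "c1", 4, 13),
        ]
        sim = [
            [1.0, 0.9, 0.0, 0.0],
            [0.9, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.9],
            [0.0, 0.0, 0.9, 1.0],
        ]
        groups = resolve_with_matrix(genes, sim)
        assert groups == [frozenset({0, 1}), frozenset({2, 3})]

    def test_below_threshold_stays_apart(self):
        genes = [lifted("A", "a", 1, 10), lifted("B", "b", 1, 10)]
        sim = [[1.0, 0.3], [0.3, 1.0]]
        assert resolve_with_matrix(genes, sim) == [frozenset({0}), frozenset({1})]

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_exhaustive_partition_oracle(self, seed):
        """On planted components (<= 8 genes) greedy resolution attains the
        score-optimal feasible partition found by exhaustive enumeration."""
        rng = random.Random(seed)
        genes, sim, _ = planted_component(rng)
        got = resolve_with_matrix(genes, sim, threshold=0.5)
        gg = [g.genome_id for g in genes]
        best = best_feasible_partition_score(gg, sim, 0.5)
        score = partition_score([list(s) for s in got], sim, 0.5)
        assert score == pytest.approx(best, abs=1e-9)

    def test_recovers_planted_partition(self):
        rng = random.Random(7)
        for _ in range(20):
            genes, sim, truth = planted_component(rng)
            assert resolve_with_matrix(genes, sim) == truth


class TestBuildPangenome:
    def test_clean_recovery_counts(self, clean_toy_dir):
        from panmatrix import build_supergenome, parse_xmfa, read_gff

        ds, paths = clean_toy_dir
        sg = build_supergenome(parse_xmfa(paths["xmfa"]))
        anns = {g: read_gff(paths[f"gff:{g}"], g) for g in sg.genome_roster}
        m = build_pangenome(sg, anns, ds.genomes)
        s = m.summary()
        assert (s.n_pan_genes, s.n_core, s.n_orphan) == (8, 5, 3)

    def test_inverted_member_keeps_group_with_minus_strand(self):
        from panmatrix.fixtures import make_toy_dataset

        ds = make_toy_dataset(seed=3, n_genomes=3, n_core=4, n_orphan_per_genome=0,
                              inversion_rate=1.0)
        sg = build_supergenome(ds.blocks)
        m = build_pangenome(sg, ds.annotations, ds.genomes)
        m.apply_tigrfam(ds.tigrfam)
        assert m == ds.truth
        strands = [mm.strand for pg in m for mm in pg.members.values()]
        assert "-" in strands  # at least one in-place inversion lifted as '-'
        assert all(pg.size == 3 for pg in m)  # inversions never break grouping

    def test_gene_count_conserved(self, noisy_toy_dir):
        from panmatrix import build_supergenome, parse_xmfa, read_gff

        ds, paths = noisy_toy_dir
        sg = build_supergenome(parse_xmfa(paths["xmfa"]))
        anns = {g: read_gff(paths[f"gff:{g}"], g) for g in sg.genome_roster}
        m = build_pangenome(sg, anns, ds.genomes)
        assert m.n_genes() == sum(len(a) for a in ds.annotations.values())
        starts = [pg.super_start for pg in m]
        assert starts == sorted(starts)

    @pytest.mark.parametrize("fraction,joined", [(0.6, True), (0.4, False)])
    def test_truncated_gene_threshold_behaviour(self, fraction, joined):
        """A 60%-length truncated copy still joins its ortholog group at the
        default identity threshold; a 40% fragment splits off."""
        rng = random.Random(5)
        full = "".join(rng.choice("ACGT") for _ in range(450))
        frag = full[: int(len(full) * fraction)]
        ident = pairwise_identity(full, frag)
        assert (ident >= 0.5) is joined

    def test_sense_sequence_orientation(self):
        ann = GeneAnnotation("A", "g", 3, 6, "-")
        assert sense_sequence(ann, "TTACGTTT") == "ACGT"
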