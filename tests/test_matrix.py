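import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import random_events
from panmatrix.fixtures import make_synthetic_matrix
from panmatrix.formats import read_panmap, write_panmap
from panmatrix.matrix import (
    AggregationError,
    Member,
    NotAggregatedError,
    NothingToUndoError,
    PanGene,
    PanGenomeMatrix,
    apply_history,
    classify,
    read_history,
)


def row(pan_id, genomes, strand="+", desc="", start=None, stop=None):
    return PanGene(
        pan_id=pan_id,
        members={g: Member(f"{g}_{pan_id}", strand, desc) for g in genomes},
        super_start=start,
        super_stop=stop,
        consensus_description=desc,
    )


@pytest.fixture
def five_genome_matrix():
    roster = [f"g{i}" for i in range(1, 6)]
    return PanGenomeMatrix(
        roster,
        [
            row("p1", ["g1", "g2"], start=1, stop=100),
            row("p2", ["g3", "g4", "g5"], start=50, stop=160),
            row("p3", ["g2", "g3"], start=200, stop=300),
            row("p4", roster, start=400, stop=500),
            row("p5", ["g5"], start=600, stop=650),
        ],
        clock=lambda: "t0",
    )


class TestClassify:
    @pytest.mark.parametrize(
        "k,n,want",
        [(32, 32, "core"), (1, 32, "orphan"), (2, 32, "dispensable"), (31, 32, "dispensable")],
    )
    def test_categories(self, k, n, want):
        pg = row("p", [f"g{i}" for i in range(k)])
        assert classify(pg, n) == want

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(row("p", ["a", "b"]), 1)


class TestSummary:
    def test_counts(self, five_genome_matrix):
        s = five_genome_matrix.summary()
        assert (s.n_genomes, s.n_pan_genes) == (5, 5)
        assert (s.n_core, s.n_orphan, s.n_dispensable) == (1, 1, 3)

    def test_empty_matrix_all_zero(self):
        s = PanGenomeMatrix(["a", "b"]).summary()
        assert (s.n_pan_genes, s.n_core, s.n_orphan, s.n_dispensable) == (0, 0, 0, 0)

    def test_orphan_completing_group_becomes_core(self):
        roster = ["g1", "g2", "g3"]
        m = PanGenomeMatrix(
            roster,
            [row("p1", ["g1", "g2"], start=1, stop=10), row("p2", ["g3"], start=5, stop=12)],
        )
        before = m.summary()
        m.aggregate(["p1", "p2"])
        after = m.summary()
        assert after.n_core == before.n_core + 1
        assert after.n_orphan == before.n_orphan - 1
        assert after.n_pan_genes == before.n_pan_genes - 1


class TestCanAggregate:
    def test_disjoint_true(self, five_genome_matrix):
        assert five_genome_matrix.can_aggregate(["p1", "p2"]) == (True, "ok")

    def test_shared_genome_reason_names_it(self, five_genome_matrix):
        ok, reason = five_genome_matrix.can_aggregate(["p1", "p3"])
        assert not ok and "g2" in reason

    def test_three_way_disjoint_opposite_strands(self):
        m = PanGenomeMatrix(
            ["g1", "g2", "g3"],
            [
                row("p1", ["g1"], strand="+"),
                row("p2", ["g2"], strand="-"),
                row("p3", ["g3"], strand="+"),
            ],
        )
        assert m.can_aggregate(["p1", "p2", "p3"])[0]

    def test_unknown_id_raises(self, five_genome_matrix):
        with pytest.raises(KeyError):
            five_genome_matrix.can_aggregate(["p1", "nope"])


class TestAggregate:
    def test_merge_2_plus_3_is_core(self, five_genome_matrix):
        m = five_genome_matrix
        agn = m.aggregate(["p1", "p2"])
        merged = m.get(agn)
        assert merged.size == 5
        assert classify(merged, 5) == "core"
        assert merged.aggregated_from == ("p1", "p2")
        assert (merged.super_start, merged.super_stop) == (1, 160)
        assert m.rank(agn) == 0  # placed at the smallest constituent position

    def test_infeasible_raises(self, five_genome_matrix):
        with pytest.raises(AggregationError, match="not feasible"):
            five_genome_matrix.aggregate(["p1", "p3"])

    def test_aggregating_an_agn_with_overlapping_genome_rejected(self, five_genome_matrix):
        m = five_genome_matrix
        inner = m.aggregate(["p1", "p2"])
        assert m.get(inner).display_label == f"{inner} (2)"
        with pytest.raises(AggregationError):
            m.aggregate([inner, "p5"])  # g5 already inside the AGN

    def test_nested_aggregation_label(self):
        m = PanGenomeMatrix(
            ["g1", "g2", "g3"],
            [row("p1", ["g1"]), row("p2", ["g2"]), row("p3", ["g3"])],
        )
        inner = m.aggregate(["p1", "p2"])
        outer = m.aggregate([inner, "p3"])
        assert m.get(outer).display_label == f"{outer} (3)"

    def test_cell_count_conserved_and_rows_drop_by_k_minus_1(self, five_genome_matrix):
        m = five_genome_matrix
        cells, rows = m.n_genes(), len(m)
        m.aggregate(["p1", "p2"])
        assert m.n_genes() == cells and len(m) == rows - 1


class TestDeaggregate:
    def test_exact_inverse(self, five_genome_matrix):
        m = five_genome_matrix
        before = m.pan_genes
        agn = m.aggregate(["p1", "p2"])
        m.deaggregate(agn)
        assert m.pan_genes == before

    def test_nested_one_level_restores_inner_agn(self):
        m = PanGenomeMatrix(
            ["g1", "g2", "g3"],
            [row("p1", ["g1"]), row("p2", ["g2"]), row("p3", ["g3"])],
        )
        inner = m.aggregate(["p1", "p2"])
        snapshot = m.pan_genes
        outer = m.aggregate([inner, "p3"])
        m.deaggregate(outer)
        assert m.pan_genes == snapshot
        assert m.get(inner).is_aggregated

    def test_plain_id_rejected(self, five_genome_matrix):
        with pytest.raises(NotAggregatedError):
            five_genome_matrix.deaggregate("p1")


class TestUndo:
    def test_undo_aggregate(self, five_genome_matrix):
        m = five_genome_matrix
        before = m.pan_genes
        m.aggregate(["p1", "p2"])
        m.undo()
        assert m.pan_genes == before
        assert [e.kind for e in m.history] == ["aggregate", "deaggregate"]

    def test_undo_deaggregate(self, five_genome_matrix):
        m = five_genome_matrix
        agn = m.aggregate(["p1", "p2"])
        state = m.pan_genes
        m.deaggregate(agn)
        m.undo()
        assert m.pan_genes == state

    def test_full_undo_chain_restores_loaded_matrix(self, five_genome_matrix):
        m = five_genome_matrix
        loaded = m.pan_genes
        agn = m.aggregate(["p1", "p2"])
        m.deaggregate(agn)
        m.aggregate(["p3", "p5"])
        m.undo_all()
        assert m.pan_genes == loaded
        with pytest.raises(NothingToUndoError):
            m.undo()


class TestHistory:
    def test_empty_history_header_only(self, five_genome_matrix, tmp_path):
        p = tmp_path / "h.tsv"
        five_genome_matrix.export_history(p)
        assert p.read_text() == "timestamp\tkind\tpan_ids\tresult\n"

    def test_two_events_two_rows(self, five_genome_matrix, tmp_path):
        m = five_genome_matrix
        agn = m.aggregate(["p1", "p2"])
        m.deaggregate(agn)
        p = tmp_path / "h.tsv"
        m.export_history(p)
        assert len(p.read_text().splitlines()) == 3

    def test_replay_reproduces_matrix(self, tmp_path):
        m = make_synthetic_matrix(4, n_genomes=4, n_core=2, n_orphan=3, n_dispensable=3)
        src = tmp_path / "m.tsv"
        write_panmap(m, src)
        random_events(m, random.Random(1), n_events=5)
        hist = tmp_path / "h.tsv"
        m.export_history(hist)
        fresh = read_panmap(src, "pangee")
        apply_history(fresh, read_history(hist))
        assert fresh == m


class TestAlgebraProperties:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_random_event_sequences_keep_invariants(self, seed, tmp_path_factory):
        """Cell count conserved, row count drops by k-1 per k-way merge,
        summary invariant always holds, and full undo restores the loaded
        matrix byte-identically through the pan-map writer."""
        tmp = tmp_path_factory.mktemp("alg")
        rng = random.Random(seed)
        m = make_synthetic_matrix(
            seed, n_genomes=rng.randint(3, 6), n_core=rng.randint(1, 3),
            n_orphan=rng.randint(1, 4), n_dispensable=rng.randint(1, 4),
        )
        p0 = tmp / "orig.tsv"
        write_panmap(m, p0)
        cells = m.n_genes()
        for _ in range(rng.randint(1, 8)):
            rows_before = len(m)
            agg_sizes = [pg.n_leaves for pg in m]
            random_events(m, rng, n_events=1)
            assert m.n_genes() == cells
            s = m.summary()
            assert s.n_core + s.n_orphan + s.n_dispensable == s.n_pan_genes
            assert sum(pg.n_leaves for pg in m) == sum(agg_sizes)
            assert abs(len(m) - rows_before) <= max(2, rows_before)
        m.undo_all()
        p1 = tmp / "restored.tsv"
        write_panmap(m, p1)
        assert p0.read_bytes() == p1.read_bytes()
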