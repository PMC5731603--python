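import pytest

from rescaf.disassemble import ValidatedSegment, ValidationConfig
from rescaf.io_utils import revcomp
from rescaf.reassemble import (
    PipelineConfig,
    PipelineError,
    Scaffold,
    build_scaffolds,
    canonical_walk,
    evaluate,
    fill_gap,
    n50,
    orient_path,
    run_pipeline,
    scaffolds_to_fasta,
    write_agp,
    write_cover_paths,
)
from rescaf.path_cover import AlternatingPathCover
from rescaf.scaffold_graph import HEAD, TAIL, Bridge, ScaffoldGraph, SolidEdge, build_graph
from rescaf.simulate import (
    MutationConfig,
    ReadSimConfig,
    TruthLayout,
    LayoutEntry,
    mutate_assembly,
    random_genome,
    simulate_reads,
)


class TestOrientPath:
    def test_forward_forward(self):
        path = [("A", TAIL), ("A", HEAD), ("B", TAIL), ("B", HEAD)]
        assert orient_path(path) == [("A", "+"), ("B", "+")]

    def test_forward_reverse(self):
        path = [("A", TAIL), ("A", HEAD), ("B", HEAD), ("B", TAIL)]
        assert orient_path(path) == [("A", "+"), ("B", "-")]

    def test_walk_direction_invariant(self):
        path = [("A", TAIL), ("A", HEAD), ("B", HEAD), ("B", TAIL)]
        assert orient_path(list(reversed(path))) == orient_path(path)
        # the non-canonical walk is the flipped reverse of the canonical one
        rev = [("B", TAIL), ("B", HEAD), ("A", HEAD), ("A", TAIL)]
        assert canonical_walk(rev) == path

    def test_singleton(self):
        assert orient_path([("X", HEAD), ("X", TAIL)]) == [("X", "-")]


def _edge(pair, bridges):
    return SolidEdge(pair[0], pair[1], len({b.read_id for b in bridges}), bridges)


class TestFillGap:
    def test_positive_gap_sequence(self):
        reads = {"r": random_genome(1000, 1)}
        br = Bridge("r", ("A", HEAD), ("B", TAIL), 200, 400, 600, 1.0)
        e = _edge((("A", HEAD), ("B", TAIL)), [br])
        join = fill_gap(e, ("A", HEAD), reads)
        assert join.gap_seq == reads["r"][400:600]
        assert join.trim == 0

    def test_reverse_traversal_revcomps(self):
        reads = {"r": random_genome(1000, 2)}
        br = Bridge("r", ("A", HEAD), ("B", TAIL), 200, 400, 600, 1.0)
        e = _edge((("A", HEAD), ("B", TAIL)), [br])
        join = fill_gap(e, ("B", TAIL), reads)
        assert join.gap_seq == revcomp(reads["r"][400:600])

    def test_negative_gap_trims(self):
        br = Bridge("r", ("A", HEAD), ("B", TAIL), -30, 430, 400, 1.0)
        e = _edge((("A", HEAD), ("B", TAIL)), [br])
        join = fill_gap(e, ("A", HEAD), {})
        assert join.gap_seq == "" and join.trim == 30

    def test_best_identity_selected(self):
        reads = {"hi": random_genome(500, 3), "lo": random_genome(500, 4)}
        pair = (("A", HEAD), ("B", TAIL))
        b_hi = Bridge("hi", *pair, 100, 100, 200, 0.99)
        b_lo = Bridge("lo", *pair, 100, 100, 200, 0.95)
        join = fill_gap(_edge(pair, [b_lo, b_hi]), ("A", HEAD), reads)
        assert join.read_id == "hi"

    def test_missing_read_raises(self):
        br = Bridge("gone", ("A", HEAD), ("B", TAIL), 10, 0, 10, 1.0)
        with pytest.raises(KeyError, match="gone"):
            fill_gap(_edge((("A", HEAD), ("B", TAIL)), [br]), ("A", HEAD), {})


class TestBuildScaffolds:
    def _two_segment_setup(self, gap_seq="", overlap=0):
        a = random_genome(600, 10)
        b = random_genome(600, 11)
        if overlap:
            b = a[-overlap:] + b[overlap:]
        segs = [
            ValidatedSegment("segA", "dA", 0, len(a), a, []),
            ValidatedSegment("segB", "dB", 0, len(b), b, []),
        ]
        read = a[-200:] + gap_seq + b[overlap:200]
        reads = {"r": read}
        gap = len(gap_seq) if gap_seq else -overlap
        jstart, jend = 200, 200 + max(gap, 0)
        br = Bridge("r", ("segA", HEAD), ("segB", TAIL), gap, jstart, jend, 1.0)
        graph = build_graph(segs, [br])
        cover = AlternatingPathCover(
            [[("segA", TAIL), ("segA", HEAD), ("segB", TAIL), ("segB", HEAD)]],
            [e.key for e in graph.solid_edges],
            1,
        )
        return cover, graph, segs, reads, a, b

    def test_gap_filled_sequence(self):
        gap = random_genome(150, 12)
        cover, graph, segs, reads, a, b = self._two_segment_setup(gap_seq=gap)
        (sc,) = build_scaffolds(cover, graph, segs, reads)
        assert sc.sequence == a + gap + b
        assert sc.parts == [("segA", "+"), ("segB", "+")]
        assert len(sc.joins) == 1

    def test_negative_gap_trim_restores_truth(self):
        cover, graph, segs, reads, a, b = self._two_segment_setup(overlap=30)
        (sc,) = build_scaffolds(cover, graph, segs, reads)
        # segB begins with segA's last 30 bases; trimming must undo that
        assert sc.sequence == a + b[30:]

    def test_ids_by_descending_length(self):
        segs = [
            ValidatedSegment("s1", "d1", 0, 100, random_genome(100, 13), []),
            ValidatedSegment("s2", "d2", 0, 900, random_genome(900, 14), []),
        ]
        graph = build_graph(segs, [])
        cover = AlternatingPathCover(
            [[("s1", TAIL), ("s1", HEAD)], [("s2", TAIL), ("s2", HEAD)]], [], 0
        )
        scaffolds = build_scaffolds(cover, graph, segs, {})
        assert scaffolds[0].scaffold_id == "scaffold_1"
        assert len(scaffolds[0].sequence) == 900


class TestEvaluate:
    def _layout(self, n, piece=100):
        entries = [
            LayoutEntry(f"d{i}", "ref", i * piece, (i + 1) * piece, "+", i)
            for i in range(n)
        ]
        return TruthLayout(entries)

    def _segments(self, n, piece=100):
        return [
            ValidatedSegment(f"seg{i}", f"d{i}", 0, piece, "N" * piece, [])
            for i in range(n)
        ]

    def test_perfect(self):
        segs, layout = self._segments(3), self._layout(3)
        sc = Scaffold("scaffold_1", [("seg0", "+"), ("seg1", "+"), ("seg2", "+")], [], "N" * 300)
        rep = evaluate([sc], segs, layout)
        assert rep.adjacency_precision == rep.adjacency_recall == 1.0
        assert rep.orientation_accuracy == 1.0
        assert rep.n50 == 300

    def test_flipped_scaffold_still_perfect(self):
        segs, layout = self._segments(2), self._layout(2)
        sc = Scaffold("scaffold_1", [("seg1", "-"), ("seg0", "-")], [], "N" * 200)
        rep = evaluate([sc], segs, layout)
        assert rep.adjacency_precision == rep.adjacency_recall == 1.0

    def test_split_scaffold_drops_recall_only(self):
        segs, layout = self._segments(4), self._layout(4)
        scaffolds = [
            Scaffold("scaffold_1", [("seg0", "+"), ("seg1", "+")], [], "N" * 200),
            Scaffold("scaffold_2", [("seg2", "+"), ("seg3", "+")], [], "N" * 200),
        ]
        rep = evaluate(scaffolds, segs, layout)
        assert rep.adjacency_precision == 1.0
        assert rep.adjacency_recall == pytest.approx(2 / 3)

    def test_wrong_orientation_detected(self):
        segs, layout = self._segments(2), self._layout(2)
        sc = Scaffold("scaffold_1", [("seg0", "+"), ("seg1", "-")], [], "N" * 200)
        rep = evaluate([sc], segs, layout)
        assert rep.adjacency_precision == 0.0
        assert rep.orientation_accuracy == 0.0

    def test_unknown_draft_id_raises(self):
        segs = [ValidatedSegment("s", "nope", 0, 10, "N" * 10, [])]
        with pytest.raises(KeyError, match="nope"):
            evaluate([], segs, self._layout(1))


def test_n50():
    assert n50([]) == 0
    assert n50([10_000]) == 10_000
    assert n50([5, 4, 3, 2, 1]) == 4


class TestRunPipeline:
    def test_fixed_point_error_free(self):
        genome = random_genome(60_000, 20)
        draft = {"chr": genome}
        reads, _ = simulate_reads(
            genome, ReadSimConfig(coverage=20, residual_error_rate=0.0, seed=21)
        )
        res = run_pipeline(draft, reads)
        assert len(res.scaffolds) == 1
        sc = res.scaffolds[0].sequence
        assert sc in genome or revcomp(sc) in genome
        assert len(sc) >= 0.995 * len(genome)

    def test_zero_reads_no_output(self):
        draft = {"chr": random_genome(20_000, 22)}
        res = run_pipeline(draft, {})
        assert res.segments == [] and res.scaffolds == []

    def test_segment_conservation(self):
        genome = random_genome(120_000, 23)
        cfg = MutationConfig(
            n_pieces=4, min_piece_len=20_000, ins_rate=0, del_rate=0, mis_rate=0,
            shuffle_seed=24, revcomp_prob=0.5,
        )
        draft, layout = mutate_assembly(genome, cfg)
        reads, _ = simulate_reads(
            genome, ReadSimConfig(coverage=20, residual_error_rate=0.0, seed=25)
        )
        res = run_pipeline(draft, reads)
        used = [seg for sc in res.scaffolds for seg, _ in sc.parts]
        assert sorted(used) == sorted(s.segment_id for s in res.segments)
        rep = evaluate(res.scaffolds, res.segments, layout)
        assert rep.adjacency_precision == 1.0
        assert rep.orientation_accuracy == 1.0

    def test_stage_error_is_labelled(self):
        # unknown draft id in explicit blocks -> align stage failure
        from conftest import make_blocks

        blocks = make_blocks([(0, 10, 0, 10)], draft_id="missing")
        with pytest.raises(PipelineError, match="stage align"):
            run_pipeline({"chr": "ACGT" * 100}, {"r": "ACGT" * 10}, blocks=blocks)


class TestWriters:
    def _result(self):
        genome = random_genome(60_000, 30)
        cfg = MutationConfig(
            n_pieces=3, min_piece_len=15_000, ins_rate=0, del_rate=0, mis_rate=0,
            shuffle_seed=31, revcomp_prob=0.5,
        )
        draft, _ = mutate_assembly(genome, cfg)
        reads, _ = simulate_reads(
            genome, ReadSimConfig(coverage=20, residual_error_rate=0.0, seed=32)
        )
        return run_pipeline(draft, reads)

    def test_cover_paths_and_agp(self, tmp_path):
        res = self._result()
        write_cover_paths(res.scaffolds, tmp_path / "paths.tsv")
        lines = (tmp_path / "paths.tsv").read_text().splitlines()
        assert len(lines) == len(res.scaffolds)
        assert lines[0].startswith("scaffold_1\t")
        write_agp(res.scaffolds, res.segments, tmp_path / "out.agp", tmp_path / "joins.tsv")
        agp = (tmp_path / "out.agp").read_text()
        assert agp.startswith("##agp-version 2.1")
        # AGP coordinates must tile each scaffold exactly
        for sc in res.scaffolds:
            rows = [l.split("\t") for l in agp.splitlines()[1:] if l.startswith(sc.scaffold_id + "\t")]
            assert int(rows[-1][2]) == len(sc.sequence)
        fasta = scaffolds_to_fasta(res.scaffolds)
        assert set(fasta) == {s.scaffold_id for s in res.scaffolds}
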