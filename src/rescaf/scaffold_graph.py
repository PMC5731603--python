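"""Breakpoint-style scaffold graph: two vertices per validated segment joined
by a dashed edge, plus solid edges between segment ends bridged by long reads,
weighted by supporting-read count."""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .align_model import AlignedBlock, AlignmentSegment, build_segments
from .disassemble import ValidationConfig, ValidatedSegment, segment_gap_pairs

TAIL = "tail"  # 5' end of a segment
HEAD = "head"  # 3' end

Vertex = tuple[str, str]  # (segment_id, TAIL|HEAD)

#: terminal-window rule: a bridging alignment must reach this close to a
#: segment end (interior hits indicate repeats, not junctions)
TERMINAL_WINDOW_BASES = 500
TERMINAL_WINDOW_FRACTION = 0.2

#: bridges between the same vertex pair whose junction gaps differ by at most
#: this many bases are considered the same junction geometry
GAP_MERGE_TOLERANCE = 100


def terminal_window(segment_len: int) -> int:
    return min(TERMINAL_WINDOW_BASES, int(TERMINAL_WINDOW_FRACTION * segment_len))


@dataclass(frozen=True)
class Bridge:
    """One read spanning the junction between two segment ends.

    ``v_first``/``v_second`` are the facing segment ends in read order;
    ``jstart``/``jend`` delimit the junction on the forward read strand
    (``jend < jstart`` means the two segment alignments overlap on the read,
    i.e. a negative gap).
    """

    read_id: str
    v_first: Vertex
    v_second: Vertex
    gap: int
    jstart: int
    jend: int
    identity: float


@dataclass
class SolidEdge:
    u: Vertex
    v: Vertex
    weight: int
    bridges: list[Bridge] = field(default_factory=list)

    @property
    def key(self) -> tuple[Vertex, Vertex]:
        return edge_key(self.u, self.v)

    @property
    def mean_gap(self) -> float:
        return statistics.fmean(b.gap for b in self.bridges) if self.bridges else 0.0


def edge_key(u: Vertex, v: Vertex) -> tuple[Vertex, Vertex]:
    return (u, v) if u <= v else (v, u)


@dataclass
class ScaffoldGraph:
    """Vertices are implied: (seg, tail) and (seg, head) for every segment."""

    segment_ids: list[str]
    seg_len: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[Vertex, Vertex], SolidEdge] = field(default_factory=dict)

    @property
    def vertices(self) -> list[Vertex]:
        return [(s, end) for s in self.segment_ids for end in (TAIL, HEAD)]

    @property
    def dashed_edges(self) -> list[tuple[Vertex, Vertex]]:
        return [((s, TAIL), (s, HEAD)) for s in self.segment_ids]

    @property
    def solid_edges(self) -> list[SolidEdge]:
        return list(self.edges.values())

    def add_solid(self, edge: SolidEdge) -> None:
        if edge.u[0] == edge.v[0]:
            raise ValueError("solid edge may not join the two ends of one segment")
        if edge.key in self.edges:
            raise ValueError(f"duplicate solid edge {edge.key}")
        self.edges[edge.key] = edge

    def validate(self) -> None:
        seen = set(self.segment_ids)
        if len(seen) != len(self.segment_ids):
            raise AssertionError("duplicate segment ids")
        for e in self.edges.values():
            for seg, end in (e.u, e.v):
                if seg not in seen or end not in (TAIL, HEAD):
                    raise AssertionError(f"edge endpoint {(seg, end)} unknown")
            if e.weight < 1:
                raise AssertionError("solid edge weight must be >= 1")

    # -- I/O -----------------------------------------------------------------

    def write_edges(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("v1_segment\tv1_end\tv2_segment\tv2_end\tkind\tweight\tmean_gap\n")
            for s in self.segment_ids:
                fh.write(f"{s}\t{TAIL}\t{s}\t{HEAD}\tdashed\t0\t0.0\n")
            for (u, v), e in sorted(self.edges.items()):
                fh.write(
                    f"{u[0]}\t{u[1]}\t{v[0]}\t{v[1]}\tsolid\t{e.weight}\t{e.mean_gap:.1f}\n"
                )

    @classmethod
    def read_edges(cls, path) -> "ScaffoldGraph":
        graph = cls(segment_ids=[])
        with open(path) as fh:
            fh.readline()
            for line in fh:
                s1, e1, s2, e2, kind, weight, mean_gap = line.rstrip("\n").split("\t")
                if kind == "dashed":
                    graph.segment_ids.append(s1)
                else:
                    gap = int(round(float(mean_gap)))
                    br = Bridge("", (s1, e1), (s2, e2), gap, 0, max(gap, 0), 1.0)
                    graph.add_solid(
                        SolidEdge((s1, e1), (s2, e2), int(weight), [br] * int(weight))
                    )
        return graph

    def to_dot(self) -> str:
        lines = ["graph scaffold {"]
        for s in self.segment_ids:
            lines.append(f'  "{s}.{TAIL}" -- "{s}.{HEAD}" [style=dashed];')
        for (u, v), e in sorted(self.edges.items()):
            lines.append(
                f'  "{u[0]}.{u[1]}" -- "{v[0]}.{v[1]}" [label={e.weight}];'
            )
        lines.append("}")
        return "\n".join(lines)


def _facing_end(hit: AlignmentSegment, side: str, seg_len: int) -> Vertex | None:
    """Segment end facing a junction on the given read ``side`` ('right' =
    later on the read), or None if the alignment stops short of that end."""
    win = terminal_window(seg_len)
    toward_head = (side == "right") == (hit.strand == "+")
    if toward_head:
        return (hit.draft_id, HEAD) if seg_len - hit.draft_end <= win else None
    return (hit.draft_id, TAIL) if hit.draft_start <= win else None


def find_bridging_reads(
    reads: dict[str, str],
    segments: list[ValidatedSegment],
    blocks: list[AlignedBlock],
    cfg: ValidationConfig | None = None,
) -> list[Bridge]:
    """Detect reads whose alignments span the junction between two segments.

    ``blocks`` are read-to-segment alignments (segment ids as draft ids). A
    hit must pass the gap-difference filter and be internally consistent
    (aligned span fraction above ``min_read_fraction``), and must reach into
    the terminal window of the segment end facing the junction. Reads hitting
    k > 2 segments yield k-1 consecutive pairwise bridges.
    """
    cfg = cfg or ValidationConfig()
    seg_seqs = {s.segment_id: s.sequence for s in segments}
    seg_lens = {s.segment_id: len(s.sequence) for s in segments}
    aln = build_segments(blocks, reads, seg_seqs)
    by_read: dict[str, list[AlignmentSegment]] = {}
    for seg in aln:
        if any(abs(g1 - g2) > cfg.max_gap_diff for g1, g2 in segment_gap_pairs(seg)):
            continue
        if not seg.aligned_span_fraction > cfg.min_read_fraction:
            continue
        by_read.setdefault(seg.read_id, []).append(seg)
    bridges: list[Bridge] = []
    for read_id in sorted(by_read):
        hits = sorted(by_read[read_id], key=lambda h: (h.read_start, h.read_end))
        for h1, h2 in zip(hits, hits[1:]):
            if h1.draft_id == h2.draft_id:
                continue
            v1 = _facing_end(h1, "right", seg_lens[h1.draft_id])
            v2 = _facing_end(h2, "left", seg_lens[h2.draft_id])
            if v1 is None or v2 is None:
                continue
            identity = (h1.mean_identity + h2.mean_identity) / 2.0
            bridges.append(
                Bridge(
                    read_id,
                    v1,
                    v2,
                    h2.read_start - h1.read_end,
                    h1.read_end,
                    h2.read_start,
                    identity,
                )
            )
    return bridges


def build_graph(
    segments: list[ValidatedSegment],
    bridges: list[Bridge],
    gap_tolerance: int = GAP_MERGE_TOLERANCE,
) -> ScaffoldGraph:
    """Merge bridges into solid edges.

    Bridges with the same unordered vertex pair and junction gaps within
    ``gap_tolerance`` are pooled into one geometry; if several geometries
    survive between a vertex pair, only the best-supported one is kept
    (ties: larger median junction identity, then smallest read id). A read
    contributes at most one support unit per edge.
    """
    graph = ScaffoldGraph(
        segment_ids=[s.segment_id for s in segments],
        seg_len={s.segment_id: len(s.sequence) for s in segments},
    )
    grouped: dict[tuple[Vertex, Vertex], list[Bridge]] = {}
    for b in bridges:
        if b.v_first[0] == b.v_second[0]:
            continue
        grouped.setdefault(edge_key(b.v_first, b.v_second), []).append(b)
    for key, group in grouped.items():
        group = sorted(group, key=lambda b: (b.gap, b.read_id))
        clusters: list[list[Bridge]] = []
        for b in group:
            if clusters and b.gap - clusters[-1][0].gap <= gap_tolerance:
                clusters[-1].append(b)
            else:
                clusters.append([b])
        best_cluster = None
        best_rank = None
        for cl in clusters:
            # one support unit per read: keep each read's highest-identity bridge
            per_read: dict[str, Bridge] = {}
            for b in sorted(cl, key=lambda b: (-b.identity, b.read_id)):
                per_read.setdefault(b.read_id, b)
            uniq = sorted(per_read.values(), key=lambda b: b.read_id)
            rank = (
                len(uniq),
                statistics.median(b.identity for b in uniq),
                uniq[0].read_id,  # lexicographic tie-break (min is deterministic)
            )
            if best_rank is None or (rank[0], rank[1]) > (best_rank[0], best_rank[1]) or (
                (rank[0], rank[1]) == (best_rank[0], best_rank[1]) and rank[2] < best_rank[2]
            ):
                best_rank = rank
                best_cluster = uniq
        assert best_cluster is not None
        graph.add_solid(SolidEdge(key[0], key[1], len(best_cluster), best_cluster))
    graph.validate()
    return graph
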