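"""Maximum weighted alternating path cover.

The cover must use every dashed edge (one per segment) exactly once and every
vertex exactly once, alternating dashed/solid edges, maximizing the sum of
solid-edge weights. Solved by a matching-based 2-approximation: take a maximum
weight matching over the solid edges, add the dashed edges, and break each
resulting cycle either by deleting its lightest solid edge once ("relaxed") or
by iteratively down-weighting and re-matching ("iterative").

An exact brute-force solver and a Hamiltonian-path reduction instance
generator are provided as test infrastructure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np

from .scaffold_graph import HEAD, TAIL, ScaffoldGraph, SolidEdge, Vertex, edge_key

EdgeKey = tuple[Vertex, Vertex]


@dataclass
class MatchingResult:
    edges: list[EdgeKey]
    weight: int  # M*
    cycles: list[list[EdgeKey]]  # solid-edge keys per alternating cycle
    k_min: int | None  # min number of solid edges over cycles


@dataclass
class AlternatingPathCover:
    paths: list[list[Vertex]]
    used_edges: list[EdgeKey]
    total_weight: int  # ALG


def _dashed_partner(v: Vertex) -> Vertex:
    return (v[0], HEAD if v[1] == TAIL else TAIL)


def _walk(graph: ScaffoldGraph, solid_partner: dict[Vertex, Vertex]):
    """Decompose matching + dashed edges into alternating paths and cycles."""
    visited: set[Vertex] = set()
    paths: list[list[Vertex]] = []
    cycles: list[list[Vertex]] = []

    def follow(start: Vertex) -> list[Vertex]:
        seq = [start]
        visited.add(start)
        cur = start
        use_dashed = True
        while True:
            nxt = _dashed_partner(cur) if use_dashed else solid_partner.get(cur)
            if nxt is None or nxt in visited:
                return seq
            seq.append(nxt)
            visited.add(nxt)
            cur = nxt
            use_dashed = not use_dashed

    for v in graph.vertices:
        if v in visited or v in solid_partner:
            continue
        paths.append(follow(v))
    for v in graph.vertices:  # remaining vertices sit on cycles
        if v not in visited:
            cycles.append(follow(v))
    return paths, cycles


def _cycle_edge_keys(cycle_vertices: list[Vertex]) -> list[EdgeKey]:
    keys = []
    for i in range(1, len(cycle_vertices), 2):
        a = cycle_vertices[i]
        b = cycle_vertices[(i + 1) % len(cycle_vertices)]
        keys.append(edge_key(a, b))
    return keys


def max_weight_matching_solid(
    graph: ScaffoldGraph, weights: dict[EdgeKey, int] | None = None
) -> MatchingResult:
    """Exact maximum-weight matching on the solid-edge subgraph.

    ``weights`` optionally overrides edge weights (edges with non-positive
    weight are ineligible). Also reports the alternating cycles formed when
    the dashed edges are added to the matching.
    """
    G = nx.Graph()
    G.add_nodes_from(graph.vertices)
    for key, e in graph.edges.items():
        w = e.weight if weights is None else weights[key]
        if w > 0:
            G.add_edge(key[0], key[1], weight=w)
    mate = nx.max_weight_matching(G, maxcardinality=False)
    solid_partner: dict[Vertex, Vertex] = {}
    keys: list[EdgeKey] = []
    total = 0
    for u, v in mate:
        solid_partner[u] = v
        solid_partner[v] = u
        keys.append(edge_key(u, v))
        total += graph.edges[edge_key(u, v)].weight if weights is None else weights[edge_key(u, v)]
    _, cycles = _walk(graph, solid_partner)
    cycle_keys = [_cycle_edge_keys(c) for c in cycles]
    k_min = min((len(c) for c in cycle_keys), default=None)
    return MatchingResult(sorted(keys), int(total), cycle_keys, k_min)


def _assemble_cover(graph: ScaffoldGraph, kept: list[EdgeKey]) -> AlternatingPathCover:
    solid_partner: dict[Vertex, Vertex] = {}
    for u, v in kept:
        solid_partner[u] = v
        solid_partner[v] = u
    paths, cycles = _walk(graph, solid_partner)
    if cycles:
        raise AssertionError("cycle survived cycle-breaking: matching bug")
    total = sum(graph.edges[k].weight for k in kept)
    cover = AlternatingPathCover(paths, sorted(kept), int(total))
    check_cover(graph, cover)
    return cover


def cover_from_matching(
    graph: ScaffoldGraph,
    matching: MatchingResult | None = None,
    variant: str = "relaxed",
) -> tuple[AlternatingPathCover, MatchingResult]:
    """Turn a solid-edge matching into an alternating path cover.

    relaxed: delete the minimum-weight solid edge of each cycle once
    (ties broken on the lexicographically smallest vertex pair).
    iterative: down-weight the minimum cycle edge to -1 (making it
    ineligible) and re-match until no cycle remains; the best acyclic
    solution seen over the rounds is returned, so the iterative variant never
    does worse than the relaxed one.
    """
    if variant not in ("relaxed", "iterative"):
        raise ValueError("variant must be 'relaxed' or 'iterative'")
    if matching is None:
        matching = max_weight_matching_solid(graph)

    def relax(mr: MatchingResult) -> list[EdgeKey]:
        dropped = set()
        for cyc in mr.cycles:
            dropped.add(min(cyc, key=lambda k: (graph.edges[k].weight, k)))
        return [k for k in mr.edges if k not in dropped]

    if variant == "relaxed":
        return _assemble_cover(graph, relax(matching)), matching

    weights = {k: e.weight for k, e in graph.edges.items()}
    mr = matching
    best: list[EdgeKey] | None = None
    best_w = -1
    for _ in range(len(graph.edges) + 1):
        kept = relax(mr)  # acyclic candidate from this round
        w = sum(graph.edges[k].weight for k in kept)
        if w > best_w:
            best, best_w = kept, w
        if not mr.cycles:
            break
        for cyc in mr.cycles:
            weights[min(cyc, key=lambda k: (weights[k], k))] = -1
        mr = max_weight_matching_solid(graph, weights)
    assert best is not None
    return _assemble_cover(graph, best), matching


def check_cover(graph: ScaffoldGraph, cover: AlternatingPathCover) -> None:
    """Assert the exact cover constraints: every vertex and every dashed edge
    exactly once, strict alternation, dashed first and last edges."""
    seen: set[Vertex] = set()
    dashed_used: set[EdgeKey] = set()
    for path in cover.paths:
        if len(path) < 2 or len(path) % 2 != 0:
            raise AssertionError(f"path {path} cannot start and end with dashed edges")
        for v in path:
            if v in seen:
                raise AssertionError(f"vertex {v} appears twice")
            seen.add(v)
        for i, (a, b) in enumerate(zip(path, path[1:])):
            if i % 2 == 0:  # dashed
                if a[0] != b[0] or a[1] == b[1]:
                    raise AssertionError(f"edge {a}-{b} at position {i} is not dashed")
                dashed_used.add(edge_key(a, b))
            else:  # solid
                if edge_key(a, b) not in graph.edges:
                    raise AssertionError(f"solid edge {a}-{b} not in graph")
    if seen != set(graph.vertices):
        raise AssertionError("cover does not touch every vertex exactly once")
    if dashed_used != {edge_key(u, v) for u, v in graph.dashed_edges}:
        raise AssertionError("cover does not use every dashed edge exactly once")
    w = sum(graph.edges[k].weight for k in cover.used_edges)
    if w != cover.total_weight:
        raise AssertionError("total_weight inconsistent with used edges")


# ---------------------------------------------------------------------------
# exact oracle and reduction (test infrastructure)
# ---------------------------------------------------------------------------

BRUTE_FORCE_MAX_SEGMENTS = 8


def brute_force_cover(graph: ScaffoldGraph) -> AlternatingPathCover:
    """Exhaustive optimum via matching enumeration with cycle pruning.

    A set of solid edges extends to an alternating path cover iff it is a
    matching and, viewing each solid edge as joining its two segments, the
    segment-level graph is acyclic; the cover weight is the matching weight.
    """
    n = len(graph.segment_ids)
    if n > BRUTE_FORCE_MAX_SEGMENTS:
        raise ValueError(f"brute force capped at {BRUTE_FORCE_MAX_SEGMENTS} segments")
    edges = sorted(graph.edges.values(), key=lambda e: (-e.weight, e.key))
    seg_index = {s: i for i, s in enumerate(graph.segment_ids)}
    suffix = [0] * (len(edges) + 1)
    for i in range(len(edges) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + edges[i].weight
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            x = parent[x]
        return x

    best_w = -1
    best_kept: list[EdgeKey] = []
    used: set[Vertex] = set()
    kept: list[EdgeKey] = []

    def rec(i: int, w: int) -> None:
        nonlocal best_w, best_kept
        if w + suffix[i] <= best_w:
            return
        if i == len(edges):
            if w > best_w:
                best_w, best_kept = w, list(kept)
            return
        e = edges[i]
        if e.u not in used and e.v not in used:
            ra, rb = find(seg_index[e.u[0]]), find(seg_index[e.v[0]])
            if ra != rb:
                parent[rb] = ra
                used.update((e.u, e.v))
                kept.append(e.key)
                rec(i + 1, w + e.weight)
                kept.pop()
                used.difference_update((e.u, e.v))
                parent[rb] = rb
        rec(i + 1, w)

    rec(0, 0)
    return _assemble_cover(graph, best_kept)


def max_matching_weight_bruteforce(edges: list[tuple[object, object, int]]) -> int:
    """Maximum weight matching by exhaustive enumeration (generic oracle)."""
    edges = sorted(edges, key=lambda e: -e[2])
    suffix = [0] * (len(edges) + 1)
    for i in range(len(edges) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + edges[i][2]
    best = 0
    used: set[object] = set()

    def rec(i: int, w: int) -> None:
        nonlocal best
        best = max(best, w)
        if i == len(edges) or w + suffix[i] <= best:
            return
        u, v, wt = edges[i]
        if u not in used and v not in used:
            used.update((u, v))
            rec(i + 1, w + wt)
            used.difference_update((u, v))
        rec(i + 1, w)

    rec(0, 0)
    return best


def hamiltonian_reduction(g: nx.Graph) -> ScaffoldGraph:
    """Scaffolding instance such that the input graph has a Hamiltonian path
    iff the instance admits a cover of weight >= n - 1.

    Each input vertex becomes one segment; each input edge (a, b) becomes two
    weight-1 solid edges, between the tail copies and between the head copies.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 vertices")
    seg_ids = [str(v) for v in sorted(g.nodes, key=str)]
    graph = ScaffoldGraph(segment_ids=seg_ids, seg_len={s: 1 for s in seg_ids})
    for a, b in g.edges:
        sa, sb = str(a), str(b)
        graph.add_solid(SolidEdge((sa, TAIL), (sb, TAIL), 1))
        graph.add_solid(SolidEdge((sa, HEAD), (sb, HEAD), 1))
    return graph


def has_hamiltonian_path(g: nx.Graph) -> bool:
    """Exhaustive Hamiltonian-path search (independent oracle, small n)."""
    nodes = list(g.nodes)
    if len(nodes) <= 1:
        return True
    for perm in permutations(nodes):
        if all(g.has_edge(a, b) for a, b in zip(perm, perm[1:])):
            return True
    return False


def random_instance(
    n_segments: int, edge_prob: float = 0.4, max_weight: int = 10, seed=0
) -> ScaffoldGraph:
    """Random scaffolding instance: each cross-segment vertex pair becomes a
    solid edge with probability ``edge_prob`` and integer weight 1..max_weight."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seg_ids = [f"s{i:02d}" for i in range(n_segments)]
    graph = ScaffoldGraph(segment_ids=seg_ids, seg_len={s: 1 for s in seg_ids})
    verts = graph.vertices
    for i in range(len(verts)):
        for j in range(i + 1, len(verts)):
            u, v = verts[i], verts[j]
            if u[0] == v[0]:
                continue
            if rng.random() < edge_prob:
                graph.add_solid(SolidEdge(u, v, int(rng.integers(1, max_weight + 1))))
    return graph
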