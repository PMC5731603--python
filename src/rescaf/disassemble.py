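"""Validation, merging and extraction of structurally consistent draft segments.

Alignment segments survive when (i) every consecutive block pair has draft/read
gap lengths within ``max_gap_diff`` of each other and (ii) the aligned fraction
of the read strictly exceeds ``min_read_fraction``. Surviving draft intervals
overlapping by at least ``delta`` are merged transitively; thinner overlaps are
truncated away so extracted segments are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align_model import AlignmentSegment, needleman_wunsch
from .io_utils import revcomp

logger = logging.getLogger(__name__)


@dataclass
class ValidationConfig:
    max_gap_diff: int = 30
    min_read_fraction: float = 0.99
    delta: int = 50
    consensus_mode: str = "simple"  # "simple" | "consensus"
    min_support: int = 1
    fraction_of_smaller: bool = False

    def __post_init__(self):
        if self.max_gap_diff < 0:
            raise ValueError("max_gap_diff must be >= 0")
        if not (0.0 < self.min_read_fraction <= 1.0):
            raise ValueError("min_read_fraction must be in (0,1]")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.consensus_mode not in ("simple", "consensus"):
            raise ValueError("consensus_mode must be 'simple' or 'consensus'")


@dataclass(frozen=True)
class SupportingRead:
    read_id: str
    read_start: int
    read_end: int
    strand: str


@dataclass
class MergedInterval:
    draft_id: str
    start: int
    end: int
    supports: list[SupportingRead] = field(default_factory=list)


@dataclass
class ValidatedSegment:
    """A structurally validated draft interval with its supporting reads."""

    segment_id: str
    draft_id: str
    start: int
    end: int
    sequence: str
    supporting_reads: list[SupportingRead]


def segment_gap_pairs(seg: AlignmentSegment) -> list[tuple[int, int]]:
    """(draft gap, read gap) lengths for every consecutive block pair."""
    pairs = []
    for prev, cur in zip(seg.blocks, seg.blocks[1:]):
        g1 = cur.DL - prev.DR
        g2 = cur.RL - prev.RR if seg.strand == "+" else prev.RL - cur.RR
        pairs.append((g1, g2))
    return pairs


def validate_segment(
    seg: AlignmentSegment, cfg: ValidationConfig, draft_len: int | None = None
) -> tuple[bool, str | None]:
    """Keep/reject decision for one alignment segment, with the first violated
    condition as the rejection reason."""
    for g1, g2 in segment_gap_pairs(seg):
        if abs(g1 - g2) > cfg.max_gap_diff:
            return False, f"gap-diff |{g1}-{g2}| > {cfg.max_gap_diff}"
    fraction = seg.aligned_read_fraction
    if cfg.fraction_of_smaller and draft_len is not None and draft_len < seg.read_len:
        fraction = fraction * seg.read_len / draft_len
    if not fraction > cfg.min_read_fraction:
        return False, f"read-fraction {fraction:.4f} <= {cfg.min_read_fraction}"
    return True, None


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def merge_segments(
    items: list[tuple[str, int, int, SupportingRead]], delta: int
) -> list[MergedInterval]:
    """Merge draft intervals under the transitive closure of 'overlap >= delta'.

    ``items`` are ``(draft_id, start, end, support)`` tuples. Intervals in one
    merged group are replaced by their union; groups whose extents still touch
    by less than ``delta`` are made disjoint by truncating the later one at the
    earlier one's end.
    """
    by_draft: dict[str, list[tuple[int, int, SupportingRead]]] = {}
    for draft_id, s, e, sup in items:
        by_draft.setdefault(draft_id, []).append((s, e, sup))
    out: list[MergedInterval] = []
    for draft_id in sorted(by_draft):
        ivals = sorted(by_draft[draft_id], key=lambda t: (t[0], t[1]))
        dsu = _DSU(len(ivals))
        prefix_max: list[int] = []
        pm = 0
        for _, e, _ in ivals:
            pm = max(pm, e)
            prefix_max.append(pm)
        # backward sweep: an earlier interval (start <= s) overlaps the current
        # one by >= delta iff its end reaches s + delta
        for i, (s, e, _) in enumerate(ivals):
            for j in range(i - 1, -1, -1):
                if prefix_max[j] < s + delta:
                    break
                if min(e, ivals[j][1]) - s >= delta:
                    dsu.union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(len(ivals)):
            groups.setdefault(dsu.find(i), []).append(i)
        merged = []
        for members in groups.values():
            start = min(ivals[i][0] for i in members)
            end = max(ivals[i][1] for i in members)
            sups = [ivals[i][2] for i in sorted(members)]
            merged.append(MergedInterval(draft_id, start, end, sups))
        merged.sort(key=lambda m: (m.start, m.end))
        disjoint: list[MergedInterval] = []
        for m in merged:
            if disjoint and m.start < disjoint[-1].end:
                m.start = disjoint[-1].end  # thin overlap: truncate the later one
                if m.start >= m.end:
                    logger.info("interval on %s swallowed during truncation", draft_id)
                    continue
            disjoint.append(m)
        out.extend(disjoint)
    return out


def _consensus_sequence(
    draft_sub: str, supports: list[SupportingRead], reads: dict[str, str]
) -> str:
    """Column-majority consensus of supporting reads realigned to the draft."""
    n = len(draft_sub)
    votes: list[dict[str, int]] = [dict() for _ in range(n)]
    inserts: list[dict[str, int]] = [dict() for _ in range(n + 1)]
    coverage = [0] * n
    for sup in supports:
        read_sub = reads[sup.read_id][sup.read_start : sup.read_end]
        if sup.strand == "-":
            read_sub = revcomp(read_sub)
        _, (ad, ar) = needleman_wunsch(draft_sub, read_sub, cap=None)
        p = 0
        pending = ""
        for cd, cr in zip(ad, ar):
            if cd == "-":
                pending += cr
                continue
            if pending:
                inserts[p][pending] = inserts[p].get(pending, 0) + 1
                pending = ""
            votes[p][cr] = votes[p].get(cr, 0) + 1
            coverage[p] += 1
            p += 1
        if pending:
            inserts[p][pending] = inserts[p].get(pending, 0) + 1
    out = []
    for p in range(n):
        ins = inserts[p]
        if ins:
            best_ins, cnt = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            if coverage[p] and cnt * 2 > coverage[p]:
                out.append(best_ins)
        if not coverage[p]:
            out.append(draft_sub[p])
            continue
        ranked = sorted(votes[p].items(), key=lambda kv: (-kv[1], kv[0]))
        best, cnt = ranked[0]
        if len(ranked) > 1 and ranked[1][1] == cnt:
            best = draft_sub[p]  # tie -> draft base
        if best != "-":
            out.append(best)
    return "".join(out)


def extract_segments(
    draft: dict[str, str],
    merged: list[MergedInterval],
    reads: dict[str, str],
    cfg: ValidationConfig,
) -> list[ValidatedSegment]:
    """Extract validated segments, verbatim or as read consensus."""
    out: list[ValidatedSegment] = []
    idx = 0
    for m in merged:
        if len(m.supports) < cfg.min_support:
            continue
        if m.draft_id not in draft:
            raise KeyError(f"draft sequence {m.draft_id!r} not found")
        seq_len = len(draft[m.draft_id])
        if not (0 <= m.start < m.end <= seq_len):
            raise ValueError(
                f"interval {m.start}:{m.end} outside draft {m.draft_id} (len {seq_len})"
            )
        sub = draft[m.draft_id][m.start : m.end]
        if cfg.consensus_mode == "consensus":
            sub = _consensus_sequence(sub, m.supports, reads)
        out.append(
            ValidatedSegment(f"seg_{idx:04d}", m.draft_id, m.start, m.end, sub, list(m.supports))
        )
        idx += 1
    return out


def run_disassembly(
    segments: list[AlignmentSegment],
    draft: dict[str, str],
    reads: dict[str, str],
    cfg: ValidationConfig | None = None,
) -> list[ValidatedSegment]:
    """validate -> merge -> extract, the full disassembling stage."""
    cfg = cfg or ValidationConfig()
    items = []
    for seg in segments:
        keep, _ = validate_segment(seg, cfg, draft_len=len(draft[seg.draft_id]))
        if not keep:
            continue
        sup = SupportingRead(seg.read_id, seg.read_start, seg.read_end, seg.strand)
        items.append((seg.draft_id, seg.draft_start, seg.draft_end, sup))
    merged = merge_segments(items, cfg.delta)
    return extract_segments(draft, merged, reads, cfg)


def write_bed(segments: list[ValidatedSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.draft_id}\t{s.start}\t{s.end}\t{s.segment_id}\n")


def segments_to_fasta(segments: list[ValidatedSegment]) -> dict[str, str]:
    return {s.segment_id: s.sequence for s in segments}
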