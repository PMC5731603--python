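"""Long-read-to-draft alignments as aligned blocks.

An aligner's tabular output is modelled as a sequence of aligned blocks
``(DL, DR, RL, RR)``: draft interval aligned to read interval. Blocks of one
(draft, read, strand) group are sorted, overlap-trimmed, and the small gaps
between consecutive blocks are closed by global (Needleman-Wunsch) alignment,
yielding one :class:`AlignmentSegment` per chain.

A toy exact-match aligner (:func:`toy_align`) produces blocks from scratch so
the whole pipeline is testable without any external aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io_utils import encode, revcomp

logger = logging.getLogger(__name__)

DEFAULT_NW_CAP = 5000


class AlignmentCapError(ValueError):
    """Raised when a global alignment would exceed the configured size cap."""


@dataclass
class AlignedBlock:
    """One aligned interval pair between a draft sequence and a read.

    Coordinates are 0-based half-open; ``RL``/``RR`` are always on the forward
    read strand, with ``strand`` recording the read orientation relative to
    the draft.
    """

    draft_id: str
    read_id: str
    DL: int
    DR: int
    RL: int
    RR: int
    strand: str = "+"
    identity: float = 1.0

    def __post_init__(self):
        if not (self.DL < self.DR and self.RL < self.RR):
            raise ValueError(f"degenerate block {self}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0,1]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def draft_span(self) -> int:
        return self.DR - self.DL

    @property
    def read_span(self) -> int:
        return self.RR - self.RL


@dataclass
class AlignmentSegment:
    """A trimmed, gap-closed chain of aligned blocks for one (draft, read) pair."""

    draft_id: str
    read_id: str
    strand: str
    blocks: list[AlignedBlock]
    closed_gaps: list[tuple[tuple[int, int], tuple[int, int], int]]
    read_len: int
    aligned_read_fraction: float

    @property
    def draft_start(self) -> int:
        return self.blocks[0].DL

    @property
    def draft_end(self) -> int:
        return self.blocks[-1].DR

    @property
    def read_start(self) -> int:
        return min(b.RL for b in self.blocks)

    @property
    def read_end(self) -> int:
        return max(b.RR for b in self.blocks)

    @property
    def mean_identity(self) -> float:
        spans = [b.read_span for b in self.blocks]
        idents = [b.identity for b in self.blocks]
        return float(np.average(idents, weights=spans))

    @property
    def aligned_span_fraction(self) -> float:
        """Aligned bases divided by the read span of the chain itself."""
        aligned = sum(b.read_span for b in self.blocks) + sum(
            abs(r1 - r0) for _, (r0, r1), _ in self.closed_gaps
        )
        span = self.read_end - self.read_start
        return aligned / span if span else 0.0


# ---------------------------------------------------------------------------
# coords dialect I/O (S1 E1 S2 E2 LEN1 LEN2 %IDY REF_ID QRY_ID, 1-based incl.)
# ---------------------------------------------------------------------------

def parse_coords(path) -> list[AlignedBlock]:
    """Parse a tab-separated aligned-block table into blocks.

    File coordinates are 1-based inclusive; reverse-strand rows carry read
    start > read end and are normalized to forward-strand half-open
    coordinates with ``strand='-'``. Header/non-numeric lines are skipped;
    zero-length rows are rejected and logged.
    """
    blocks: list[AlignedBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if not fields or not fields[0]:
                continue
            try:
                int(fields[0])
            except ValueError:
                continue  # header line
            if len(fields) < 9:
                raise ValueError(f"malformed coords row at line {lineno}: {line!r}")
            try:
                s1, e1, s2, e2 = (int(x) for x in fields[:4])
                idy = float(fields[6])
                ref_id, qry_id = fields[7], fields[8]
            except ValueError as exc:
                raise ValueError(f"malformed coords row at line {lineno}: {exc}") from exc
            if s1 == e1 or s2 == e2:
                logger.warning("coords line %d: zero-length interval, skipped", lineno)
                continue
            if s2 <= e2:
                rl, rr, strand = s2 - 1, e2, "+"
            else:
                rl, rr, strand = e2 - 1, s2, "-"
            blocks.append(
                AlignedBlock(ref_id, qry_id, s1 - 1, e1, rl, rr, strand, idy / 100.0)
            )
    return blocks


def write_coords(blocks: list[AlignedBlock], path) -> None:
    """Write blocks back to the 9-column coords dialect (inverse of parse)."""
    with open(path, "w") as fh:
        fh.write("S1\tE1\tS2\tE2\tLEN1\tLEN2\t%IDY\tREF_ID\tQRY_ID\n")
        for b in blocks:
            if b.strand == "+":
                s2, e2 = b.RL + 1, b.RR
            else:
                s2, e2 = b.RR, b.RL + 1
            fh.write(
                f"{b.DL + 1}\t{b.DR}\t{s2}\t{e2}\t{b.draft_span}\t{b.read_span}"
                f"\t{b.identity * 100:.2f}\t{b.draft_id}\t{b.read_id}\n"
            )


# ---------------------------------------------------------------------------
# overlap trimming
# ---------------------------------------------------------------------------

def trim_overlaps(blocks: list[AlignedBlock]) -> list[AlignedBlock]:
    """Remove draft/read overlaps between consecutive blocks of one chain.

    Blocks must belong to one (draft, read, strand) group and be sorted by
    ``DL``. When consecutive blocks overlap in draft or read coordinates, the
    left ends (draft and read jointly) of the right block are advanced by the
    larger of the two overlaps; blocks reduced to nothing are dropped.
    """
    out: list[AlignedBlock] = []
    for blk in blocks:
        cur = blk
        if out:
            prev = out[-1]
            od = prev.DR - cur.DL
            if cur.strand == "+":
                orr = prev.RR - cur.RL
            else:
                orr = cur.RR - prev.RL
            t = max(od, orr, 0)
            if t > 0:
                if t >= cur.draft_span or t >= cur.read_span:
                    continue  # fully contained, drop
                if cur.strand == "+":
                    cur = replace(cur, DL=cur.DL + t, RL=cur.RL + t)
                else:
                    cur = replace(cur, DL=cur.DL + t, RR=cur.RR - t)
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# Needleman-Wunsch
# ---------------------------------------------------------------------------

def _nw_matrix(a: np.ndarray, b: np.ndarray, match: int, mismatch: int, gap: int) -> np.ndarray:
    n, m = a.size, b.size
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    idx = np.arange(m + 1, dtype=np.int32)
    H[0] = gap * idx
    gidx = gap * idx
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], match, mismatch).astype(np.int32)
        cand = np.empty(m + 1, dtype=np.int32)
        cand[0] = gap * i
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap, out=cand[1:])
        # fold in horizontal (left) gaps with a running max
        H[i] = np.maximum.accumulate(cand - gidx) + gidx
    return H


def needleman_wunsch(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -1,
    cap: int | None = DEFAULT_NW_CAP,
    with_alignment: bool = True,
):
    """Optimal global alignment of two nucleotide strings.

    Returns ``(score, (aligned_a, aligned_b))`` (or just the score when
    ``with_alignment`` is false). Scoring is linear-gap with defaults
    match=+1, mismatch=-1, gap=-1. Raises :class:`AlignmentCapError` when
    either sequence exceeds ``cap``.
    """
    if cap is not None and (len(a) > cap or len(b) > cap):
        raise AlignmentCapError(f"alignment size {len(a)}x{len(b)} exceeds cap {cap}")
    ca, cb = encode(a), encode(b)
    H = _nw_matrix(ca, cb, match, mismatch, gap)
    score = int(H[len(a), len(b)])
    if not with_alignment:
        return score
    # traceback, preferring diagonal then up then left
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if ca[i - 1] == cb[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
            continue
        ra.append("-")
        rb.append(b[j - 1])
        j -= 1
    return score, ("".join(reversed(ra)), "".join(reversed(rb)))


def _count_pairwise_ops(aligned_ref: str, aligned_alt: str) -> dict[str, int]:
    counts = {"ins": 0, "del": 0, "mis": 0, "match": 0}
    for r, q in zip(aligned_ref, aligned_alt):
        if r == "-":
            counts["ins"] += 1
        elif q == "-":
            counts["del"] += 1
        elif r == q:
            counts["match"] += 1
        else:
            counts["mis"] += 1
    return counts


# ---------------------------------------------------------------------------
# toy exact-match aligner
# ---------------------------------------------------------------------------

def _kmer_array(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes plus a validity mask (no ambiguous bases)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    km = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        km = (km << 2) | codes[j : n - k + 1 + j].astype(np.int64)
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return km, valid


def _build_index(targets: dict[str, str], k: int):
    names = list(targets)
    codes = {t: encode(targets[t]) for t in names}
    index: dict[int, tuple[str, int]] = {}
    dup: set[int] = set()
    for t in names:
        km, valid = _kmer_array(codes[t], k)
        for pos, (v, ok) in enumerate(zip(km.tolist(), valid.tolist())):
            if not ok or v in dup:
                continue
            if v in index:
                del index[v]
                dup.add(v)
            else:
                index[v] = (t, pos)
    return index, codes


def _extend_right(q: np.ndarray, t: np.ndarray, qi: int, ti: int) -> int:
    run = 0
    while True:
        c = min(4096, q.size - qi - run, t.size - ti - run)
        if c <= 0:
            return run
        eq = q[qi + run : qi + run + c] == t[ti + run : ti + run + c]
        bad = np.flatnonzero(~eq)
        if bad.size:
            return run + int(bad[0])
        run += c


def _extend_left(q: np.ndarray, t: np.ndarray, qi: int, ti: int) -> int:
    run = 0
    while True:
        c = min(4096, qi - run, ti - run)
        if c <= 0:
            return run
        eq = q[qi - run - c : qi - run] == t[ti - run - c : ti - run]
        bad = np.flatnonzero(~eq)
        if bad.size:
            return run + (c - 1 - int(bad[-1]))
        run += c


def _scan(q_codes, index, codes, k: int, stride: int):
    """Greedy seed-and-extend of one query against the shared k-mer index."""
    km, valid = _kmer_array(q_codes, k)
    kml = km.tolist()
    vl = valid.tolist()
    hits: list[tuple[str, int, int, int, int]] = []
    covered: dict[tuple[str, int], int] = {}
    i = 0
    n = len(kml)
    while i < n:
        if vl[i]:
            hit = index.get(kml[i])
            if hit is not None:
                t_id, tpos = hit
                diag = tpos - i
                if covered.get((t_id, diag), -1) < i:
                    tc = codes[t_id]
                    left = _extend_left(q_codes, tc, i, tpos)
                    right = _extend_right(q_codes, tc, i + k, tpos + k)
                    qs, qe = i - left, i + k + right
                    hits.append((t_id, qs, qe, tpos - left, tpos + k + right))
                    covered[(t_id, diag)] = qe
                    i = max(i + 1, qe)
                    continue
        i += stride
    return hits


def toy_align(
    queries: dict[str, str],
    targets: dict[str, str],
    k: int = 21,
    stride: int = 20,
    min_block: int = 30,
) -> list[AlignedBlock]:
    """Exact-match block aligner for tests and self-contained pipelines.

    Seeds on unique target k-mers, extends maximally in both directions, and
    emits one block per maximal exact run (both query strands are scanned).
    Repeated target k-mers are ignored, so this is only appropriate for
    low-repeat (random or simulated) sequences; residual mismatches between
    runs are left for the Needleman-Wunsch gap-closing step.
    """
    index, codes = _build_index(targets, k)
    blocks: list[AlignedBlock] = []
    for q_id, q_seq in queries.items():
        qlen = len(q_seq)
        for strand in "+-":
            q_codes = encode(q_seq if strand == "+" else revcomp(q_seq))
            for t_id, qs, qe, ts, te in _scan(q_codes, index, codes, k, stride):
                if qe - qs < min_block:
                    continue
                if strand == "+":
                    rl, rr = qs, qe
                else:
                    rl, rr = qlen - qe, qlen - qs
                blocks.append(AlignedBlock(t_id, q_id, ts, te, rl, rr, strand, 1.0))
    return blocks


# ---------------------------------------------------------------------------
# segment building
# ---------------------------------------------------------------------------

def group_blocks(blocks: list[AlignedBlock]) -> dict[tuple[str, str, str], list[AlignedBlock]]:
    groups: dict[tuple[str, str, str], list[AlignedBlock]] = {}
    for b in blocks:
        groups.setdefault((b.draft_id, b.read_id, b.strand), []).append(b)
    for g in groups.values():
        g.sort(key=lambda b: (b.DL, b.RL))
    return groups


def _split_read_order(blocks: list[AlignedBlock]) -> list[list[AlignedBlock]]:
    """Split a DL-sorted group where read order fails to advance (inversions)."""
    chains: list[list[AlignedBlock]] = []
    for b in blocks:
        if chains:
            prev = chains[-1][-1]
            ok = b.RL >= prev.RL if b.strand == "+" else b.RR <= prev.RR
            if not ok:
                chains.append([b])
                continue
            chains[-1].append(b)
        else:
            chains.append([b])
    return chains


def build_segments(
    blocks: list[AlignedBlock],
    reads: dict[str, str],
    draft: dict[str, str],
    nw_cap: int = DEFAULT_NW_CAP,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -1,
) -> list[AlignmentSegment]:
    """Assemble per-(draft, read, strand) alignment segments.

    Each group is sorted, overlap-trimmed, and inter-block gaps are closed by
    Needleman-Wunsch on the intervening draft and read substrings. Gaps larger
    than ``nw_cap`` on either side split the chain into separate segments.
    """
    segments: list[AlignmentSegment] = []
    for (draft_id, read_id, strand), group in group_blocks(blocks).items():
        if read_id not in reads:
            raise KeyError(f"read {read_id!r} missing from read FASTA")
        if draft_id not in draft:
            raise KeyError(f"draft sequence {draft_id!r} missing from draft FASTA")
        read_seq = reads[read_id]
        draft_seq = draft[draft_id]
        read_len = len(read_seq)
        for chain in _split_read_order(group):
            trimmed = trim_overlaps(chain)
            if not trimmed:
                continue
            # split further where a gap exceeds the NW cap
            pieces: list[list[AlignedBlock]] = [[trimmed[0]]]
            for prev, cur in zip(trimmed, trimmed[1:]):
                g1 = cur.DL - prev.DR
                g2 = cur.RL - prev.RR if strand == "+" else prev.RL - cur.RR
                if g1 > nw_cap or g2 > nw_cap:
                    logger.info(
                        "gap %d/%d exceeds cap %d for %s~%s; segment split",
                        g1, g2, nw_cap, draft_id, read_id,
                    )
                    pieces.append([cur])
                else:
                    pieces[-1].append(cur)
            for piece in pieces:
                closed: list[tuple[tuple[int, int], tuple[int, int], int]] = []
                for prev, cur in zip(piece, piece[1:]):
                    dgap = (prev.DR, cur.DL)
                    rgap = (prev.RR, cur.RL) if strand == "+" else (cur.RR, prev.RL)
                    if dgap[1] - dgap[0] <= 0 and rgap[1] - rgap[0] <= 0:
                        continue
                    dsub = draft_seq[dgap[0] : dgap[1]]
                    rsub = read_seq[rgap[0] : rgap[1]]
                    if strand == "-":
                        rsub = revcomp(rsub)
                    score = needleman_wunsch(
                        dsub, rsub, match, mismatch, gap, cap=None, with_alignment=False
                    )
                    closed.append((dgap, rgap, score))
                aligned = sum(b.read_span for b in piece) + sum(
                    r1 - r0 for _, (r0, r1), _ in closed
                )
                segments.append(
                    AlignmentSegment(
                        draft_id,
                        read_id,
                        strand,
                        piece,
                        closed,
                        read_len,
                        aligned / read_len if read_len else 0.0,
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# realignment-based edit-op counting (used by the simulator calibration)
# ---------------------------------------------------------------------------

def count_edit_ops(ref: str, alt: str, k: int = 13, stride: int = 2) -> dict[str, int]:
    """Count insertion/deletion/mismatch events of ``alt`` relative to ``ref``.

    Anchors ``alt`` on ``ref`` with maximal exact matches, chains them
    monotonically from the longest anchor under a diagonal-drift constraint,
    and scores the inter-anchor gaps (and the flanks) with Needleman-Wunsch,
    counting events from the tracebacks.
    """
    rc, ac = encode(ref), encode(alt)
    index, codes = _build_index({"r": ref}, k)
    raw = _scan(ac, index, codes, k, stride)
    # (t_id, qs, qe, ts, te) -> keep as (ts, te, qs, qe), sorted by ref pos
    blocks = sorted((ts, te, qs, qe) for _, qs, qe, ts, te in raw)
    chain: list[tuple[int, int, int, int]] = []
    if blocks:
        anchor = max(range(len(blocks)), key=lambda i: blocks[i][1] - blocks[i][0])
        chain = [blocks[anchor]]
        for ts, te, qs, qe in blocks[anchor + 1 :]:  # forward pass
            lts, lte, lqs, lqe = chain[-1]
            if qs < lqs or abs((ts - qs) - (lte - lqe)) > 200:
                continue
            t = max(lte - ts, lqe - qs, 0)
            if t >= te - ts or t >= qe - qs:
                continue
            chain.append((ts + t, te, qs + t, qe))
        head: list[tuple[int, int, int, int]] = []
        for ts, te, qs, qe in reversed(blocks[:anchor]):  # backward pass
            fts, fte, fqs, fqe = head[0] if head else chain[0]
            if qe > fqe or abs((ts - qs) - (fts - fqs)) > 200:
                continue
            t = max(te - fts, qe - fqs, 0)
            if t >= te - ts or t >= qe - qs:
                continue
            head.insert(0, (ts, te - t, qs, qe - t))
        chain = head + chain

    counts = {"ins": 0, "del": 0, "mis": 0, "match": 0}

    def add_gap(r0, r1, a0, a1):
        if r1 <= r0 and a1 <= a0:
            return
        _, (ar, aa) = needleman_wunsch(ref[r0:r1], alt[a0:a1], cap=None)
        for key, v in _count_pairwise_ops(ar, aa).items():
            counts[key] += v

    last_te, last_qe = 0, 0
    for ts, te, qs, qe in chain:
        add_gap(last_te, ts, last_qe, qs)
        counts["match"] += te - ts
        last_te, last_qe = te, qe
    add_gap(last_te, rc.size, last_qe, ac.size)
    return counts
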