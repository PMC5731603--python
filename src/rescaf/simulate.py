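"""Synthetic data generation: reference genomes, structurally corrupted draft
assemblies, and error-corrected long-read sets with truth annotations.

The corruption protocol mirrors the evaluation setup the pipeline is designed
for: the reference is cut ``N-1`` times at random points, the pieces are
shuffled and some reverse-complemented, and base-level noise (insertions,
deletions, mismatches) is applied per position. A :class:`TruthLayout` records
the provenance of every draft record so downstream results can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .io_utils import BASES, decode, encode, revcomp

# Defaults of the truncated lognormal read-length distribution, solved
# numerically so that the truncated distribution has mean 4070 bp and upper
# quartile 6231 bp (truncation bounds 100 / 15000 bp).
DEFAULT_LENGTH_LOG_MEAN = 8.6158184
DEFAULT_LENGTH_LOG_SD = 1.99989097
DEFAULT_MIN_LEN = 100
DEFAULT_MAX_LEN = 15000


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MutationConfig:
    """Parameters of the structural + base-level draft corruption."""

    n_pieces: int = 50
    min_piece_len: int = 10_000
    ins_rate: float = 0.02
    del_rate: float = 0.02
    mis_rate: float = 0.02
    shuffle_seed: int = 0
    revcomp_prob: float = 0.5

    def __post_init__(self):
        if self.n_pieces < 1:
            raise ValueError("n_pieces must be >= 1")
        if self.min_piece_len < 1:
            raise ValueError("min_piece_len must be >= 1")
        for name in ("ins_rate", "del_rate", "mis_rate", "revcomp_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValueError(f"{name} must be a finite fraction in [0,1]")
        if self.ins_rate + self.del_rate + self.mis_rate >= 1.0:
            raise ValueError("ins_rate + del_rate + mis_rate must be < 1")


@dataclass(frozen=True)
class LayoutEntry:
    """Provenance of one draft record: its source interval on the reference."""

    draft_id: str
    ref_id: str
    ref_start: int  # 0-based half-open
    ref_end: int
    strand: str  # '+' or '-'
    order_index: int


@dataclass
class TruthLayout:
    entries: list[LayoutEntry] = field(default_factory=list)

    def check_partition(self, ref_lengths: dict[str, int]) -> None:
        """Assert that source intervals partition each reference exactly."""
        by_ref: dict[str, list[tuple[int, int]]] = {}
        for e in self.entries:
            by_ref.setdefault(e.ref_id, []).append((e.ref_start, e.ref_end))
        for ref_id, ivals in by_ref.items():
            ivals.sort()
            if ivals[0][0] != 0 or ivals[-1][1] != ref_lengths[ref_id]:
                raise AssertionError(f"layout does not span reference {ref_id}")
            for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
                if e0 != s1:
                    raise AssertionError(f"layout gap/overlap at {e0}:{s1} on {ref_id}")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("draft_id\tref_id\tref_start\tref_end\tstrand\torder_index\n")
            for e in self.entries:
                fh.write(
                    f"{e.draft_id}\t{e.ref_id}\t{e.ref_start}\t{e.ref_end}"
                    f"\t{e.strand}\t{e.order_index}\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "TruthLayout":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("draft_id"):
                raise ValueError("malformed layout file: missing header")
            for line in fh:
                d, r, s, e, st, oi = line.rstrip("\n").split("\t")
                entries.append(LayoutEntry(d, r, int(s), int(e), st, int(oi)))
        return cls(entries)


@dataclass
class ReadSimConfig:
    """Parameters of the simulated error-corrected long-read set."""

    coverage: float = 25.0
    length_log_mean: float = DEFAULT_LENGTH_LOG_MEAN
    length_log_sd: float = DEFAULT_LENGTH_LOG_SD
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    residual_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if not (0.0 <= self.residual_error_rate <= 0.05):
            raise ValueError("residual_error_rate must be in [0, 0.05]")


def random_genome(length: int, seed=0) -> str:
    """Uniform random nucleotide sequence of the given length."""
    rng = _as_rng(seed)
    return decode(rng.integers(0, 4, length).astype(np.uint8))


def cut_genome(sequence: str, n_pieces: int, min_piece_len: int, seed=0) -> list[tuple[int, int]]:
    """Cut a sequence into ``n_pieces`` contiguous intervals.

    With ``m`` cuts remaining and ``L`` bases of uncut suffix, the next cut
    point is drawn uniformly from ``[min_piece_len, L // (m + 1)]`` measured
    from the left end of the suffix, so every resulting piece (including the
    final remainder) has at least ``min_piece_len`` bases.
    """
    L = len(sequence)
    if L < n_pieces * min_piece_len:
        raise ValueError(
            f"sequence of length {L} cannot be cut into {n_pieces} pieces "
            f"of at least {min_piece_len} bases"
        )
    rng = _as_rng(seed)
    intervals: list[tuple[int, int]] = []
    pos = 0
    remaining = L
    for m in range(n_pieces - 1, 0, -1):
        hi = remaining // (m + 1)
        cut = int(rng.integers(min_piece_len, hi, endpoint=True))
        intervals.append((pos, pos + cut))
        pos += cut
        remaining -= cut
    intervals.append((pos, L))
    return intervals


def corrupt_sequence(sequence: str, ins_rate: float, del_rate: float, mis_rate: float, rng) -> str:
    """Apply independent per-position corruption events.

    At each position at most one event occurs: a single random base is
    inserted before it (``ins_rate``), the base is deleted (``del_rate``), or
    substituted with a different base (``mis_rate``).
    """
    rng = _as_rng(rng)
    codes = encode(sequence)
    n = codes.size
    if n == 0:
        return ""
    u = rng.random(n)
    out = codes.copy()

    sub = (u >= ins_rate + del_rate) & (u < ins_rate + del_rate + mis_rate)
    n_sub = int(sub.sum())
    if n_sub:
        out[sub] = (out[sub] + rng.integers(1, 4, n_sub).astype(np.uint8)) % 4

    keep = ~((u >= ins_rate) & (u < ins_rate + del_rate))
    kept = out[keep]

    ins = u < ins_rate
    n_ins = int(ins.sum())
    if n_ins:
        kept_index = np.cumsum(keep) - 1  # index of each surviving base in `kept`
        where = kept_index[ins]
        kept = np.insert(kept, where, rng.integers(0, 4, n_ins).astype(np.uint8))
    return decode(kept)


def mutate_assembly(
    sequence: str, config: MutationConfig, ref_id: str = "ref"
) -> tuple[dict[str, str], TruthLayout]:
    """Produce a structurally corrupted draft assembly plus its truth layout.

    The reference is cut, the pieces are permuted uniformly at random, each is
    independently reverse-complemented with ``revcomp_prob``, and base-level
    noise is applied. Deterministic given ``config.shuffle_seed``.
    """
    if not sequence:
        raise ValueError("reference sequence is empty")
    rng = np.random.default_rng(config.shuffle_seed)
    intervals = cut_genome(sequence, config.n_pieces, config.min_piece_len, rng)
    perm = rng.permutation(config.n_pieces)
    draft: dict[str, str] = {}
    layout = TruthLayout()
    for order_index, piece_idx in enumerate(perm):
        start, end = intervals[piece_idx]
        piece = sequence[start:end]
        strand = "-" if rng.random() < config.revcomp_prob else "+"
        if strand == "-":
            piece = revcomp(piece)
        piece = corrupt_sequence(piece, config.ins_rate, config.del_rate, config.mis_rate, rng)
        draft_id = f"piece_{order_index:04d}"
        draft[draft_id] = piece
        layout.entries.append(
            LayoutEntry(draft_id, ref_id, int(start), int(end), strand, order_index)
        )
    return draft, layout


def sample_read_lengths(n: int, config: ReadSimConfig, rng) -> np.ndarray:
    """Draw ``n`` read lengths from the doubly truncated lognormal."""
    rng = _as_rng(rng)
    mu, sd = config.length_log_mean, config.length_log_sd
    lo = ndtr((np.log(config.min_len) - mu) / sd)
    hi = ndtr((np.log(config.max_len) - mu) / sd)
    u = rng.uniform(lo, hi, n)
    lengths = np.rint(np.exp(mu + sd * ndtri(u))).astype(np.int64)
    return np.clip(lengths, config.min_len, config.max_len)


def simulate_reads(
    sequence: str, config: ReadSimConfig, ref_id: str = "ref"
) -> tuple[dict[str, str], list[tuple[str, str, int, int, str]]]:
    """Simulate error-corrected long reads from a reference sequence.

    Reads have uniformly random start positions and truncated-lognormal
    lengths (clipped at the sequence end), are reverse-complemented with
    probability 0.5, and carry ``residual_error_rate`` corruption split
    equally across insertions, deletions and mismatches. Returns the reads
    plus truth tuples ``(read_id, ref_id, start, end, strand)``.
    """
    L = len(sequence)
    if L < config.min_len:
        raise ValueError(f"reference length {L} is shorter than min_len {config.min_len}")
    rng = np.random.default_rng(config.seed)
    target = config.coverage * L
    per_event = config.residual_error_rate / 3.0
    reads: dict[str, str] = {}
    truth: list[tuple[str, str, int, int, str]] = []
    total = 0
    idx = 0
    while total < target:
        batch = max(16, int((target - total) / max(config.min_len, 1) / 8))
        lengths = sample_read_lengths(batch, config, rng)
        starts = rng.integers(0, L - config.min_len + 1, batch)
        strands = rng.random(batch) < 0.5
        for ln, st, neg in zip(lengths, starts, strands):
            end = min(int(st + ln), L)
            frag = sequence[st:end]
            strand = "-" if neg else "+"
            if neg:
                frag = revcomp(frag)
            if config.residual_error_rate > 0:
                frag = corrupt_sequence(frag, per_event, per_event, per_event, rng)
            read_id = f"read_{idx:06d}"
            reads[read_id] = frag
            truth.append((read_id, ref_id, int(st), end, strand))
            idx += 1
            total += end - int(st)
            if total >= target:
                break
    return reads, truth


def measure_corruption_rates(
    reference: str, draft: dict[str, str], layout: TruthLayout
) -> dict[str, float]:
    """Realign every draft piece to its source interval and measure realized
    per-reference-base insertion, deletion and mismatch rates."""
    from .align_model import count_edit_ops

    totals = {"ins": 0, "del": 0, "mis": 0}
    ref_bases = 0
    for e in layout.entries:
        src = reference[e.ref_start : e.ref_end]
        if e.strand == "-":
            src = revcomp(src)
        counts = count_edit_ops(src, draft[e.draft_id])
        for k in totals:
            totals[k] += counts[k]
        ref_bases += len(src)
    return {k: v / ref_bases for k, v in totals.items()}
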