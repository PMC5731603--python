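import numpy as np
import pytest

from rescaf.align_model import AlignedBlock, AlignmentSegment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blocks(coords, draft_id="d", read_id="r", strand="+", identity=1.0):
    """Build AlignedBlocks from (DL, DR, RL, RR) tuples."""
    return [
        AlignedBlock(draft_id, read_id, dl, dr, rl, rr, strand, identity)
        for dl, dr, rl, rr in coords
    ]


def make_segment(coords, read_len, strand="+", draft_id="d", read_id="r", identity=1.0):
    """AlignmentSegment straight from block coordinates (no gap closing)."""
    blocks = make_blocks(coords, draft_id, read_id, strand, identity)
    aligned = sum(b.read_span for b in blocks)
    return AlignmentSegment(
        draft_id, read_id, strand, blocks, [], read_len, aligned / read_len
    )
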