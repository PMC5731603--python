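# rescaf

Disassemble–reassemble correction and scaffolding of draft genome assemblies
guided by error-corrected single-molecule long reads.

The pipeline has two stages:

1. **Disassemble.** Long-read-to-draft alignments (aligned-block tables in the
   `show-coords -T -l` column order, or blocks from the built-in exact-match
   aligner) are trimmed, gap-closed with Needleman–Wunsch, and filtered by
   three criteria: consecutive-block gap agreement (|g1−g2| ≤ 30), aligned
   read fraction (> 0.99), and a merge overlap threshold (δ = 50). Surviving
   draft intervals are extracted verbatim or as a read consensus — these are
   the structurally validated segments.
2. **Reassemble.** Every segment becomes two vertices (tail/head) joined by a
   weight-0 dashed edge; reads bridging two segment ends contribute solid
   edges weighted by supporting-read count. Scaffolding is a maximum weighted
   alternating path cover over this graph, solved with a matching-based
   2-approximation (maximum weight matching over solid edges, add dashed
   edges, break each cycle by deleting its lightest solid edge; an iterative
   re-matching variant is available). Inter-segment gaps are filled with the
   bridging read's junction subsequence; negative junction distances trim the
   downstream segment instead.

A simulation module generates random references, structurally corrupted
drafts (random cuts, shuffling, reverse complements, per-base
insertion/deletion/mismatch noise) and error-corrected long reads with truth
annotations, so everything is testable offline. An exact brute-force cover
solver and a Hamiltonian-path reduction generator back the approximation
guarantees in the test suite.

## CLI

```sh
# simulate a 500 kb reference, a 10-piece shuffled/flipped draft, 25x reads
rescaf simulate --genome-len 500000 --n-pieces 10 --ins 0 --del 0 --mis 0 \
    --coverage 25 --read-error 0 --seed 1 --outdir sim/

# full pipeline (alignments computed by the built-in aligner when --coords
# is omitted), with evaluation against the simulation truth
rescaf run --draft sim/draft.fasta --reads sim/reads.fasta \
    --truth sim/layout.tsv --outdir out/

# disassembly only: validated segments as FASTA + BED
rescaf disassemble --draft sim/draft.fasta --reads sim/reads.fasta \
    --out-prefix segments

# score an existing scaffold layout
rescaf eval --scaffold-paths out/scaffolds.paths.tsv \
    --segments-bed segments.bed --truth sim/layout.tsv
```

`rescaf run` writes `scaffolds.fasta`, an AGP v2.1 layout with a joins
sidecar TSV, the scaffold graph as an edge list and GraphViz DOT, and (with
`--truth`) an evaluation TSV with N50, adjacency precision/recall and
orientation accuracy.

External aligner output is accepted with `--coords FILE` (tab-separated,
columns `S1 E1 S2 E2 LEN1 LEN2 %IDY REF_ID QRY_ID`, 1-based inclusive,
reverse-strand rows with start > end on the read side).

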