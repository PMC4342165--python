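# trackview

A headless, scriptable genomic-data track viewer. It loads the standard
region-indexed track formats — coordinate-sorted BAM alignments, BED
features, WIG/bedGraph (and BIGWIG) signal, SEG segmented copy number —
computes pileup coverage with mismatch highlighting, thins the displayed
reads by windowed reservoir sampling *without ever distorting the coverage
chart*, and renders stacked tracks deterministically to SVG (or PNG). Views
are shareable as compact launch links encoding genome + locus + datasets.

It is aimed at pipelines and papers rather than mice and touchscreens:
anywhere you would screenshot a genome browser, `trackview` gives you a
reproducible, diffable figure from a one-line command or a few library
calls.

## What it computes

**Pileup.** For a viewed interval, every overlapping read is decomposed into
aligned blocks by its CIGAR string. Each aligned base increments a per-column
count for its base; deletion gaps (`D`) increment a deletion count; spliced
gaps (`N`) contribute nothing (they are drawn as a thin connector line, not
coverage). Column depth is the sum of base counts plus deletions. A column is
highlighted when its mismatch fraction — non-reference A/C/G/T bases over
depth — reaches a threshold (default 0.2) at sufficient depth.

**Downsampling.** The view is split into windows of `w` bp (default 50);
each read belongs to the window containing its start. A window holding
`n > k` reads keeps a seeded reservoir of `k` (default 100) via Algorithm R,
so every read is retained with probability exactly `k/n`. Crucially the
coverage chart is computed from **all** reads *before* any are discarded, so
it always shows true depth.

**Read stacking.** Start-sorted reads are packed into display rows by greedy
first-fit; with zero gap this left-endpoint colouring of the interval graph
is optimal — the row count equals the maximum overlap depth.

**Multi-resolution signal.** Numeric tracks can be pre-binned into a
power-of-two pyramid (`.tss`, tiled signal store) of
(mean, min, max, count) bins, so any viewport is answered with a bounded
number of bins at the right zoom level; parent bins are exact count-weighted
aggregates of their two children.

**Copy number.** SEG segments draw as red/blue heatmap cells — hue by sign
of the log2 ratio, intensity saturating at |value| = 1.5 — and samples can
be sorted by the length-weighted mean value in the viewed region
(strongest deletion first, or strongest amplification first).

## Worked example

Everything below runs offline on a bundled synthetic dataset: a two-
chromosome toy genome at ~30× read depth with a planted 30% allele-fraction
SNV at chrA:5,001, a spliced junction, a stepped signal profile, and a
5-sample copy-number design.

```sh
trackview fixtures --out demo --seed 1
cd demo
trackview render --fasta toy1.fa --features genes.bed --session session.json --out view.svg
trackview pileup reads.bam toy1.fa "chrA:4,996-5,005"
```

The pileup prints one row per reference position (1-based), with depth and
base composition:

```
pos	depth	A	C	G	T	N	del
4996	35	0	0	0	35	0	0
...
5001	36	0	0	25	11	0	0
...
5005	38	38	0	0	0	0	0
```

At position 5,001 the planted variant is visible: 11 of 36 reads (31%)
carry T against the G reference, so the rendered coverage chart splits that
bar into a 25:11 stacked colour pair, and the SVG shows the variant bases
highlighted inside the grey read bars. Every other column is unanimous.

The view you just rendered is also shareable as a link:

```sh
trackview link session.json
# trackview://launch?genome=toy1&locus=chrA:4,801-5,200&file=reads.bam,genes.bed,signal.bedgraph,cn.seg&name=reads,genes,signal,copy%20number
```

Rendering from that link (`trackview render --link "..."`) produces the
byte-identical SVG — determinism is part of the output contract.

## Library use

```python
from trackview import (AlignmentSource, GenomeModel, GenomicInterval,
                       compute_pileup, fetch_reference, mark_mismatches,
                       read_alignments)

genome = GenomeModel.from_fasta("demo/toy1.fa")
region = GenomicInterval("chrA", 4_900, 5_100)
reads = read_alignments(AlignmentSource("demo/reads.bam"), region)
ref = fetch_reference(region, genome)
cov = compute_pileup(reads, region, ref)
for mark in mark_mismatches(cov, ref, min_fraction=0.2):
    print(mark.position + 1, round(mark.total_mismatch_fraction, 3), mark.fractions)
# 5001 0.306 {'T': 0.3055555555555556}
```

## Documentation

`docs/methods.md` describes the models, parameter defaults, file-format
conventions, and the synthetic data generator in detail.
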