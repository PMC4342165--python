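# Methods

This note documents the data model, the algorithms, the parameter defaults
and the deliberate design choices behind `trackview`, and what the synthetic
test data do and do not establish about behaviour on real data.

## Coordinates

Internally every interval is 0-based half-open (`[start, end)`), the BAM/BED
convention; all conversions happen at the I/O boundary, once:

| surface | convention |
|---|---|
| BED, bedGraph | 0-based half-open (unchanged) |
| WIG | 1-based with `span`; converted on read |
| SEG | 1-based inclusive; converted on read/write |
| locus strings ("chrA:1,001-2,000") | 1-based inclusive, commas permitted |

Locus parsing accepts `chrom:start-end`, `chrom:pos` (a 41-base window
centred on the queried base — odd width so the base sits exactly in the
middle; configurable), bare `chrom` (whole chromosome), and otherwise falls
through to case-insensitive feature-name lookup. When several features share
a name, the result is the union span on the chromosome of the first match in
file order — deterministic without interactive disambiguation. Chromosome
name matching is exact; an explicit alias table may be supplied, but no
silent "chr" prefix fuzzing is done, because silent aliasing causes
coordinate bugs. Out-of-range loci are clamped to chromosome bounds;
clamping is idempotent and never widens.

The SEG format has no published coordinate convention; 1-based inclusive is
this package's documented choice (it matches how the common segmentation
tools emit the format).

## Pileup and mismatch marking

Reads are decomposed into reference-tiling blocks from their CIGAR:
`M/=/X` → aligned, `N` → splice gap, `D` → deletion gap; `I/S` consume query
only and emit no block. `=`/`X` are deliberately collapsed into plain
aligned blocks: mismatches are always recomputed against the reference, so
rendering does not depend on which aligner produced the file. Depth at a
column is (aligned base count) + (deletion count); splice gaps contribute
nothing, because an intron under an RNA read is not covered sequence.
Insertions are counted in no column — depth is reference-anchored.

A column is marked as a mismatch locus when depth ≥ `min_depth` (default 1)
and the mismatch fraction ≥ `min_fraction` (default 0.2). The mismatch
fraction is the share of depth carried by non-reference A/C/G/T bases. `N`
in the read or the reference never counts (an unknown base is not
evidence), and deletion gaps are not counted as base mismatches — they are
rendered as gaps. The 0.2 default is a policy choice, exposed in
configuration; marking is monotone in the threshold by construction.
Duplicate-flagged reads are kept (only unmapped and vendor-failed reads are
excluded); a stricter filter is configuration, not a default.

## Downsampling

The displayed read set is thinned per window: the view is partitioned into
consecutive `window_bp` windows (default 50 bp) and each read is assigned to
the window containing its start, so every read is sampled exactly once
rather than once per overlapped window. Windows at or under
`max_reads_per_window` (default 100) keep everything; above it, reservoir
sampling (Algorithm R) keeps exactly `k` reads with uniform inclusion
probability `k/n`. The per-window RNG is seeded with the string
`"{seed}|{window_index}"` — string seeding hashes through SHA-512, which is
platform-stable, so a fixed (input order, seed) always retains the same set.

The coverage chart is computed from **all** overlapping reads *before*
downsampling. This ordering is a contract, not an optimisation detail: the
chart must show true depth however aggressively the displayed reads are
thinned, and a dedicated check asserts byte-level equality of the coverage
export with an independent brute-force counting oracle while the display is
capped at 5 reads per window.

## Read stacking and base-sorting

Rows are assigned by greedy first-fit over start-sorted reads: each read
takes the lowest row whose last occupied end plus `min_gap_bp` does not pass
the read's start. With zero gap this is left-endpoint greedy colouring of an
interval graph, which is optimal — row count equals maximum overlap depth —
and that optimality is oracle-checked against a per-point depth scan.

Sorting reads at a column (SNP inspection) is a stable sort with key order:
non-reference bases first, grouped by descending count of that base at the
column (alphabetical on ties), then reference-base reads, then deletions,
then reads not covering the position (including reads spliced over it).

## Multi-resolution signal store

Raw signal is aggregated into a power-of-two pyramid: level 0 bins are
`base_bin_width` wide (default 10 bp), level *i* bins `2^i` times that. Each
bin stores (mass, count, min, max) where mass = Σ value × covered-bases and
count = covered bases; the mean is mass/count. Parents are exact pairwise
sums of children, so Σ(mean × count) is conserved across levels to floating
round-off and the parent/child invariants are testable equalities rather
than approximations — the reason a power-of-two hierarchy was chosen over a
fixed-bins-per-level scheme. A count of zero marks an *empty* bin (absence
of data, distinct from a measured zero); empty bins are never returned by
queries and never drawn.

A query picks the coarsest level whose bin width ≤ span/`max_points`,
falling back to the finest, so render cost is bounded regardless of region
size and the level choice is monotone in `max_points`. The on-disk container
(`.tss`) is a little-endian header (magic, version, genome id, geometry)
followed by dense per-chromosome, per-level arrays; floats round-trip
bit-exactly. BIGWIG files are read through pyBigWig when present; the
package never writes BIGWIG.

## Track layout and rendering

Layout functions are pure: (data, viewport, config) → glyph list, with the
affine genomic→pixel map `x(p) = (p − start) / bases_per_pixel`. Glyphs
carry *style roles* (read_body, mismatch_base_G, splice_connector,
coverage_bar, …) rather than colours; one theme table in the renderer
resolves roles, so a backend can restyle everything in one place. The
copy-number cell is the exception — its colour is data (computed from the
segment value) and rides in the glyph payload.

Defaults and their reasons:

- **Visibility threshold 30,000 bp.** Read-level data are fetched only when
  the viewport span is at or under the threshold; reads are tens of bases
  long, so a tens-of-kb window is where individual reads become
  distinguishable. Above it the alignment track emits a "zoom in to see
  reads" label and performs zero source fetches, observable through a fetch
  counter on the alignment handle.
- **Quality→opacity `q_lo=5, q_hi=20, min_opacity=0.1`.** Mismatch glyph
  opacity ramps linearly between the Phred bounds; the floor keeps even
  poor calls visible.
- **Coverage aggregation by max.** When several bases share a pixel the
  column takes the maximum depth — preserving peaks, the standard browser
  behaviour; a mean would flatten exactly the features one zooms out to
  find. At marked loci the bar splits into stacked portions proportional to
  each base's share of the marked column's depth.
- **Numeric autoscale.** `[0, max]` for non-negative data, symmetric
  `[−m, m]` otherwise (negative bars hang below the baseline); a fixed range
  can be configured per track.
- **Copy-number scale cap 1.5 log2 units**, white neutral, pure red
  positive / pure blue negative. Pure hues are equidistant from white, so
  colour intensity is exactly odd-symmetric in the value. Sample sorting
  scores each sample by the length-weighted mean of its segments intersected
  with the region (no overlap scores 0); deletion sorts ascending,
  amplification descending, ties alphabetical.
- **Mismatch base colours** follow the conventional A-green / C-blue /
  G-orange / T-red assignment, as restylable tokens.

The scene serializer formats every coordinate with fixed 2-decimal
precision, so identical scenes give byte-identical SVG on any platform;
element order equals glyph order. Glyphs are clipped to their panel at
composition. The ruler places ticks on a 1/2/5 × 10^k ladder, choosing the
smallest spacing that keeps ticks ≥ 70 px apart. PNG output rasterizes the
same glyphs through Pillow (text is skipped in raster output, which has no
fixed-metrics font); its absence degrades to a capability error.

## Sessions and links

A launch link's query string carries `genome`, `locus`, `file`
(comma-separated, order defines track order) and `name` (position-paired
with `file`); values are percent-encoded per element, and list splitting
happens before decoding so commas inside names survive. The grammar is this
package's own, versioned here; serialization emits keys in fixed order so
parse ∘ serialize is the identity on canonical sessions. A JSON session file
carries the display options a compact link omits. Track types are inferred
from extensions (`.bam`→alignment+coverage, `.bed`→feature,
`.wig/.bedgraph/.tss/.bw`→numeric, `.seg`→segment) unless overridden, and a
failure in one track renders as an error panel without aborting the rest.
Remote URLs go through the same reader interface as local paths; transport
is not logic.

## Synthetic data generator

The generator emulates the structures the viewer exists to show: a uniform
random genome (default 20 kb + 8 kb; the test suite and acceptance script
use a 3 kb + 1.2 kb scaling at 50× depth to keep runs in seconds), plain
reads copied exactly from the reference at ~30–50× depth with a two-level
base-quality model (Phred 30 with probability 0.9, else 12), planted SNVs
whose alternate-base fraction among covering reads is exact to within one
read, a spliced junction with a stated number of M-N-M supporting reads, an
exact piecewise-constant signal, and a copy-number design whose sample S3
carries the strongest deletion. All randomness flows through one seeded
generator; outputs are byte-reproducible across platforms. Read names
encode their origin and planted events, so fixtures are self-validating.

What the fixtures deliberately lack: sequencing error, indel and soft-clip
noise, duplicate and fragment-size structure, mapping-quality variation,
and reference ambiguity. Passing tests therefore establish the *counting,
sampling and rendering semantics* — not robustness to noisy alignments.
On real data the same code paths run, but mismatch marking at the default
0.2 threshold will also flag systematic error sites, and packing/downsampling
behaviour depends on the real read-length and depth distributions.

## Numerical and degenerate-input choices

- Interval invariants (`0 ≤ start < end`) are enforced at construction;
  zero-length intervals are rejected everywhere.
- Unknown chromosomes in region queries yield empty results, not errors;
  unknown chromosomes in locus text fall through to feature search and then
  to a locus-not-found error naming the query.
- Reservoir and packing require start-sorted input and fail loudly
  (contract error) otherwise, rather than silently resorting.
- An all-zero coverage or empty numeric track draws nothing rather than a
  zero-height frame; autoscale over an all-zero track uses a unit range to
  avoid division by zero.
- Bases outside {A,C,G,T,N} in reads tally as N.
- Truncated or wrong-magic tile stores raise format errors; a version bump
  raises a distinct version error.

## Known limitations

Paired-end arcs, read-group colouring, insertion glyph detail, ideogram
banding and interactive hit-testing are out of scope. CRAM and VCF are not
read. BED parsing is plain (no tabix), adequate at desk scale. The SVG text
metrics use a fixed per-character width estimate, so label fitting is
approximate.
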