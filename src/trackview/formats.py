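"""Readers and writers for the supported track file types.

Alignments (SAM/BAM) go through pysam with region-windowed indexed access;
BED, WIG, bedGraph and SEG are small line-oriented dialects parsed here with
explicit coordinate conventions:

============  =======================  =========================
format        on-disk convention       converted to (internal)
============  =======================  =========================
BED/bedGraph  0-based half-open        unchanged
WIG           1-based, span attribute  0-based half-open
SEG           1-based inclusive        0-based half-open
SAM/BAM       1-based (text)           0-based half-open (pysam)
============  =======================  =========================

All coordinate conversions happen at this I/O boundary only.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .errors import (
    ContractError,
    IndexRequiredError,
    ParseError,
    SchemaError,
    TrackViewError,
)
from .genome import GenomicInterval

# CIGAR operations, by the classes of sequence they consume.
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")
CIGAR_OPS = "MIDNSHP=X"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read: position, CIGAR, bases and qualities.

    ``cigar`` is a tuple of ``(op, length)`` with op one of ``MIDNSHP=X``;
    query-consuming lengths must sum to ``len(bases) == len(quals)``.
    """

    name: str
    chrom: str
    start: int  # 0-based leftmost reference position
    strand: str  # '+' or '-'
    cigar: tuple
    bases: str
    quals: tuple
    mapping_quality: int = 0
    flags: int = 0

    def __post_init__(self):
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
        if qlen != len(self.bases) or len(self.bases) != len(self.quals):
            raise ContractError(
                f"read {self.name!r}: CIGAR query length {qlen} != "
                f"|bases| {len(self.bases)} or |quals| {len(self.quals)}"
            )

    @property
    def end(self) -> int:
        """One past the last reference base this read aligns to."""
        return self.start + sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class AlignedBlock:
    """One piece of a read's alignment on the reference.

    ``aligned`` blocks carry read bases; ``splice_gap`` (CIGAR N) and
    ``deletion_gap`` (CIGAR D) consume reference only, so their query span
    is empty.
    """

    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    kind: str  # 'aligned' | 'splice_gap' | 'deletion_gap'


@dataclass(frozen=True)
class Feature:
    """A named annotation (BED record)."""

    interval: GenomicInterval
    name: str = ""
    score: Optional[float] = None
    strand: Optional[str] = None


@dataclass(frozen=True)
class SignalInterval:
    """A constant signal value over an interval (WIG/bedGraph datum)."""

    interval: GenomicInterval
    value: float


@dataclass(frozen=True)
class Segment:
    """One sample's segmented copy-number value (SEG row, log2 ratio)."""

    sample: str
    interval: GenomicInterval
    value: float


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------


def parse_cigar(text: str) -> tuple:
    """Parse a CIGAR string into ``((op, length), ...)``."""
    if not text or text == "*":
        raise ParseError(f"empty CIGAR {text!r}")
    out = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ParseError(f"malformed CIGAR {text!r} at offset {pos}")
        out.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text):
        raise ParseError(f"malformed CIGAR {text!r} at offset {pos}")
    return tuple(out)


def cigar_to_blocks(read: AlignedRead) -> list[AlignedBlock]:
    """Decompose a read into reference-tiling blocks.

    M/=/X runs become ``aligned`` blocks (= and X are treated as M:
    mismatches are always recomputed against the reference, so the aligner's
    own match/mismatch distinction is ignored). N runs become ``splice_gap``,
    D runs ``deletion_gap``. I and S consume query only and emit no block.
    The blocks tile ``[read.start, read.end)`` exactly.
    """
    blocks: list[AlignedBlock] = []
    ref = read.start
    query = 0
    for op, n in read.cigar:
        if op in "M=X":
            blocks.append(AlignedBlock(ref, ref + n, query, query + n, "aligned"))
            ref += n
            query += n
        elif op == "N":
            blocks.append(AlignedBlock(ref, ref + n, query, query, "splice_gap"))
            ref += n
        elif op == "D":
            blocks.append(AlignedBlock(ref, ref + n, query, query, "deletion_gap"))
            ref += n
        elif op in "IS":
            query += n
        elif op in "HP":
            pass
        else:  # pragma: no cover - parse_cigar rejects these
            raise ParseError(f"unknown CIGAR op {op!r}")
    # merge adjacent aligned runs (e.g. "5M5M") so block lists are canonical
    merged: list[AlignedBlock] = []
    for b in blocks:
        if (
            merged
            and b.kind == "aligned"
            and merged[-1].kind == "aligned"
            and merged[-1].ref_end == b.ref_start
            and merged[-1].query_end == b.query_start
        ):
            prev = merged.pop()
            b = AlignedBlock(prev.ref_start, b.ref_end, prev.query_start, b.query_end, "aligned")
        merged.append(b)
    return merged


def cigar_to_string(cigar: Sequence) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


# ---------------------------------------------------------------------------
# alignments (SAM/BAM via pysam)
# ---------------------------------------------------------------------------


class AlignmentSource:
    """Handle on a coordinate-sorted, indexed SAM/BAM file.

    Carries a ``fetch_count`` so callers (and tests) can observe that the
    zoom-visibility gate really performs zero source reads when the view is
    too wide.
    """

    def __init__(self, path):
        import pysam

        self.path = str(path)
        mode = "rb" if self.path.endswith(".bam") else "r"
        self._file = pysam.AlignmentFile(self.path, mode)
        self.fetch_count = 0

    @property
    def references(self) -> tuple:
        return tuple(self._file.references)

    def fetch(self, region: GenomicInterval) -> Iterator[AlignedRead]:
        self.fetch_count += 1
        if region.chrom not in self._file.references:
            return
        try:
            it = self._file.fetch(region.chrom, region.start, region.end)
        except ValueError as exc:
            raise IndexRequiredError(
                f"{self.path}: region query requires a coordinate index ({exc})"
            ) from None
        for seg in it:
            if seg.is_unmapped or seg.is_qcfail:
                continue
            yield _from_pysam(seg)

    def scan(self) -> Iterator[AlignedRead]:
        """Sequential full scan (no index needed); does not count as a
        region fetch."""
        for seg in self._file.fetch(until_eof=True):
            if seg.is_unmapped or seg.is_qcfail:
                continue
            yield _from_pysam(seg)

    def close(self) -> None:
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _from_pysam(seg) -> AlignedRead:
    cigar = tuple((CIGAR_OPS[op], n) for op, n in seg.cigartuples)
    quals = seg.query_qualities
    return AlignedRead(
        name=seg.query_name,
        chrom=seg.reference_name,
        start=seg.reference_start,
        strand="-" if seg.is_reverse else "+",
        cigar=cigar,
        bases=(seg.query_sequence or "").upper(),
        quals=tuple(quals) if quals is not None else (0,) * len(seg.query_sequence or ""),
        mapping_quality=seg.mapping_quality,
        flags=seg.flag,
    )


def read_alignments(
    source: AlignmentSource, region: GenomicInterval
) -> list[AlignedRead]:
    """Reads whose reference span overlaps *region*, in start order.

    Unmapped and vendor-failed (QC-fail) reads are excluded; an unknown
    chromosome yields an empty result, not an error.
    """
    reads = list(source.fetch(region))
    reads.sort(key=lambda r: r.start)
    return reads


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _open_lines(source):
    if hasattr(source, "read"):
        return source.read().splitlines()
    with open(source) as fh:
        return fh.read().splitlines()


def read_features(source, region: Optional[GenomicInterval] = None) -> list[Feature]:
    """Parse BED (0-based half-open; track/browser/comment lines skipped).

    Features come back sorted by (chromosome file order, start); *region*,
    when given, keeps only overlapping features.
    """
    feats: list[Feature] = []
    chrom_order: dict[str, int] = {}
    for lineno, line in enumerate(_open_lines(source), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(("track", "browser", "#")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise ParseError(f"BED record needs >= 3 columns, got {len(cols)}", lineno)
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(f"non-integer BED coordinates {cols[1]!r}/{cols[2]!r}", lineno) from None
        if start >= end or start < 0:
            raise ParseError(f"invalid BED span [{start}, {end})", lineno)
        name = cols[3] if len(cols) > 3 else ""
        score: Optional[float] = None
        if len(cols) > 4 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError:
                raise ParseError(f"non-numeric BED score {cols[4]!r}", lineno) from None
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-." else None
        chrom_order.setdefault(chrom, len(chrom_order))
        feats.append(Feature(GenomicInterval(chrom, start, end), name, score, strand))
    feats.sort(key=lambda f: (chrom_order[f.interval.chrom], f.interval.start, f.interval.end))
    if region is not None:
        feats = [f for f in feats if f.interval.overlaps(region)]
    return feats


def write_bed(features: Iterable[Feature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            cols = [f.interval.chrom, str(f.interval.start), str(f.interval.end)]
            if f.name or f.score is not None or f.strand is not None:
                cols.append(f.name or ".")
            if f.score is not None or f.strand is not None:
                cols.append(_num(f.score) if f.score is not None else "0")
            if f.strand is not None:
                cols.append(f.strand)
            fh.write("\t".join(cols) + "\n")


def _num(x: float) -> str:
    """Shortest exact-ish decimal: ints print as ints."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------------------
# WIG / bedGraph
# ---------------------------------------------------------------------------


def read_signal(source) -> list[SignalInterval]:
    """Parse WIG (fixedStep/variableStep, 1-based, span honoured) or bedGraph
    (0-based half-open); the dialect is auto-detected from the header.

    BIGWIG files are routed to pybigwig when the path ends in .bw/.bigwig.
    Output is sorted by (chrom, start).
    """
    if isinstance(source, (str, os.PathLike)) and str(source).lower().endswith(
        (".bw", ".bigwig")
    ):
        return _read_bigwig(str(source))
    out: list[SignalInterval] = []
    mode = None  # 'fixed' | 'variable' | 'bedgraph'
    chrom = ""
    step = span = 1
    cur = 0  # next 1-based start for fixedStep
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("track"):
            continue
        if line.startswith(("fixedStep", "variableStep")):
            kw = dict(
                part.split("=", 1) for part in line.split()[1:] if "=" in part
            )
            chrom = kw.get("chrom", "")
            if not chrom:
                raise ParseError("step declaration missing chrom=", lineno)
            span = int(kw.get("span", 1))
            if line.startswith("fixedStep"):
                mode = "fixed"
                try:
                    cur = int(kw["start"])
                except KeyError:
                    raise ParseError("fixedStep missing start=", lineno) from None
                step = int(kw.get("step", 1))
            else:
                mode = "variable"
            continue
        fields = line.split()
        if mode is None:
            if len(fields) == 4:
                mode = "bedgraph"
            else:
                raise ParseError(f"unknown signal header keyword {fields[0]!r}", lineno)
        if mode == "bedgraph":
            if len(fields) != 4:
                raise ParseError("bedGraph rows need 4 columns", lineno)
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError("malformed bedGraph row", lineno) from None
            out.append(SignalInterval(GenomicInterval(fields[0], s, e), v))
        elif mode == "fixed":
            try:
                v = float(fields[0])
            except ValueError:
                raise ParseError("malformed fixedStep value", lineno) from None
            out.append(SignalInterval(GenomicInterval(chrom, cur - 1, cur - 1 + span), v))
            cur += step
        else:  # variable
            if len(fields) != 2:
                raise ParseError("variableStep rows need position and value", lineno)
            try:
                pos, v = int(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError("malformed variableStep row", lineno) from None
            out.append(SignalInterval(GenomicInterval(chrom, pos - 1, pos - 1 + span), v))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return out


def _read_bigwig(path: str) -> list[SignalInterval]:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise TrackViewError(f"BIGWIG support requires pyBigWig: {exc}") from None
    out = []
    with pyBigWig.open(path) as bw:
        for chrom in sorted(bw.chroms()):
            for s, e, v in bw.intervals(chrom) or []:
                out.append(SignalInterval(GenomicInterval(chrom, s, e), float(v)))
    return out


def write_bedgraph(signal: Iterable[SignalInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("track type=bedGraph\n")
        for s in signal:
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t{_num(s.value)}\n"
            )


def write_wig(signal: Iterable[SignalInterval], path) -> None:
    """Write as variableStep WIG; a new declaration starts whenever the
    chromosome or the interval span changes."""
    with open(path, "w") as fh:
        cur = (None, None)
        for s in signal:
            key = (s.interval.chrom, s.interval.span)
            if key != cur:
                fh.write(f"variableStep chrom={s.interval.chrom} span={s.interval.span}\n")
                cur = key
            fh.write(f"{s.interval.start + 1}\t{_num(s.value)}\n")


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_HEADER = "ID\tchrom\tloc.start\tloc.end\tseg.mean"


def read_segments(source) -> list[Segment]:
    """Parse SEG: tab-separated with a header row, columns
    sample / chrom / start / end / value (value = last column; an optional
    marker-count column in between is ignored). Coordinates are 1-based
    inclusive on disk.
    """
    lines = [l for l in _open_lines(source) if l.strip() and not l.startswith("#")]
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 5:
        raise SchemaError(
            f"SEG needs >= 5 tab-separated columns (sample/chrom/start/end/value), got {len(header)}"
        )
    out: list[Segment] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise ParseError(f"SEG row has {len(cols)} columns, need >= 5", lineno)
        try:
            start1, end1 = int(cols[2]), int(cols[3])
            value = float(cols[-1])
        except ValueError:
            raise ParseError("malformed SEG row (non-numeric field)", lineno) from None
        out.append(Segment(cols[0], GenomicInterval(cols[1], start1 - 1, end1), value))
    return out


def write_seg(segments: Iterable[Segment], path) -> None:
    with open(path, "w") as fh:
        fh.write(_SEG_HEADER + "\n")
        for s in segments:
            fh.write(
                f"{s.sample}\t{s.interval.chrom}\t{s.interval.start + 1}"
                f"\t{s.interval.end}\t{_num(s.value)}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / SAM writers + fixture round-trip surface
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    """Write sequences and create the .fai index."""
    import pysam

    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    pysam.faidx(str(path))


def write_sam(reads: Sequence[AlignedRead], chrom_lengths: dict, path) -> None:
    """Write coordinate-sorted SAM with proper @SQ headers."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
    }
    ordered = sorted(reads, key=lambda r: (list(chrom_lengths).index(r.chrom), r.start))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.name
            seg.reference_name = r.chrom
            seg.reference_start = r.start
            seg.cigarstring = cigar_to_string(r.cigar)
            seg.query_sequence = r.bases
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            seg.mapping_quality = r.mapping_quality
            seg.flag = r.flags | (16 if r.strand == "-" else 0)
            out.write(seg)


def sam_to_indexed_bam(sam_path, bam_path) -> str:
    """Sort to BAM and index; returns the BAM path."""
    import pysam

    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return str(bam_path)


def write_fixture_files(records, path, kind: str) -> None:
    """Uniform write entry point used by the fixture generator and tests."""
    writers = {
        "bed": write_bed,
        "wig": write_wig,
        "bedgraph": write_bedgraph,
        "seg": write_seg,
        "fasta": write_fasta,
    }
    if kind == "sam":
        reads, chrom_lengths = records
        write_sam(reads, chrom_lengths, path)
    elif kind in writers:
        writers[kind](records, path)
    else:
        raise TrackViewError(f"unknown fixture kind {kind!r}")
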