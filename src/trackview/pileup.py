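"""Alignment analytics: coverage, mismatch marking, downsampling, sorting, packing.

The ordering of operations matters and is part of the contract: coverage is
computed from **all** reads overlapping the view, *before* any downsampling,
so the coverage chart always shows true depth no matter how aggressively the
displayed reads are thinned.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import ContractError
from .formats import AlignedRead, cigar_to_blocks
from .genome import GenomicInterval

BASES = "ACGTN"
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PileupColumn:
    """Per-position tally: depth, base composition and deletion count.

    ``depth == sum(base_counts.values()) + deletion_count`` always holds;
    spliced-over positions contribute nothing (a splice gap is not coverage).
    """

    position: int
    depth: int
    base_counts: dict
    deletion_count: int


class CoverageData:
    """Dense per-base pileup over an interval.

    Stored as numpy arrays (5 x span base counts in ACGTN order plus a
    deletion row) so depth math is vectorised; :meth:`column` and
    :meth:`columns` give the record view.
    """

    def __init__(self, interval: GenomicInterval, base_counts: np.ndarray, deletions: np.ndarray):
        if base_counts.shape != (5, interval.span) or deletions.shape != (interval.span,):
            raise ContractError("coverage array shapes do not match interval span")
        self.interval = interval
        self.base_counts = base_counts
        self.deletions = deletions

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=0) + self.deletions

    def column(self, position: int) -> PileupColumn:
        i = position - self.interval.start
        if not 0 <= i < self.interval.span:
            raise ContractError(f"position {position} outside {self.interval}")
        counts = {b: int(self.base_counts[j, i]) for j, b in enumerate(BASES)}
        return PileupColumn(position, int(self.depth[i]), counts, int(self.deletions[i]))

    def columns(self) -> Iterator[PileupColumn]:
        for pos in range(self.interval.start, self.interval.end):
            yield self.column(pos)


@dataclass(frozen=True)
class MismatchMark:
    """A column where a notable share of reads disagrees with the reference."""

    position: int
    fractions: dict  # non-reference base -> share of depth
    total_mismatch_fraction: float


@dataclass(frozen=True)
class DownsampleConfig:
    """Windowed reservoir-sampling parameters.

    The seed fully determines the retained set for a fixed input order;
    windows are sampled independently.
    """

    window_bp: int = 50
    max_reads_per_window: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.window_bp <= 0 or self.max_reads_per_window <= 0:
            raise ContractError("window_bp and max_reads_per_window must be > 0")


def compute_pileup(
    reads: Iterable[AlignedRead],
    interval: GenomicInterval,
    reference: str,
) -> CoverageData:
    """Per-base coverage and base composition over *interval*.

    Aligned blocks tally the read base at each reference position; deletion
    gaps increment the deletion count; splice gaps contribute nothing.
    Insertions consume no reference and are counted in no column. Reads not
    overlapping the interval are ignored.
    """
    if len(reference) != interval.span:
        raise ContractError(
            f"reference length {len(reference)} != interval span {interval.span}"
        )
    base_counts = np.zeros((5, interval.span), dtype=np.int64)
    deletions = np.zeros(interval.span, dtype=np.int64)
    for read in reads:
        if read.chrom != interval.chrom:
            continue
        seq = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8)
        for blk in cigar_to_blocks(read):
            lo = max(blk.ref_start, interval.start)
            hi = min(blk.ref_end, interval.end)
            if lo >= hi:
                continue
            if blk.kind == "aligned":
                qoff = blk.query_start + (lo - blk.ref_start)
                idx = _BASE_INDEX[seq[qoff : qoff + (hi - lo)]]
                cols = np.arange(lo - interval.start, hi - interval.start)
                valid = idx >= 0
                np.add.at(base_counts, (idx[valid], cols[valid]), 1)
                # bases outside ACGTN tally as N
                if not valid.all():
                    np.add.at(base_counts, (np.full((~valid).sum(), 4), cols[~valid]), 1)
            elif blk.kind == "deletion_gap":
                deletions[lo - interval.start : hi - interval.start] += 1
            # splice_gap: thin-line region, not coverage
    return CoverageData(interval, base_counts, deletions)


def mark_mismatches(
    cov: CoverageData,
    reference: str,
    min_fraction: float = 0.2,
    min_depth: int = 1,
) -> list[MismatchMark]:
    """Columns where the mismatch fraction reaches *min_fraction* at depth
    >= *min_depth*.

    The mismatch fraction is the share of depth carried by non-reference
    A/C/G/T bases. N — in the read or the reference — never counts as
    evidence of mismatch, and deletion gaps are drawn as gaps, not counted
    as base mismatches. Raising *min_fraction* never adds marks.
    """
    if not (0 < min_fraction <= 1) or min_depth < 1:
        raise ContractError("need 0 < min_fraction <= 1 and min_depth >= 1")
    if len(reference) != cov.interval.span:
        raise ContractError("reference length != coverage span")
    marks: list[MismatchMark] = []
    depth = cov.depth
    for i in range(cov.interval.span):
        d = int(depth[i])
        if d < min_depth:
            continue
        ref_base = reference[i].upper()
        if ref_base not in "ACGT":
            continue
        ref_idx = BASES.index(ref_base)
        mismatch = int(cov.base_counts[:4, i].sum() - cov.base_counts[ref_idx, i])
        frac = mismatch / d
        if frac >= min_fraction:
            fractions = {
                b: int(cov.base_counts[j, i]) / d
                for j, b in enumerate("ACGT")
                if j != ref_idx and cov.base_counts[j, i] > 0
            }
            marks.append(MismatchMark(cov.interval.start + i, fractions, frac))
    return marks


def _check_sorted(reads: Sequence[AlignedRead]) -> None:
    for a, b in zip(reads, reads[1:]):
        if b.start < a.start:
            raise ContractError("reads must be sorted by start")


def downsample(
    reads: Sequence[AlignedRead],
    region: GenomicInterval,
    cfg: DownsampleConfig,
) -> list[AlignedRead]:
    """Windowed reservoir downsampling.

    The region is split into consecutive windows of ``cfg.window_bp``; each
    read belongs to the window containing its start (so it is sampled exactly
    once). Windows at or under capacity keep everything; over capacity, a
    seeded reservoir (Algorithm R) keeps ``max_reads_per_window`` reads, each
    with inclusion probability max/n. Output preserves start order and is
    deterministic for a fixed (input order, seed).
    """
    _check_sorted(reads)
    windows: dict[int, list[tuple[int, AlignedRead]]] = {}
    for i, read in enumerate(reads):
        w = (read.start - region.start) // cfg.window_bp
        windows.setdefault(w, []).append((i, read))
    kept: list[tuple[int, AlignedRead]] = []
    k = cfg.max_reads_per_window
    for w in sorted(windows):
        items = windows[w]
        if len(items) <= k:
            kept.extend(items)
            continue
        rng = random.Random(f"{cfg.seed}|{w}")  # str seeding: platform-stable
        reservoir = list(items[:k])
        for i in range(k, len(items)):
            j = rng.randint(0, i)
            if j < k:
                reservoir[j] = items[i]
        kept.extend(reservoir)
    kept.sort(key=lambda t: (t[1].start, t[0]))
    return [r for _, r in kept]


def base_at(read: AlignedRead, position: int) -> Optional[str]:
    """The read's base aligned at a reference position.

    Returns the base character for aligned coverage, ``"-"`` for a deletion
    gap, and None when the read does not cover the position (outside its
    span, or spliced over it).
    """
    for blk in cigar_to_blocks(read):
        if blk.ref_start <= position < blk.ref_end:
            if blk.kind == "aligned":
                return read.bases[blk.query_start + (position - blk.ref_start)].upper()
            if blk.kind == "deletion_gap":
                return "-"
            return None  # splice gap
    return None


def sort_reads_by_base(
    reads: Sequence[AlignedRead], position: int, reference_base: str
) -> list[AlignedRead]:
    """Stable SNP-inspection ordering at one column.

    Non-reference bases come first, grouped by descending count of that base
    at the column (alphabetical on ties), then reference-base reads, then
    deletions, then reads not covering the position. Original order is
    preserved within each group.
    """
    reference_base = reference_base.upper()
    calls = [base_at(r, position) for r in reads]
    counts: dict[str, int] = {}
    for c in calls:
        if c is not None and c != "-" and c != reference_base:
            counts[c] = counts.get(c, 0) + 1

    def key(i: int):
        c = calls[i]
        if c is None:
            return (3, 0, "")
        if c == "-":
            return (2, 0, "")
        if c == reference_base:
            return (1, 0, "")
        return (0, -counts[c], c)

    order = sorted(range(len(reads)), key=key)  # sorted() is stable
    return [reads[i] for i in order]


def pack_rows(items: Sequence, min_gap_bp: int = 0) -> list[int]:
    """Greedy first-fit packing of start-sorted intervals into display rows.

    Accepts reads, features, or anything exposing ``start``/``end`` or an
    ``interval``; returns one row index per input item. Each item takes the
    lowest row whose last occupied end + *min_gap_bp* <= item start. With a
    zero gap this left-endpoint greedy colouring is optimal: row count equals
    the maximum overlap depth.
    """
    spans = [_span_of(it) for it in items]
    for a, b in zip(spans, spans[1:]):
        if b[0] < a[0]:
            raise ContractError("items must be sorted by start")
    row_ends: list[int] = []
    rows: list[int] = []
    for start, end in spans:
        for r, last_end in enumerate(row_ends):
            if last_end + min_gap_bp <= start:
                row_ends[r] = end
                rows.append(r)
                break
        else:
            row_ends.append(end)
            rows.append(len(row_ends) - 1)
    return rows


def _span_of(item) -> tuple[int, int]:
    if hasattr(item, "interval"):
        return item.interval.start, item.interval.end
    if hasattr(item, "start"):
        return item.start, item.end
    start, end = item
    return start, end


def pileup_to_tsv(cov: CoverageData) -> str:
    """TSV export (1-based positions) for oracle diffing.

    Columns: pos, depth, A, C, G, T, N, del.
    """
    lines = ["pos\tdepth\tA\tC\tG\tT\tN\tdel"]
    depth = cov.depth
    for i in range(cov.interval.span):
        counts = "\t".join(str(int(cov.base_counts[j, i])) for j in range(5))
        lines.append(
            f"{cov.interval.start + i + 1}\t{int(depth[i])}\t{counts}\t{int(cov.deletions[i])}"
        )
    return "\n".join(lines) + "\n"
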