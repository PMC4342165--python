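"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive everything from first principles — a naive
CIGAR interpreter and per-position scans — and share no code with the
package's pileup/packing/rendering paths.
"""

from __future__ import annotations


def walk_cigar(start: int, cigar, bases: str):
    """Naive CIGAR interpreter.

    Yields ``(ref_pos, kind, base)`` for every reference position the
    alignment touches: kind is 'base' (with the read base), 'del' or
    'splice'. Insertions and clips advance the query only.
    """
    ref = start
    q = 0
    for op, n in cigar:
        if op in "M=X":
            for i in range(n):
                yield ref + i, "base", bases[q + i]
            ref += n
            q += n
        elif op == "D":
            for i in range(n):
                yield ref + i, "del", None
            ref += n
        elif op == "N":
            for i in range(n):
                yield ref + i, "splice", None
            ref += n
        elif op in "IS":
            q += n
        # H, P: nothing


def brute_force_pileup(reads, chrom: str, start: int, end: int):
    """Per-base counting oracle: dict arrays over [start, end).

    Returns (depth, base_counts, deletions) as plain lists; base_counts is a
    dict base -> list. Splice positions contribute nothing.
    """
    span = end - start
    counts = {b: [0] * span for b in "ACGTN"}
    deletions = [0] * span
    for r in reads:
        if r.chrom != chrom:
            continue
        for pos, kind, base in walk_cigar(r.start, r.cigar, r.bases):
            if not start <= pos < end:
                continue
            if kind == "base":
                b = base.upper()
                counts[b if b in "ACGTN" else "N"][pos - start] += 1
            elif kind == "del":
                deletions[pos - start] += 1
    depth = [
        sum(counts[b][i] for b in "ACGTN") + deletions[i] for i in range(span)
    ]
    return depth, counts, deletions


def brute_force_pileup_tsv(reads, chrom: str, start: int, end: int) -> str:
    """The oracle twin of the package's coverage TSV export."""
    depth, counts, deletions = brute_force_pileup(reads, chrom, start, end)
    lines = ["pos\tdepth\tA\tC\tG\tT\tN\tdel"]
    for i in range(end - start):
        per_base = "\t".join(str(counts[b][i]) for b in "ACGTN")
        lines.append(f"{start + i + 1}\t{depth[i]}\t{per_base}\t{deletions[i]}")
    return "\n".join(lines) + "\n"


def overlap_aligned_length(read, start: int, end: int) -> int:
    """Reference bases of the read inside [start, end) that carry coverage
    (aligned bases or deletion gaps; splice gaps excluded)."""
    total = 0
    for pos, kind, _ in walk_cigar(read.start, read.cigar, read.bases):
        if start <= pos < end and kind in ("base", "del"):
            total += 1
    return total


def max_overlap_depth(spans) -> int:
    """Per-point depth scan over (start, end) interval pairs."""
    if not spans:
        return 0
    best = 0
    points = sorted({s for s, _ in spans} | {e for _, e in spans})
    for p in points:
        depth = sum(1 for s, e in spans if s <= p < e)
        best = max(best, depth)
    return best


def brute_force_overlapping_reads(reads, chrom: str, start: int, end: int):
    """Linear scan overlap filter (the indexed-fetch equivalence oracle)."""
    out = []
    for r in reads:
        ref_len = sum(n for op, n in r.cigar if op in "MDN=X")
        if r.chrom == chrom and r.start < end and r.start + ref_len > start:
            out.append(r)
    return sorted(out, key=lambda r: r.start)
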