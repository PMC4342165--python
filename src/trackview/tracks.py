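"""Track view-models: data + viewport -> style-tagged drawing glyphs.

Each ``layout_*`` function is a pure function of (data, viewport, config):
identical inputs give identical glyph lists, which is what makes rendered
output byte-reproducible. Glyphs carry *style roles*, not colors; a theme
table in the renderer resolves roles to concrete colors, so backends can
restyle without touching layout. The one exception is the copy-number cell,
whose color is data-dependent (computed by :func:`cn_value_to_color`) and
travels in the glyph payload.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .errors import ContractError
from .formats import AlignedRead, Feature, Segment, SignalInterval, cigar_to_blocks
from .genome import GenomicInterval
from .pileup import BASES, CoverageData, MismatchMark, pack_rows
from .tiled_signal import Bin

#: conventional per-base highlight colors, carried as style roles
MISMATCH_ROLES = {b: f"mismatch_base_{b}" for b in "ACGT"}

DEFAULT_VISIBILITY_THRESHOLD_BP = 30_000


@dataclass(frozen=True)
class Viewport:
    """The displayed interval plus its width in pixels."""

    interval: GenomicInterval
    pixel_width: int

    def __post_init__(self):
        if self.pixel_width < 1:
            raise ContractError("pixel_width must be >= 1")

    @property
    def bases_per_pixel(self) -> float:
        return self.interval.span / self.pixel_width

    def x(self, position: int) -> float:
        """Affine, order-preserving genomic -> pixel mapping."""
        return (position - self.interval.start) / self.bases_per_pixel


@dataclass(frozen=True)
class Glyph:
    """One resolution-independent drawing primitive.

    ``shape`` is rect/hline/vline/text; hlines have ``h == 0`` (y is the
    line's vertical position, w its length), vlines ``w == 0``. Glyph order
    defines paint order.
    """

    shape: str
    x: float
    y: float
    w: float
    h: float
    style_role: str
    opacity: float = 1.0
    payload: Optional[str] = None


@dataclass(frozen=True)
class QualityOpacityPolicy:
    """Base-quality -> mismatch-glyph opacity mapping.

    Opacity ramps linearly from ``min_opacity`` at Phred ``q_lo`` to 1.0 at
    ``q_hi``, so confident variant calls pop and noisy ones fade.
    """

    q_lo: int = 5
    q_hi: int = 20
    min_opacity: float = 0.1

    def opacity(self, qual: int) -> float:
        t = (qual - self.q_lo) / (self.q_hi - self.q_lo)
        return max(self.min_opacity, min(1.0, t))


@dataclass(frozen=True)
class CnColorScale:
    """Red/blue diverging copy-number scale.

    ``cap`` is the |log2 ratio| at full saturation; value 0 maps to neutral,
    amplification interpolates toward ``positive_hue`` (red), deletion toward
    ``negative_hue`` (blue). Odd-symmetric and monotone in |value|.
    """

    cap: float = 1.5
    neutral: tuple = (255, 255, 255)
    # pure red/blue: equidistant from the white neutral, so the scale is
    # exactly odd-symmetric in intensity
    positive_hue: tuple = (255, 0, 0)
    negative_hue: tuple = (0, 0, 255)


def cn_value_to_color(v: float, scale: CnColorScale = CnColorScale()) -> tuple:
    """Interpolate neutral -> hue at min(|v|/cap, 1)."""
    t = min(abs(v) / scale.cap, 1.0)
    hue = scale.positive_hue if v > 0 else scale.negative_hue
    if v == 0:
        return scale.neutral
    return tuple(
        round(n + (h - n) * t) for n, h in zip(scale.neutral, hue)
    )


def should_load_alignments(
    viewport: Viewport, threshold_bp: int = DEFAULT_VISIBILITY_THRESHOLD_BP
) -> bool:
    """Zoom-visibility gate: fetch read-level data only when the view is
    small enough that individual reads (tens of bases) are distinguishable."""
    if threshold_bp <= 0:
        raise ContractError("threshold_bp must be > 0")
    return viewport.interval.span <= threshold_bp


# ---------------------------------------------------------------------------
# alignment track
# ---------------------------------------------------------------------------


def layout_alignment_track(
    reads: Sequence[AlignedRead],
    rows: Sequence[int],
    viewport: Viewport,
    reference: str,
    policy: QualityOpacityPolicy = QualityOpacityPolicy(),
    row_height_px: int = 10,
    read_height_px: int = 7,
) -> list[Glyph]:
    """Read bodies, splice connectors, deletion lines and per-base mismatches.

    One grey ``read_body`` rect per aligned block; one thin ``splice_connector``
    hline per splice gap; deletion gaps as a ``deletion_gap`` hline with no
    body. Mismatching bases get a ``mismatch_base_X`` rect whose opacity
    follows the base quality via *policy*. N in read or reference is never
    drawn as a mismatch.
    """
    if len(reference) != viewport.interval.span:
        raise ContractError("reference must cover the viewport")
    view = viewport.interval
    glyphs: list[Glyph] = []
    for read, row in zip(reads, rows):
        y = row * row_height_px
        mid_y = y + read_height_px / 2
        for blk in cigar_to_blocks(read):
            lo, hi = max(blk.ref_start, view.start), min(blk.ref_end, view.end)
            if lo >= hi:
                continue
            x0, x1 = viewport.x(lo), viewport.x(hi)
            if blk.kind == "aligned":
                glyphs.append(
                    Glyph("rect", x0, y, x1 - x0, read_height_px, "read_body")
                )
            elif blk.kind == "splice_gap":
                glyphs.append(
                    Glyph("hline", x0, mid_y, x1 - x0, 0.0, "splice_connector")
                )
            else:
                glyphs.append(
                    Glyph("hline", x0, mid_y, x1 - x0, 0.0, "deletion_gap")
                )
        # mismatch glyphs on top of read bodies
        for blk in cigar_to_blocks(read):
            if blk.kind != "aligned":
                continue
            lo, hi = max(blk.ref_start, view.start), min(blk.ref_end, view.end)
            for pos in range(lo, hi):
                q = blk.query_start + (pos - blk.ref_start)
                base = read.bases[q].upper()
                ref_base = reference[pos - view.start].upper()
                if base == ref_base or base == "N" or ref_base == "N":
                    continue
                role = MISMATCH_ROLES.get(base, "mismatch_base_N")
                glyphs.append(
                    Glyph(
                        "rect",
                        viewport.x(pos),
                        y,
                        viewport.x(pos + 1) - viewport.x(pos),
                        read_height_px,
                        role,
                        opacity=policy.opacity(read.quals[q]),
                        payload=base,
                    )
                )
    return glyphs


# ---------------------------------------------------------------------------
# coverage track
# ---------------------------------------------------------------------------


def layout_coverage_track(
    cov: CoverageData,
    marks: Sequence[MismatchMark],
    viewport: Viewport,
    height_px: int = 60,
) -> list[Glyph]:
    """Coverage bar chart with mismatch loci split into colored portions.

    One ``coverage_bar`` per pixel column; when bases-per-pixel > 1 the
    column aggregates by **max** depth (preserves peaks). At marked loci the
    bar splits into stacked ``coverage_mismatch_portion`` rects proportional
    to each base's share of that column's depth (payload = base letter,
    reference share drawn first as a plain bar segment). Heights scale
    linearly to the max depth in view.
    """
    view = viewport.interval
    depth = cov.depth
    marks_by_pos = {m.position: m for m in marks}
    max_depth = int(depth.max()) if len(depth) else 0
    if max_depth == 0:
        return []
    glyphs: list[Glyph] = []
    bpp = viewport.bases_per_pixel
    for px in range(viewport.pixel_width):
        lo = view.start + int(px * bpp)
        hi = view.start + max(int((px + 1) * bpp), int(px * bpp) + 1)
        lo_i, hi_i = lo - view.start, min(hi, view.end) - view.start
        if lo_i >= cov.interval.span:
            break
        d = int(depth[lo_i:hi_i].max()) if hi_i > lo_i else 0
        if d == 0:
            continue
        bar_h = d / max_depth * height_px
        marked = [p for p in range(lo, min(hi, view.end)) if p in marks_by_pos]
        if marked:
            # use the marked column itself for the composition split
            pos = max(marked, key=lambda p: int(depth[p - view.start]))
            col_i = pos - view.start
            col_depth = int(depth[col_i])
            y = height_px
            shares = []
            for j, b in enumerate(BASES):
                c = int(cov.base_counts[j, col_i])
                if c:
                    shares.append((b, c / col_depth))
            if cov.deletions[col_i]:
                shares.append(("-", int(cov.deletions[col_i]) / col_depth))
            for b, share in shares:
                h = share * bar_h
                y -= h
                glyphs.append(
                    Glyph(
                        "rect", px, y, 1.0, h, "coverage_mismatch_portion",
                        payload=b,
                    )
                )
        else:
            glyphs.append(
                Glyph("rect", px, height_px - bar_h, 1.0, bar_h, "coverage_bar")
            )
    return glyphs


# ---------------------------------------------------------------------------
# numeric track
# ---------------------------------------------------------------------------

NumericDatum = Union[SignalInterval, tuple]


def layout_numeric_track(
    points: Sequence[NumericDatum],
    viewport: Viewport,
    height_px: int = 60,
    fixed_range: Optional[tuple] = None,
) -> list[Glyph]:
    """Vertical bars with height linear in the data value.

    Accepts raw :class:`SignalInterval` lists or ``(interval, Bin)`` pairs
    from the tiled store (the bin's mean is drawn). Autoscale uses
    ``[0, max]`` for non-negative data and a symmetric ``[-m, m]`` otherwise;
    a ``fixed_range`` overrides autoscale. Negative values hang below the
    baseline.
    """
    data: list[tuple[GenomicInterval, float]] = []
    for p in points:
        if isinstance(p, SignalInterval):
            data.append((p.interval, p.value))
        else:
            iv, b = p
            data.append((iv, b.mean if isinstance(b, Bin) else float(b)))
    view = viewport.interval
    data = [(iv, v) for iv, v in data if iv.overlaps(view)]
    if not data:
        return []
    if fixed_range is not None:
        lo, hi = fixed_range
    else:
        vmax = max(v for _, v in data)
        vmin = min(v for _, v in data)
        if vmin >= 0:
            lo, hi = 0.0, vmax
        else:
            m = max(abs(vmin), abs(vmax))
            lo, hi = -m, m
    span = hi - lo if hi > lo else 1.0
    baseline_v = max(lo, min(0.0, hi))
    baseline_y = height_px * (1 - (baseline_v - lo) / span)
    glyphs = []
    for iv, v in data:
        clipped = iv.intersect(view)
        x0, x1 = viewport.x(clipped.start), viewport.x(clipped.end)
        frac = (min(max(v, lo), hi) - baseline_v) / span
        h = abs(frac) * height_px
        y = baseline_y - h if v >= baseline_v else baseline_y
        glyphs.append(Glyph("rect", x0, y, x1 - x0, h, "numeric_bar"))
    return glyphs


# ---------------------------------------------------------------------------
# segmented copy-number track
# ---------------------------------------------------------------------------


def sort_samples(
    segments: Sequence[Segment],
    region: GenomicInterval,
    direction: str = "deletion",
) -> list[str]:
    """Order samples by copy-number level within *region*.

    The per-sample score is the length-weighted mean of segment values
    intersected with the region (no overlap scores 0). ``deletion`` sorts
    ascending (strongest deletion first), ``amplification`` descending;
    ties break by sample name. The result is a permutation of the distinct
    input sample names.
    """
    if direction not in ("deletion", "amplification"):
        raise ContractError(f"unknown sort direction {direction!r}")
    samples: dict[str, tuple[float, int]] = {}
    for seg in segments:
        mass, length = samples.get(seg.sample, (0.0, 0))
        clipped = seg.interval.intersect(region)
        if clipped is not None:
            mass += seg.value * clipped.span
            length += clipped.span
        samples[seg.sample] = (mass, length)
    scores = {
        name: (mass / length if length else 0.0)
        for name, (mass, length) in samples.items()
    }
    reverse = direction == "amplification"
    return sorted(scores, key=lambda n: (-scores[n] if reverse else scores[n], n))


def layout_segment_track(
    segments: Sequence[Segment],
    sample_order: Sequence[str],
    viewport: Viewport,
    scale: CnColorScale = CnColorScale(),
    row_height_px: int = 12,
) -> list[Glyph]:
    """One heatmap cell per (sample, segment ∩ viewport), rows stacked in the
    given order; spans without data draw nothing. Cell color rides in the
    payload as ``#rrggbb``."""
    row_of = {name: i for i, name in enumerate(sample_order)}
    glyphs = []
    for seg in segments:
        if seg.sample not in row_of:
            continue
        clipped = seg.interval.intersect(viewport.interval)
        if clipped is None:
            continue
        r, g, b = cn_value_to_color(seg.value, scale)
        x0, x1 = viewport.x(clipped.start), viewport.x(clipped.end)
        glyphs.append(
            Glyph(
                "rect",
                x0,
                row_of[seg.sample] * row_height_px,
                x1 - x0,
                row_height_px - 1,
                "cn_cell",
                payload=f"#{r:02x}{g:02x}{b:02x}",
            )
        )
    glyphs.sort(key=lambda g: (g.y, g.x))
    return glyphs


# ---------------------------------------------------------------------------
# feature track
# ---------------------------------------------------------------------------

CHAR_WIDTH_PX = 6  # fixed per-character estimate for label fitting


def layout_feature_track(
    features: Sequence[Feature],
    viewport: Viewport,
    row_height_px: int = 14,
    box_height_px: int = 9,
) -> list[Glyph]:
    """Feature boxes packed into sub-rows, labelled when pixel room permits.

    Overlapping features reuse the first-fit row packing from the pileup
    module; the strand is appended to the label as an arrow.
    """
    view = viewport.interval
    in_view = sorted(
        (f for f in features if f.interval.overlaps(view)),
        key=lambda f: f.interval.start,
    )
    rows = pack_rows(in_view, min_gap_bp=max(1, int(viewport.bases_per_pixel)))
    glyphs = []
    for feat, row in zip(in_view, rows):
        clipped = feat.interval.intersect(view)
        x0, x1 = viewport.x(clipped.start), viewport.x(clipped.end)
        y = row * row_height_px
        glyphs.append(Glyph("rect", x0, y, x1 - x0, box_height_px, "feature_box"))
        label = feat.name
        if feat.strand == "+":
            label += " >"
        elif feat.strand == "-":
            label += " <"
        if label.strip() and len(label) * CHAR_WIDTH_PX <= (x1 - x0):
            glyphs.append(
                Glyph(
                    "text",
                    (x0 + x1) / 2,
                    y + box_height_px - 1,
                    0.0,
                    0.0,
                    "label",
                    payload=label,
                )
            )
    return glyphs
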