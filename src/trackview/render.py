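"""Scene composition and deterministic serialization to SVG (and PNG).

The scene is the renderer's whole contract: an ordered list of track panels,
each a label plus glyph list, with a coordinate ruler on top. ``to_svg``
formats every number with fixed 2-decimal precision so the same scene always
serializes to byte-identical text, on any platform — that determinism is a
feature, not an accident: it is what makes rendered views diffable and
shareable artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import CapabilityError
from .tracks import Glyph, Viewport

#: style role -> fill/stroke color; the single place visual identity lives.
DEFAULT_THEME = {
    "background": "#ffffff",
    "read_body": "#c8c8c8",
    "mismatch_base_A": "#00a000",
    "mismatch_base_C": "#0000ff",
    "mismatch_base_G": "#ff7f00",
    "mismatch_base_T": "#ff0000",
    "mismatch_base_N": "#808080",
    "splice_connector": "#a0a0c0",
    "deletion_gap": "#000000",
    "coverage_bar": "#9f9f9f",
    "coverage_mismatch_portion": "#9f9f9f",  # per-base override below
    "numeric_bar": "#4878a8",
    "cn_cell": "#ffffff",  # actual color carried per-glyph in payload
    "feature_box": "#2c5aa0",
    "ruler_tick": "#000000",
    "label": "#202020",
    "error_label": "#b00020",
    "panel_border": "#e0e0e0",
}

#: coverage-portion colors keyed by the base letter in the glyph payload.
PORTION_COLORS = {
    "A": "#00a000",
    "C": "#0000ff",
    "G": "#ff7f00",
    "T": "#ff0000",
    "N": "#808080",
    "-": "#404040",
}

RULER_HEIGHT = 24
PANEL_MARGIN = 4
LABEL_GUTTER = 14


@dataclass
class Panel:
    """One horizontal track panel placed inside a scene."""

    label: str
    y_offset: int
    height: int
    glyphs: list


@dataclass
class Scene:
    """Composed, resolution-fixed drawing: ruler + stacked panels."""

    width: int
    height: int
    panels: list
    ruler_glyphs: list
    viewport: Viewport


def _tick_spacing(viewport: Viewport, min_px_gap: float = 70.0) -> int:
    """Smallest 1/2/5 x 10^k spacing leaving at least *min_px_gap* pixels."""
    min_bases = min_px_gap * viewport.bases_per_pixel
    k = 0
    while True:
        for m in (1, 2, 5):
            s = m * 10**k
            if s >= min_bases:
                return s
        k += 1


def _ruler(viewport: Viewport) -> list:
    spacing = _tick_spacing(viewport)
    iv = viewport.interval
    glyphs = []
    first = -(-iv.start // spacing) * spacing
    for pos in range(first, iv.end, spacing):
        x = viewport.x(pos)
        glyphs.append(Glyph("vline", x, RULER_HEIGHT - 8, 0.0, 8.0, "ruler_tick"))
        glyphs.append(
            Glyph("text", x, RULER_HEIGHT - 10, 0.0, 0.0, "label", payload=f"{pos + 1:,}")
        )
    return glyphs


def _clip(g: Glyph, width: float, height: float) -> Optional[Glyph]:
    """Clamp a glyph to panel bounds; drop it when fully outside."""
    x0, x1 = g.x, g.x + g.w
    y0, y1 = g.y, g.y + g.h
    if x1 < 0 or x0 > width or y1 < 0 or y0 > height:
        return None
    if g.shape == "text":
        return g
    x0, x1 = max(0.0, x0), min(width, x1)
    y0, y1 = max(0.0, y0), min(height, y1)
    return Glyph(g.shape, x0, y0, x1 - x0, y1 - y0, g.style_role, g.opacity, g.payload)


def compose(
    tracks: Sequence[tuple],
    viewport: Viewport,
    margin: int = PANEL_MARGIN,
) -> Scene:
    """Stack track panels under a coordinate ruler.

    *tracks* is a sequence of ``(label, glyphs, height_px)`` in display
    order. Glyphs are clipped to their panel bounds here, so nothing in the
    scene ever paints outside its panel.
    """
    panels: list[Panel] = []
    y = RULER_HEIGHT + margin
    for label, glyphs, height in tracks:
        clipped = [
            c for g in glyphs if (c := _clip(g, viewport.pixel_width, height)) is not None
        ]
        panels.append(Panel(label, y, height, clipped))
        y += height + LABEL_GUTTER + margin
    return Scene(viewport.pixel_width, y, panels, _ruler(viewport), viewport)


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------


def _f(x: float) -> str:
    """Fixed 2-decimal formatting; the byte-stability workhorse."""
    return f"{x + 0.0:.2f}"  # +0.0 normalizes -0.0


def _esc(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _glyph_svg(g: Glyph, theme: dict) -> str:
    color = theme.get(g.style_role, "#000000")
    if g.style_role == "cn_cell" and g.payload:
        color = g.payload
    if g.style_role == "coverage_mismatch_portion" and g.payload:
        color = PORTION_COLORS.get(g.payload, color)
    op = "" if g.opacity >= 1.0 else f' opacity="{_f(g.opacity)}"'
    if g.shape == "rect":
        return (
            f'<rect x="{_f(g.x)}" y="{_f(g.y)}" width="{_f(g.w)}" '
            f'height="{_f(g.h)}" fill="{color}"{op}/>'
        )
    if g.shape == "hline":
        return (
            f'<line x1="{_f(g.x)}" y1="{_f(g.y)}" x2="{_f(g.x + g.w)}" '
            f'y2="{_f(g.y)}" stroke="{color}" stroke-width="1"{op}/>'
        )
    if g.shape == "vline":
        return (
            f'<line x1="{_f(g.x)}" y1="{_f(g.y)}" x2="{_f(g.x)}" '
            f'y2="{_f(g.y + g.h)}" stroke="{color}" stroke-width="1"{op}/>'
        )
    if g.shape == "text":
        return (
            f'<text x="{_f(g.x)}" y="{_f(g.y)}" font-size="10" '
            f'font-family="monospace" text-anchor="middle" '
            f'fill="{color}"{op}>{_esc(g.payload or "")}</text>'
        )
    raise CapabilityError(f"unknown glyph shape {g.shape!r}")


def to_svg(scene: Scene, theme: Optional[dict] = None) -> str:
    """Serialize to SVG 1.1; element order equals glyph order."""
    theme = {**DEFAULT_THEME, **(theme or {})}
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{scene.width}" '
        f'height="{scene.height}" viewBox="0 0 {scene.width} {scene.height}">',
        f'<rect x="0" y="0" width="{scene.width}" height="{scene.height}" '
        f'fill="{theme["background"]}"/>',
    ]
    for g in scene.ruler_glyphs:
        out.append(_glyph_svg(g, theme))
    for panel in scene.panels:
        out.append(f'<g transform="translate(0,{panel.y_offset})">')
        out.append(
            f'<rect x="0" y="0" width="{scene.width}" height="{panel.height}" '
            f'fill="none" stroke="{theme["panel_border"]}"/>'
        )
        for g in panel.glyphs:
            out.append(_glyph_svg(g, theme))
        if panel.label:
            role = "error_label" if panel.label.startswith("error") else "label"
            out.append(
                f'<text x="4" y="{panel.height + 11}" font-size="10" '
                f'font-family="monospace" text-anchor="start" '
                f'fill="{theme[role]}">{_esc(panel.label)}</text>'
            )
        out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PNG (optional raster backend)
# ---------------------------------------------------------------------------


def to_png(scene: Scene, path, scale: float = 1.0, theme: Optional[dict] = None) -> None:
    """Rasterize via Pillow; degrades to a capability error when absent."""
    try:
        from PIL import Image, ImageDraw
    except ImportError as exc:  # pragma: no cover - Pillow is a hard dep here
        raise CapabilityError(f"raster output requires Pillow: {exc}") from None
    theme = {**DEFAULT_THEME, **(theme or {})}
    w, h = round(scene.width * scale), round(scene.height * scale)
    img = Image.new("RGB", (w, h), theme["background"])
    draw = ImageDraw.Draw(img, "RGBA")

    def color_of(g: Glyph) -> tuple:
        c = theme.get(g.style_role, "#000000")
        if g.style_role == "cn_cell" and g.payload:
            c = g.payload
        if g.style_role == "coverage_mismatch_portion" and g.payload:
            c = PORTION_COLORS.get(g.payload, c)
        r, gr, b = int(c[1:3], 16), int(c[3:5], 16), int(c[5:7], 16)
        return (r, gr, b, round(255 * g.opacity))

    def paint(g: Glyph, dy: float) -> None:
        x0, y0 = g.x * scale, (g.y + dy) * scale
        if g.shape == "rect":
            draw.rectangle([x0, y0, (g.x + g.w) * scale, (g.y + g.h + dy) * scale], fill=color_of(g))
        elif g.shape == "hline":
            draw.line([x0, y0, (g.x + g.w) * scale, y0], fill=color_of(g))
        elif g.shape == "vline":
            draw.line([x0, y0, x0, (g.y + g.h + dy) * scale], fill=color_of(g))
        # text skipped in raster output (fixed-metrics fonts unavailable)

    for g in scene.ruler_glyphs:
        paint(g, 0)
    for panel in scene.panels:
        for g in panel.glyphs:
            paint(g, panel.y_offset)
    img.save(path, format="PNG")
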