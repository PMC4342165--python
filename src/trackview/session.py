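"""Shareable session links and session files.

A launch link is a plain URL whose query string reconstructs a view:

    https://host/launch?genome=toy1&locus=chrA:1,000-2,000&file=a.bam,b.seg&name=reads,cn

Recognized keys, in canonical emission order: ``genome``, ``locus``,
``file`` (comma-separated, order-preserving — the track order in the scene),
``name`` (comma-separated, position-paired with ``file``). Values are
percent-encoded per element, so names containing commas or spaces survive the
round trip. Unknown keys are ignored with a logged warning; the grammar is
versioned by this module.

A session can also live in a JSON session file, which additionally carries
the display options (visibility threshold, downsampling, mismatch thresholds,
copy-number scale) that a compact link omits.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence
from urllib.parse import quote, unquote, urlsplit

from .errors import (
    IncompleteLinkError,
    PairingError,
    TrackViewError,
    UnknownGenomeError,
)
from .formats import (
    AlignmentSource,
    read_alignments,
    read_features,
    read_segments,
    read_signal,
)
from .genome import GenomeModel, fetch_reference, parse_locus
from .pileup import (
    DownsampleConfig,
    compute_pileup,
    downsample,
    mark_mismatches,
    pack_rows,
)
from .render import Scene, compose
from .tiled_signal import load_store, query
from .tracks import (
    CnColorScale,
    Glyph,
    Viewport,
    layout_alignment_track,
    layout_coverage_track,
    layout_feature_track,
    layout_numeric_track,
    layout_segment_track,
    should_load_alignments,
    sort_samples,
)

logger = logging.getLogger(__name__)

LINK_KEYS = ("genome", "locus", "file", "name")

#: file extension -> track type
_EXT_TYPES = {
    ".bam": "alignment",
    ".sam": "alignment",
    ".bed": "feature",
    ".wig": "numeric",
    ".bedgraph": "numeric",
    ".bg": "numeric",
    ".bw": "numeric",
    ".bigwig": "numeric",
    ".tss": "numeric",
    ".seg": "segment",
}


@dataclass(frozen=True)
class TrackSpec:
    """One dataset in a session: where it lives, what to call it, how to draw it."""

    path: str
    name: Optional[str] = None
    track_type: Optional[str] = None  # override; else inferred from extension

    def inferred_type(self) -> str:
        if self.track_type:
            return self.track_type
        ext = os.path.splitext(self.path)[1].lower()
        ttype = _EXT_TYPES.get(ext)
        if ttype is None:
            raise TrackViewError(f"cannot infer track type from {self.path!r}")
        return ttype


@dataclass(frozen=True)
class DisplayOptions:
    """Adjustable view parameters a link omits but a session file keeps."""

    threshold_bp: int = 30_000
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    mismatch_min_fraction: float = 0.2
    mismatch_min_depth: int = 1
    cn_scale: CnColorScale = field(default_factory=CnColorScale)
    cn_sort: Optional[str] = None  # 'deletion' | 'amplification' | None


@dataclass(frozen=True)
class Session:
    """Genome + locus + ordered datasets + display options."""

    genome_id: Optional[str]
    locus_text: str
    tracks: tuple = ()
    options: DisplayOptions = field(default_factory=DisplayOptions)


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------


def parse_link(url: str) -> Session:
    """Parse a launch link into a Session.

    A missing ``genome`` falls back to the configured default at load time;
    missing both ``genome`` and ``locus`` is an error, as is a ``name`` list
    whose length differs from ``file``.
    """
    parts = urlsplit(url)
    if not parts.query:
        raise IncompleteLinkError(f"link has no query component: {url!r}")
    values: dict[str, list[str]] = {}
    for chunk in parts.query.split("&"):
        if not chunk:
            continue
        key, _, raw = chunk.partition("=")
        key = unquote(key)
        if key not in LINK_KEYS:
            logger.warning("ignoring unknown link key %r", key)
            continue
        if key in ("file", "name"):
            # split on commas BEFORE percent-decoding so %2C inside values survives
            items = [unquote(piece) for piece in raw.split(",")]
        else:
            items = [unquote(raw)]
        values.setdefault(key, []).extend(items)
    genome_id = values.get("genome", [None])[0]
    locus = values.get("locus", [None])[0]
    if genome_id is None and locus is None:
        raise IncompleteLinkError("link specifies neither genome nor locus")
    files = values.get("file", [])
    names = values.get("name", [])
    if names and len(names) != len(files):
        raise PairingError(
            f"link has {len(files)} file(s) but {len(names)} name(s)"
        )
    tracks = tuple(
        TrackSpec(path, names[i] if names else None) for i, path in enumerate(files)
    )
    return Session(genome_id, locus or "", tracks)


def serialize_link(session: Session, base_url: str) -> str:
    """Emit the canonical link: keys in fixed order, values percent-encoded.

    ``parse_link(serialize_link(s)) == s`` for canonical sessions (display
    options are not carried by links; use a session file for those).
    """
    pairs = []
    if session.genome_id:
        pairs.append(("genome", quote(session.genome_id, safe="")))
    if session.locus_text:
        pairs.append(("locus", quote(session.locus_text, safe=":,-")))
    if session.tracks:
        pairs.append(
            ("file", ",".join(quote(t.path, safe="") for t in session.tracks))
        )
        if any(t.name for t in session.tracks):
            pairs.append(
                ("name", ",".join(quote(t.name or "", safe="") for t in session.tracks))
            )
    sep = "&" if "?" in base_url else "?"
    return base_url + sep + "&".join(f"{k}={v}" for k, v in pairs)


# ---------------------------------------------------------------------------
# session files (JSON)
# ---------------------------------------------------------------------------


def rebase_tracks(session: Session, base_dir: str) -> Session:
    """Resolve relative track paths against *base_dir* (typically the
    directory holding the session file); absolute paths pass through."""
    tracks = tuple(
        t if os.path.isabs(t.path) else replace(t, path=os.path.join(base_dir, t.path))
        for t in session.tracks
    )
    return replace(session, tracks=tracks)


def session_to_json(session: Session) -> str:
    opt = session.options
    doc = {
        "genome": session.genome_id,
        "locus": session.locus_text,
        "tracks": [
            {"path": t.path, "name": t.name, "type": t.track_type}
            for t in session.tracks
        ],
        "options": {
            "threshold_bp": opt.threshold_bp,
            "downsample": {
                "window_bp": opt.downsample.window_bp,
                "max_reads_per_window": opt.downsample.max_reads_per_window,
                "seed": opt.downsample.seed,
            },
            "mismatch_min_fraction": opt.mismatch_min_fraction,
            "mismatch_min_depth": opt.mismatch_min_depth,
            "cn_cap": opt.cn_scale.cap,
            "cn_sort": opt.cn_sort,
        },
    }
    return json.dumps(doc, indent=2) + "\n"


def session_from_json(text: str) -> Session:
    doc = json.loads(text)
    o = doc.get("options", {})
    ds = o.get("downsample", {})
    options = DisplayOptions(
        threshold_bp=o.get("threshold_bp", 30_000),
        downsample=DownsampleConfig(
            window_bp=ds.get("window_bp", 50),
            max_reads_per_window=ds.get("max_reads_per_window", 100),
            seed=ds.get("seed", 0),
        ),
        mismatch_min_fraction=o.get("mismatch_min_fraction", 0.2),
        mismatch_min_depth=o.get("mismatch_min_depth", 1),
        cn_scale=CnColorScale(cap=o.get("cn_cap", 1.5)),
        cn_sort=o.get("cn_sort"),
    )
    tracks = tuple(
        TrackSpec(t["path"], t.get("name"), t.get("type"))
        for t in doc.get("tracks", [])
    )
    return Session(doc.get("genome"), doc.get("locus", ""), tracks, options)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

ALIGNMENT_PANEL_MAX_ROWS = 40
PLACEHOLDER_LABEL = "zoom in to see reads"


def load_session(
    session: Session,
    registry: dict,
    pixel_width: int = 1000,
    default_genome_id: Optional[str] = None,
    source_cache: Optional[dict] = None,
) -> Scene:
    """Resolve a session into a composed scene.

    *registry* maps genome id -> :class:`GenomeModel`. Track types come from
    file extensions unless overridden. Alignment tracks respect the zoom
    visibility gate (no source fetch happens above the threshold — observable
    through ``source_cache``, which maps path -> :class:`AlignmentSource` and
    may be pre-populated by the caller for instrumentation). A failure on one
    track does not abort the others; the failed track renders as an
    error-label panel.
    """
    genome_id = session.genome_id or default_genome_id
    if genome_id is None and registry:
        genome_id = next(iter(registry))
    genome = registry.get(genome_id)
    if genome is None:
        raise UnknownGenomeError(f"genome {genome_id!r} not in registry")
    view_interval = parse_locus(session.locus_text, genome)
    viewport = Viewport(view_interval, pixel_width)
    if source_cache is None:
        source_cache = {}

    panels: list[tuple] = []
    for spec in session.tracks:
        label = spec.name or os.path.basename(spec.path)
        try:
            panels.extend(
                _layout_track(spec, label, viewport, genome, session.options, source_cache)
            )
        except Exception as exc:  # noqa: BLE001 - isolation rule: one bad track
            logger.warning("track %s failed: %s", spec.path, exc)
            panels.append(
                (
                    f"error: {label}: {exc}",
                    [Glyph("text", pixel_width / 2, 12.0, 0.0, 0.0, "error_label",
                           payload=f"failed to load: {label}")],
                    20,
                )
            )
    return compose(panels, viewport)


def _layout_track(
    spec: TrackSpec,
    label: str,
    viewport: Viewport,
    genome: GenomeModel,
    options: DisplayOptions,
    source_cache: dict,
) -> list[tuple]:
    ttype = spec.inferred_type()
    view = viewport.interval
    if ttype == "alignment":
        return _layout_alignment(spec, label, viewport, genome, options, source_cache)
    if ttype == "feature":
        feats = read_features(spec.path, region=view)
        glyphs = layout_feature_track(feats, viewport)
        height = max((int(g.y + g.h) for g in glyphs), default=14) + 2
        return [(label, glyphs, height)]
    if ttype == "numeric":
        if spec.path.lower().endswith(".tss"):
            store = load_store(spec.path)
            points = query(store, view, max_points=viewport.pixel_width)
            glyphs = layout_numeric_track(points, viewport)
        else:
            signal = read_signal(spec.path)
            glyphs = layout_numeric_track(signal, viewport)
        return [(label, glyphs, 60)]
    if ttype == "segment":
        segments = read_segments(spec.path)
        if options.cn_sort:
            order = sort_samples(segments, view, options.cn_sort)
        else:
            order = sorted({s.sample for s in segments})
        glyphs = layout_segment_track(segments, order, viewport, options.cn_scale)
        return [(label, glyphs, max(12 * len(order), 12))]
    raise TrackViewError(f"unknown track type {ttype!r}")


def _layout_alignment(
    spec: TrackSpec,
    label: str,
    viewport: Viewport,
    genome: GenomeModel,
    options: DisplayOptions,
    source_cache: dict,
) -> list[tuple]:
    view = viewport.interval
    if not should_load_alignments(viewport, options.threshold_bp):
        placeholder = [
            Glyph("text", viewport.pixel_width / 2, 14.0, 0.0, 0.0, "label",
                  payload=PLACEHOLDER_LABEL)
        ]
        return [(label, placeholder, 24)]
    source = source_cache.get(spec.path)
    if source is None:
        source = AlignmentSource(spec.path)
        source_cache[spec.path] = source
    reads = read_alignments(source, view)
    if genome.sequence_source is not None:
        reference = fetch_reference(view, genome)
    else:
        reference = "N" * view.span
    # coverage from ALL reads, before any downsampling: the chart always
    # shows true depth
    cov = compute_pileup(reads, view, reference)
    marks = mark_mismatches(
        cov, reference, options.mismatch_min_fraction, options.mismatch_min_depth
    )
    shown = downsample(reads, view, options.downsample)
    rows = pack_rows(shown, min_gap_bp=1)
    keep = [i for i, r in enumerate(rows) if r < ALIGNMENT_PANEL_MAX_ROWS]
    shown = [shown[i] for i in keep]
    rows = [rows[i] for i in keep]
    cov_glyphs = layout_coverage_track(cov, marks, viewport)
    read_glyphs = layout_alignment_track(shown, rows, viewport, reference)
    n_rows = (max(rows) + 1) if rows else 1
    return [
        (f"{label} coverage", cov_glyphs, 60),
        (label, read_glyphs, max(10 * n_rows, 10)),
    ]
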