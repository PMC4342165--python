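"""Multi-resolution binned signal store.

Pre-computes a power-of-two pyramid of (mean, min, max, count) bins per
chromosome so that any viewport can be answered with a bounded number of
bins, whatever the zoom level — the role a binary tiled format plays in a
networked genome browser, reduced to its essential data structure.

Level 0 is the finest (bin width = ``base_bin_width``); level i has width
``base_bin_width * 2**i``. Every parent bin covers exactly two children and
satisfies exact aggregation invariants:

* ``parent.count = left.count + right.count``
* ``parent.mean`` = count-weighted mean of the children
* ``parent.min/max`` = min/max over the children

``count`` is the number of covered bases contributing to the bin; a count of
zero marks an *empty* bin — absence of data, distinct from a measured zero —
and empty bins are never drawn.

The on-disk container (".tss", tiled signal store) is a little-endian layout:
header (magic ``TSSb``, u16 version, genome id, u32 base_bin_width, u16
num_levels, u16 n_chroms), then per chromosome: name, u64 length, and per
level the u64 bin count followed by the four dense arrays (f8 mass, i8 count,
f8 min, f8 max). Floats round-trip bit-exactly.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import BinaryIO, Optional, Sequence

import numpy as np

from .errors import ContractError, FormatError, VersionError
from .formats import SignalInterval
from .genome import GenomeModel, GenomicInterval

MAGIC = b"TSSb"
VERSION = 1


@dataclass(frozen=True)
class Bin:
    """Aggregate over one bin: value statistics plus covered-base count."""

    mean: float
    min: float
    max: float
    count: int


class _LevelArrays:
    """Dense arrays for one (chromosome, level): mass = sum(value * covered)."""

    __slots__ = ("mass", "count", "vmin", "vmax")

    def __init__(self, nbins: int):
        self.mass = np.zeros(nbins, dtype=np.float64)
        self.count = np.zeros(nbins, dtype=np.int64)
        self.vmin = np.full(nbins, np.inf, dtype=np.float64)
        self.vmax = np.full(nbins, -np.inf, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.count)

    def bin(self, i: int) -> Bin:
        c = int(self.count[i])
        if c == 0:
            return Bin(0.0, 0.0, 0.0, 0)
        return Bin(float(self.mass[i] / c), float(self.vmin[i]), float(self.vmax[i]), c)


class TileStore:
    """The pyramid: per chromosome, one :class:`_LevelArrays` per level."""

    def __init__(
        self,
        genome_id: str,
        chrom_lengths: dict,
        base_bin_width: int,
        num_levels: int,
    ):
        self.genome_id = genome_id
        self.chrom_lengths = dict(chrom_lengths)
        self.base_bin_width = base_bin_width
        self.num_levels = num_levels
        self.levels: dict[str, list[_LevelArrays]] = {}
        for chrom, length in self.chrom_lengths.items():
            per_level = []
            for lvl in range(num_levels):
                w = base_bin_width * (1 << lvl)
                per_level.append(_LevelArrays(-(-length // w)))
            self.levels[chrom] = per_level

    def bin_width(self, level: int) -> int:
        return self.base_bin_width * (1 << level)


def build_store(
    signal: Sequence[SignalInterval],
    genome: GenomeModel,
    base_bin_width: int = 10,
    num_levels: int = 6,
) -> TileStore:
    """Aggregate raw signal into the pyramid.

    The finest level weights each interval's value by the bases it covers in
    each bin; coarser levels are built by exact pairwise aggregation, so the
    parent/child invariants hold to the last bit of integer count and the
    total mass sum(mean x count) is conserved across levels.
    """
    if base_bin_width < 1 or num_levels < 1:
        raise ContractError("base_bin_width and num_levels must be >= 1")
    chrom_lengths = {c.name: c.length for c in genome.chromosomes}
    store = TileStore(genome.id, chrom_lengths, base_bin_width, num_levels)
    last_end: dict[str, int] = {}
    ordered = sorted(signal, key=lambda s: (s.interval.chrom, s.interval.start))
    for s in ordered:
        chrom = s.interval.chrom
        if chrom not in store.levels:
            continue
        if s.interval.start < last_end.get(chrom, 0):
            raise ContractError(
                f"overlapping signal intervals on {chrom} at {s.interval.start}"
            )
        last_end[chrom] = s.interval.end
        finest = store.levels[chrom][0]
        start = s.interval.start
        end = min(s.interval.end, chrom_lengths[chrom])
        w = base_bin_width
        for b in range(start // w, (end - 1) // w + 1):
            covered = min(end, (b + 1) * w) - max(start, b * w)
            finest.mass[b] += s.value * covered
            finest.count[b] += covered
            finest.vmin[b] = min(finest.vmin[b], s.value)
            finest.vmax[b] = max(finest.vmax[b], s.value)
    for chrom, per_level in store.levels.items():
        for lvl in range(1, num_levels):
            child, parent = per_level[lvl - 1], per_level[lvl]
            n = len(child)
            for p in range(len(parent)):
                lo, hi = 2 * p, min(2 * p + 2, n)
                parent.mass[p] = child.mass[lo:hi].sum()
                parent.count[p] = child.count[lo:hi].sum()
                if parent.count[p] > 0:
                    covered = child.count[lo:hi] > 0
                    parent.vmin[p] = child.vmin[lo:hi][covered].min()
                    parent.vmax[p] = child.vmax[lo:hi][covered].max()
    return store


def query(
    store: TileStore, region: GenomicInterval, max_points: int
) -> list[tuple[GenomicInterval, Bin]]:
    """Bins overlapping *region* at the zoom-appropriate level.

    Chooses the coarsest level whose bin width <= span / max_points, falling
    back to the finest; only non-empty bins come back, ascending. At most
    ceil(span / width) + 1 bins are returned, so render cost is bounded by
    *max_points* regardless of region size.
    """
    if max_points < 1:
        raise ContractError("max_points must be >= 1")
    per_level = store.levels.get(region.chrom)
    if per_level is None:
        return []
    target = region.span / max_points
    level = 0
    for lvl in range(store.num_levels - 1, -1, -1):
        if store.bin_width(lvl) <= target:
            level = lvl
            break
    w = store.bin_width(level)
    arrays = per_level[level]
    chrom_len = store.chrom_lengths[region.chrom]
    out = []
    for b in range(region.start // w, min((region.end - 1) // w + 1, len(arrays))):
        if arrays.count[b] == 0:
            continue
        iv = GenomicInterval(region.chrom, b * w, min((b + 1) * w, chrom_len))
        out.append((iv, arrays.bin(b)))
    return out


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------


def _write_str(fh: BinaryIO, s: str) -> None:
    data = s.encode("utf-8")
    fh.write(struct.pack("<H", len(data)))
    fh.write(data)


def _read_exact(fh: BinaryIO, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise FormatError(f"truncated tiled signal store (wanted {n} bytes, got {len(data)})")
    return data


def _read_str(fh: BinaryIO) -> str:
    (n,) = struct.unpack("<H", _read_exact(fh, 2))
    return _read_exact(fh, n).decode("utf-8")


def save_store(store: TileStore, path) -> None:
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<H", VERSION))
        _write_str(fh, store.genome_id)
        fh.write(struct.pack("<IHH", store.base_bin_width, store.num_levels, len(store.chrom_lengths)))
        for chrom, length in store.chrom_lengths.items():
            _write_str(fh, chrom)
            fh.write(struct.pack("<Q", length))
            for arrays in store.levels[chrom]:
                fh.write(struct.pack("<Q", len(arrays)))
                fh.write(arrays.mass.astype("<f8").tobytes())
                fh.write(arrays.count.astype("<i8").tobytes())
                fh.write(arrays.vmin.astype("<f8").tobytes())
                fh.write(arrays.vmax.astype("<f8").tobytes())


def load_store(path) -> TileStore:
    with open(path, "rb") as fh:
        if _read_exact(fh, 4) != MAGIC:
            raise FormatError("not a tiled signal store (bad magic)")
        (version,) = struct.unpack("<H", _read_exact(fh, 2))
        if version != VERSION:
            raise VersionError(f"tiled signal store version {version}, expected {VERSION}")
        genome_id = _read_str(fh)
        base_bin_width, num_levels, n_chroms = struct.unpack("<IHH", _read_exact(fh, 8))
        chrom_lengths: dict[str, int] = {}
        payload: dict[str, list[_LevelArrays]] = {}
        for _ in range(n_chroms):
            chrom = _read_str(fh)
            (length,) = struct.unpack("<Q", _read_exact(fh, 8))
            chrom_lengths[chrom] = length
            per_level = []
            for _lvl in range(num_levels):
                (nbins,) = struct.unpack("<Q", _read_exact(fh, 8))
                arrays = _LevelArrays(nbins)
                arrays.mass = np.frombuffer(_read_exact(fh, 8 * nbins), dtype="<f8").copy()
                arrays.count = np.frombuffer(_read_exact(fh, 8 * nbins), dtype="<i8").copy()
                arrays.vmin = np.frombuffer(_read_exact(fh, 8 * nbins), dtype="<f8").copy()
                arrays.vmax = np.frombuffer(_read_exact(fh, 8 * nbins), dtype="<f8").copy()
                per_level.append(arrays)
            payload[chrom] = per_level
    store = TileStore(genome_id, chrom_lengths, base_bin_width, num_levels)
    store.levels = payload
    return store
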