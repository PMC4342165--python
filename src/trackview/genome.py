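"""Reference-genome model: chromosomes, coordinates, locus parsing, sequence access.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (``[start, end)``), the BED/BAM
convention. User-facing locus strings are 1-based inclusive ("chr1:1,001-2,000"),
the convention genome browsers print. The conversion happens exactly once, in
:func:`parse_locus` / :func:`format_locus`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

from .errors import (
    CapabilityError,
    LocusNotFoundError,
    MalformedLocusError,
    TrackViewError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints only
    from .formats import Feature

#: width of the window opened around a point locus ("chr1:500"); odd so the
#: queried base sits exactly in the middle.
DEFAULT_POINT_WINDOW = 41


@dataclass(frozen=True)
class Chromosome:
    """One reference sequence: a name and its length in bases."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if not self.name:
            raise TrackViewError("chromosome name must be non-empty")
        if self.length <= 0:
            raise TrackViewError(f"chromosome {self.name!r} length must be > 0")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span on a chromosome, 0-based half-open.

    The universal addressing unit: every reader, track and viewport speaks
    in these.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise TrackViewError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Intersection with *other*, or None when disjoint."""
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


class GenomeModel:
    """A genome build: ordered chromosome registry plus optional sequence and
    feature-name indexes.

    Parameters
    ----------
    genome_id:
        Build label, e.g. ``"toy1"`` or ``"hg19"``.
    chromosomes:
        Ordered chromosomes; the order defines genome-wide sorting.
    sequence_source:
        Open :class:`pysam.FastaFile` (or anything with a compatible
        ``fetch(reference, start, end)``), optional.
    aliases:
        Optional explicit name-alias table (alias -> canonical name). Matching
        is otherwise exact: silent "chr" prefix fuzzing causes coordinate bugs.
    """

    def __init__(
        self,
        genome_id: str,
        chromosomes: Iterable[Chromosome],
        sequence_source=None,
        aliases: Optional[dict] = None,
    ):
        self.id = genome_id
        self.chromosomes = list(chromosomes)
        if not self.chromosomes:
            raise TrackViewError("a genome needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise TrackViewError("duplicate chromosome names")
        self._by_name = {c.name: c for c in self.chromosomes}
        self._order = {c.name: i for i, c in enumerate(self.chromosomes)}
        self.sequence_source = sequence_source
        self.aliases = dict(aliases or {})
        self.feature_index: Optional[dict[str, list]] = None
        if sequence_source is not None:
            self._check_sequence_lengths()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_fasta(cls, path, genome_id: Optional[str] = None, aliases=None):
        """Build a genome from an indexed FASTA (creates the .fai if absent)."""
        import os

        import pysam

        fasta = pysam.FastaFile(str(path))
        chroms = [
            Chromosome(name, length)
            for name, length in zip(fasta.references, fasta.lengths)
        ]
        if genome_id is None:
            genome_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(genome_id, chroms, sequence_source=fasta, aliases=aliases)

    def _check_sequence_lengths(self) -> None:
        src = self.sequence_source
        try:
            lengths = dict(zip(src.references, src.lengths))
        except AttributeError:
            return
        for c in self.chromosomes:
            if c.name in lengths and lengths[c.name] != c.length:
                raise TrackViewError(
                    f"sequence length for {c.name} ({lengths[c.name]}) does not "
                    f"match registered chromosome length ({c.length})"
                )

    def build_feature_index(self, features: Iterable["Feature"]) -> None:
        """Index features by lower-cased name for gene-name search.

        File order is preserved per name so multi-match resolution is
        deterministic.
        """
        index: dict[str, list] = {}
        for feat in features:
            if feat.name:
                index.setdefault(feat.name.lower(), []).append(feat)
        self.feature_index = index

    # -- lookup ------------------------------------------------------------

    def chromosome(self, name: str) -> Optional[Chromosome]:
        name = self.aliases.get(name, name)
        return self._by_name.get(name)

    def chrom_order(self, name: str) -> int:
        name = self.aliases.get(name, name)
        return self._order.get(name, len(self._order))

    def clamp(self, chrom: str, start: int, end: int) -> GenomicInterval:
        """Clamp a candidate span to chromosome bounds.

        Idempotent and never widening; a span entirely beyond the chromosome
        end collapses onto its last base.
        """
        c = self.chromosome(chrom)
        if c is None:
            raise LocusNotFoundError(f"unknown chromosome {chrom!r}")
        start = max(0, min(start, c.length - 1))
        end = max(start + 1, min(end, c.length))
        return GenomicInterval(c.name, start, end)


# -- locus text ------------------------------------------------------------


def parse_locus(
    text: str,
    genome: GenomeModel,
    point_window: int = DEFAULT_POINT_WINDOW,
) -> GenomicInterval:
    """Resolve search-box text to an interval.

    Accepted forms, tried in order:

    * ``chrom:start-end`` — 1-based inclusive, commas permitted;
    * ``chrom:pos`` — a window of ``point_window`` bases centred on ``pos``;
    * ``chrom`` — the whole chromosome;
    * anything else — gene/feature name lookup (:func:`lookup_feature`).

    The result is clamped to chromosome bounds.
    """
    text = text.strip()
    if not text:
        raise MalformedLocusError("empty locus text")

    def fall_through():
        # unknown chromosome: last chance is the feature-name index; without
        # one the query is simply not found
        try:
            return lookup_feature(text, genome)
        except CapabilityError:
            raise LocusNotFoundError(f"locus or feature {text!r} not found") from None

    if ":" in text:
        chrom_part, _, coord_part = text.partition(":")
        chrom = genome.chromosome(chrom_part.strip())
        if chrom is None:
            return fall_through()
        coord_part = coord_part.replace(",", "").strip()
        if "-" in coord_part:
            s_txt, _, e_txt = coord_part.partition("-")
            try:
                start1, end1 = int(s_txt), int(e_txt)
            except ValueError:
                raise MalformedLocusError(f"malformed locus {text!r}") from None
            if start1 > end1:
                raise MalformedLocusError(
                    f"locus {text!r}: start {start1} > end {end1}"
                )
            return genome.clamp(chrom.name, start1 - 1, end1)
        try:
            pos1 = int(coord_part)
        except ValueError:
            raise MalformedLocusError(f"malformed locus {text!r}") from None
        half = point_window // 2
        return genome.clamp(chrom.name, pos1 - 1 - half, pos1 - 1 - half + point_window)
    chrom = genome.chromosome(text)
    if chrom is not None:
        return GenomicInterval(chrom.name, 0, chrom.length)
    return fall_through()


def format_locus(interval: GenomicInterval) -> str:
    """Render an interval as user-facing 1-based inclusive text with commas."""
    return f"{interval.chrom}:{interval.start + 1:,}-{interval.end:,}"


def lookup_feature(name: str, genome: GenomeModel) -> GenomicInterval:
    """Case-insensitive exact feature-name lookup.

    Several features may share a name (e.g. multi-exon gene rows); the result
    is the union span on the chromosome holding the first match in file order
    — deterministic without interactive disambiguation.
    """
    if genome.feature_index is None:
        raise CapabilityError("genome has no feature index for name search")
    matches = genome.feature_index.get(name.strip().lower())
    if not matches:
        raise LocusNotFoundError(f"locus or feature {name!r} not found")
    chrom = matches[0].interval.chrom
    same = [f.interval for f in matches if f.interval.chrom == chrom]
    start = min(iv.start for iv in same)
    end = max(iv.end for iv in same)
    return genome.clamp(chrom, start, end)


def fetch_reference(interval: GenomicInterval, genome: GenomeModel) -> str:
    """Reference bases for *interval*, uppercase, alphabet {A,C,G,T,N}."""
    if genome.sequence_source is None:
        raise CapabilityError("genome has no sequence source")
    c = genome.chromosome(interval.chrom)
    if c is None or interval.start < 0 or interval.end > c.length:
        raise TrackViewError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            "outside chromosome bounds"
        )
    seq = genome.sequence_source.fetch(c.name, interval.start, interval.end)
    return seq.upper()
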