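"""Deterministic synthetic-data generator.

Produces a toy genome and every supported track file type with *planted*,
known structure — a heterozygous-like SNV at a chosen allele fraction, a
spliced junction with a known number of supporting reads, a piecewise-
constant signal, a copy-number design with a designated strongest-deletion
sample — so every module is testable end to end without any downloads.
Read names encode their true origin (start position, planted-event tags),
making the fixtures self-validating.

All randomness flows through one seeded numpy generator; the same spec and
seed reproduce byte-identical text outputs on any platform.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import TrackViewError
from .formats import (
    AlignedRead,
    Feature,
    Segment,
    SignalInterval,
    parse_cigar,
    sam_to_indexed_bam,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_sam,
    write_seg,
    write_wig,
)
from .genome import GenomicInterval
from .session import Session, TrackSpec, serialize_link, session_to_json


@dataclass(frozen=True)
class PlantedSNV:
    """A single-nucleotide variant planted into a known fraction of reads.

    ``alt`` may be None, in which case the alternate base is picked as the
    next base after the reference in ACGT order once the genome exists.
    """

    chrom: str
    position: int  # 0-based
    fraction: float
    alt: Optional[str] = None

    def __post_init__(self):
        if not 0 < self.fraction < 1:
            raise TrackViewError("SNV fraction must be in (0, 1)")


@dataclass(frozen=True)
class PlantedJunction:
    """A spliced junction: reads align M-N-M across [donor, acceptor)."""

    chrom: str
    donor: int  # 0-based exon/intron boundary
    acceptor: int  # 0-based intron/exon boundary
    supporting_reads: int = 12


@dataclass
class FixtureSpec:
    """Everything the generator needs, with study-scale defaults.

    Defaults give ~30x read depth over a 20 kb + 8 kb two-chromosome toy
    genome, a 30% and a 10% allele-fraction SNV, one spliced junction, a
    stepped signal profile, and a 5-sample copy-number design whose sample
    S3 carries the strongest deletion.
    """

    seed: int = 0
    genome_id: str = "toy1"
    chrom_lengths: dict = field(default_factory=lambda: {"chrA": 20_000, "chrB": 8_000})
    read_length: int = 50
    depth: float = 30.0
    snvs: list = field(
        default_factory=lambda: [
            PlantedSNV("chrA", 5_000, 0.30),
            PlantedSNV("chrA", 7_000, 0.10),
        ]
    )
    junction: Optional[PlantedJunction] = field(
        default_factory=lambda: PlantedJunction("chrA", 10_000, 10_600, 12)
    )
    #: (chrom, start, end, value) piecewise-constant signal levels
    signal_levels: list = field(
        default_factory=lambda: [
            ("chrA", 0, 4_000, 1.0),
            ("chrA", 4_000, 8_000, 3.0),
            ("chrA", 8_000, 12_000, 0.5),
            ("chrA", 12_000, 20_000, 2.0),
            ("chrB", 0, 8_000, 1.5),
        ]
    )
    #: sample -> list of (chrom, start, end, log2 ratio); S3 planted deletion
    cn_design: dict = field(
        default_factory=lambda: {
            "S1": [("chrA", 0, 10_000, 0.1), ("chrA", 10_000, 20_000, -0.2)],
            "S2": [("chrA", 0, 20_000, 0.8)],
            "S3": [("chrA", 2_000, 18_000, -2.0)],
            "S4": [("chrA", 0, 20_000, -0.5)],
            "S5": [("chrA", 0, 20_000, 1.4)],
        }
    )
    #: (name, chrom, start, end, strand) gene annotations
    features: list = field(
        default_factory=lambda: [
            ("GENE1", "chrA", 4_800, 5_400, "+"),
            ("GENE2", "chrA", 9_800, 10_900, "-"),
            ("GENE2", "chrA", 11_000, 11_400, "-"),
            ("GENE3", "chrB", 1_000, 2_000, "+"),
        ]
    )
    #: two-level base-quality model: (high_q, low_q, probability_of_high)
    quality_model: tuple = (30, 12, 0.9)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        doc = json.loads(text)
        spec = cls()
        for key, value in doc.items():
            if not hasattr(spec, key):
                raise TrackViewError(f"unknown fixture spec field {key!r}")
            setattr(spec, key, value)
        if spec.snvs and isinstance(spec.snvs[0], (list, dict)):
            spec.snvs = [
                PlantedSNV(**s) if isinstance(s, dict) else PlantedSNV(*s)
                for s in spec.snvs
            ]
        if spec.junction and isinstance(spec.junction, (list, dict)):
            j = spec.junction
            spec.junction = PlantedJunction(**j) if isinstance(j, dict) else PlantedJunction(*j)
        return spec


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_genome(spec: FixtureSpec, outdir) -> str:
    """Seeded uniform-random genome; writes FASTA + .fai, returns the path."""
    rng = np.random.default_rng(spec.seed)
    sequences = {}
    for chrom, length in spec.chrom_lengths.items():
        idx = rng.integers(0, 4, size=length)
        sequences[chrom] = "".join(np.array(list("ACGT"))[idx])
    path = os.path.join(outdir, f"{spec.genome_id}.fa")
    write_fasta(sequences, path)
    return path


def _load_sequences(fasta_path: str) -> dict:
    import pysam

    fa = pysam.FastaFile(fasta_path)
    try:
        return {name: fa.fetch(name).upper() for name in fa.references}
    finally:
        fa.close()


def make_reads(spec: FixtureSpec, fasta_path: str, outdir) -> tuple:
    """Simulate reads and write SAM plus a sorted, indexed BAM.

    Plain reads copy the reference exactly (so zero mismatches without
    planted events). At each planted SNV, ``round(fraction x covering)``
    covering reads carry the alternate base — within one read of the exact
    requested fraction. Junction-supporting reads carry M-N-M CIGARs spanning
    the planted gap. Base qualities come from the two-level quality model.

    Returns ``(sam_path, bam_path)``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sequences = _load_sequences(fasta_path)
    rl = spec.read_length
    hi_q, lo_q, p_hi = spec.quality_model
    reads: list[AlignedRead] = []

    def quals(n: int) -> tuple:
        return tuple(int(hi_q) if u < p_hi else int(lo_q) for u in rng.random(n))

    for chrom, seq in sequences.items():
        length = len(seq)
        n_reads = int(round(spec.depth * length / rl))
        starts = np.sort(rng.integers(0, length - rl + 1, size=n_reads))
        for i, start in enumerate(starts):
            start = int(start)
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                AlignedRead(
                    name=f"rd_{chrom}_{start}_{i}",
                    chrom=chrom,
                    start=start,
                    strand=strand,
                    cigar=(("M", rl),),
                    bases=seq[start : start + rl],
                    quals=quals(rl),
                    mapping_quality=60,
                )
            )

    # plant SNVs into exactly round(fraction * covering) plain reads
    for snv in spec.snvs:
        seq = sequences[snv.chrom]
        ref_base = seq[snv.position]
        alt = snv.alt or "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        if alt == ref_base:
            raise TrackViewError(f"SNV alt base equals reference at {snv.position}")
        covering = [
            i
            for i, r in enumerate(reads)
            if r.chrom == snv.chrom and r.start <= snv.position < r.start + rl
        ]
        n_alt = int(round(snv.fraction * len(covering)))
        chosen = rng.choice(len(covering), size=n_alt, replace=False)
        for ci in chosen:
            i = covering[int(ci)]
            r = reads[i]
            off = snv.position - r.start
            reads[i] = AlignedRead(
                name=r.name + f"_snv{snv.position}{alt}",
                chrom=r.chrom,
                start=r.start,
                strand=r.strand,
                cigar=r.cigar,
                bases=r.bases[:off] + alt + r.bases[off + 1 :],
                quals=r.quals,
                mapping_quality=r.mapping_quality,
            )

    # junction-supporting spliced reads: aM gN bM with a+b = read length
    if spec.junction is not None:
        j = spec.junction
        seq = sequences[j.chrom]
        gap = j.acceptor - j.donor
        if gap <= 0:
            raise TrackViewError("junction acceptor must lie beyond donor")
        for i in range(j.supporting_reads):
            a = int(rng.integers(10, rl - 9))
            b = rl - a
            start = j.donor - a
            bases = seq[start : j.donor] + seq[j.acceptor : j.acceptor + b]
            reads.append(
                AlignedRead(
                    name=f"junc_{j.chrom}_{start}_{i}",
                    chrom=j.chrom,
                    start=start,
                    strand="+",
                    cigar=(("M", a), ("N", gap), ("M", b)),
                    bases=bases,
                    quals=quals(rl),
                    mapping_quality=60,
                )
            )

    sam_path = os.path.join(outdir, "reads.sam")
    write_sam(reads, spec.chrom_lengths, sam_path)
    bam_path = sam_to_indexed_bam(sam_path, os.path.join(outdir, "reads.bam"))
    return sam_path, bam_path


def make_signal(spec: FixtureSpec, outdir) -> tuple:
    """Write the piecewise-constant signal as both WIG and bedGraph."""
    signal = [
        SignalInterval(GenomicInterval(chrom, start, end), float(value))
        for chrom, start, end, value in spec.signal_levels
    ]
    wig_path = os.path.join(outdir, "signal.wig")
    bg_path = os.path.join(outdir, "signal.bedgraph")
    write_wig(signal, wig_path)
    write_bedgraph(signal, bg_path)
    return wig_path, bg_path


def make_segments(spec: FixtureSpec, outdir) -> str:
    """Write the copy-number design as a SEG file, one row per segment."""
    segments = [
        Segment(sample, GenomicInterval(chrom, start, end), float(value))
        for sample, segs in spec.cn_design.items()
        for chrom, start, end, value in segs
    ]
    path = os.path.join(outdir, "cn.seg")
    write_seg(segments, path)
    return path


def make_features(spec: FixtureSpec, outdir) -> str:
    feats = [
        Feature(GenomicInterval(chrom, start, end), name, None, strand)
        for name, chrom, start, end, strand in spec.features
    ]
    path = os.path.join(outdir, "genes.bed")
    write_bed(feats, path)
    return path


def write_fixture_dir(spec: FixtureSpec, outdir) -> dict:
    """Generate the complete fixture set and return a path map.

    Writes FASTA(+fai), SAM, sorted+indexed BAM, BED, WIG, bedGraph, SEG, a
    JSON session file, and a launch link (link.txt) pointing the initial view
    at the first planted SNV.
    """
    os.makedirs(outdir, exist_ok=True)
    fasta = make_genome(spec, outdir)
    sam, bam = make_reads(spec, fasta, outdir)
    wig, bedgraph = make_signal(spec, outdir)
    seg = make_segments(spec, outdir)
    bed = make_features(spec, outdir)
    if spec.snvs:
        focus = spec.snvs[0]
        lo, hi = max(0, focus.position - 200), focus.position + 200
        locus = f"{focus.chrom}:{lo + 1:,}-{hi:,}"
    else:
        chrom = next(iter(spec.chrom_lengths))
        locus = chrom
    # track paths are relative to the fixture directory, so the whole
    # directory stays relocatable and seed-reproducible byte for byte
    session = Session(
        genome_id=spec.genome_id,
        locus_text=locus,
        tracks=(
            TrackSpec(os.path.basename(bam), "reads"),
            TrackSpec(os.path.basename(bed), "genes"),
            TrackSpec(os.path.basename(bedgraph), "signal"),
            TrackSpec(os.path.basename(seg), "copy number"),
        ),
    )
    session_path = os.path.join(outdir, "session.json")
    with open(session_path, "w") as fh:
        fh.write(session_to_json(session))
    link = serialize_link(session, "trackview://launch")
    link_path = os.path.join(outdir, "link.txt")
    with open(link_path, "w") as fh:
        fh.write(link + "\n")
    return {
        "fasta": fasta,
        "sam": sam,
        "bam": bam,
        "bed": bed,
        "wig": wig,
        "bedgraph": bedgraph,
        "seg": seg,
        "session": session_path,
        "link": link_path,
    }
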