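"""Shared fixtures: small synthetic datasets generated once per session."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from trackview.fixtures import (
    FixtureSpec,
    PlantedJunction,
    PlantedSNV,
    write_fixture_dir,
)
from trackview.formats import AlignedRead, parse_cigar, read_features
from trackview.genome import GenomeModel


def small_spec(seed: int = 0) -> FixtureSpec:
    """A scaled-down fixture: ~50x depth over a 3 kb + 1.2 kb toy genome,
    with the same planted-event structure as the defaults."""
    return FixtureSpec(
        seed=seed,
        genome_id="toy1",
        chrom_lengths={"chrA": 3_000, "chrB": 1_200},
        read_length=50,
        depth=50.0,
        snvs=[PlantedSNV("chrA", 1_500, 0.30), PlantedSNV("chrA", 2_200, 0.10)],
        junction=PlantedJunction("chrA", 700, 1_000, 10),
        signal_levels=[
            ("chrA", 0, 1_000, 1.0),
            ("chrA", 1_000, 2_000, 3.0),
            ("chrA", 2_000, 3_000, 0.5),
            ("chrB", 0, 1_200, 1.5),
        ],
        cn_design={
            "S1": [("chrA", 0, 1_500, 0.1), ("chrA", 1_500, 3_000, -0.2)],
            "S2": [("chrA", 0, 3_000, 0.8)],
            "S3": [("chrA", 200, 2_800, -2.0)],
            "S4": [("chrA", 0, 3_000, -0.5)],
            "S5": [("chrA", 0, 3_000, 1.4)],
        },
        features=[
            ("GENE1", "chrA", 1_400, 1_700, "+"),
            ("GENE2", "chrA", 600, 1_100, "-"),
            ("GENE2", "chrA", 1_150, 1_300, "-"),
            ("GENE3", "chrB", 100, 400, "+"),
        ],
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Complete generated fixture directory (FASTA/BAM/BED/WIG/bedGraph/SEG)."""
    out = tmp_path_factory.mktemp("fixture")
    spec = small_spec()
    paths = write_fixture_dir(spec, str(out))
    paths["spec"] = spec
    return paths


@pytest.fixture(scope="session")
def toy_genome(fixture_dir):
    genome = GenomeModel.from_fasta(
        fixture_dir["fasta"], genome_id=fixture_dir["spec"].genome_id
    )
    genome.build_feature_index(read_features(fixture_dir["bed"]))
    return genome


def make_read(
    name="r", chrom="chrA", start=0, cigar="10M", bases=None, quals=None, strand="+"
):
    """Terse AlignedRead builder for unit tests."""
    ops = parse_cigar(cigar)
    qlen = sum(n for op, n in ops if op in "MIS=X")
    if bases is None:
        bases = "A" * qlen
    if quals is None:
        quals = (30,) * qlen
    return AlignedRead(name, chrom, start, strand, ops, bases, tuple(quals))
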