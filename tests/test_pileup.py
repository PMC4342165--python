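"""Pileup analytics: coverage, mismatch marking, downsampling, sorting, packing."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    brute_force_pileup,
    max_overlap_depth,
    overlap_aligned_length,
)
from trackview.errors import ContractError
from trackview.genome import GenomicInterval
from trackview.pileup import (
    DownsampleConfig,
    compute_pileup,
    downsample,
    mark_mismatches,
    pack_rows,
    pileup_to_tsv,
    sort_reads_by_base,
)

from conftest import make_read


def _random_reads(rng, n, lo=0, hi=500):
    """Reads with random positions and mixed CIGAR shapes (M, D, N, I, S)."""
    shapes = ["30M", "10M5D15M", "10M40N10M", "5S20M", "10M2I10M", "8M100N8M2D6M"]
    reads = []
    for i in range(n):
        start = rng.randrange(lo, hi)
        cigar = rng.choice(shapes)
        bases = "".join(rng.choice("ACGT") for _ in range(30))
        reads.append(
            make_read(f"r{i}", start=start, cigar=cigar, bases=None)
            if cigar == "30M"
            else make_read(f"r{i}", start=start, cigar=cigar)
        )
    reads.sort(key=lambda r: r.start)
    return reads


class TestComputePileup:
    def test_two_overlapping_reads_stack(self):
        reads = [
            make_read("a", start=100, cigar="10M"),
            make_read("b", start=105, cigar="10M"),
        ]
        iv = GenomicInterval("chrA", 100, 115)
        cov = compute_pileup(reads, iv, "A" * 15)
        assert list(cov.depth) == [1] * 5 + [2] * 5 + [1] * 5

    def test_no_reads_gives_zero_columns(self):
        iv = GenomicInterval("chrA", 0, 10)
        cov = compute_pileup([], iv, "A" * 10)
        assert not cov.depth.any()

    def test_splice_gap_contributes_no_coverage(self):
        read = make_read("s", start=100, cigar="20M100N20M")
        iv = GenomicInterval("chrA", 100, 240)
        cov = compute_pileup([read], iv, "A" * 140)
        d = cov.depth
        assert list(d[:20]) == [1] * 20
        assert not d[20:120].any()
        assert list(d[120:140]) == [1] * 20

    def test_deletion_counts_in_depth_but_not_bases(self):
        read = make_read("d", start=0, cigar="5M2D5M")
        iv = GenomicInterval("chrA", 0, 12)
        cov = compute_pileup([read], iv, "A" * 12)
        col = cov.column(5)
        assert col.depth == 1 and col.deletion_count == 1
        assert sum(col.base_counts.values()) == 0

    def test_reference_length_mismatch_is_contract_error(self):
        with pytest.raises(ContractError):
            compute_pileup([], GenomicInterval("chrA", 0, 10), "AC")

    def test_matches_brute_force_oracle_on_random_reads(self):
        rng = random.Random(7)
        reads = _random_reads(rng, 80)
        iv = GenomicInterval("chrA", 50, 450)
        cov = compute_pileup(reads, iv, "A" * 400)
        depth, counts, deletions = brute_force_pileup(reads, "chrA", 50, 450)
        assert list(cov.depth) == depth
        assert list(cov.deletions) == deletions
        for j, b in enumerate("ACGTN"):
            assert list(cov.base_counts[j]) == counts[b]

    def test_depth_conservation_over_randomized_fixtures(self):
        """Sum of column depths equals summed per-read overlap, exactly."""
        for seed in range(30):
            rng = random.Random(seed)
            reads = _random_reads(rng, 25)
            iv = GenomicInterval("chrA", 100, 400)
            cov = compute_pileup(reads, iv, "N" * 300)
            total = sum(overlap_aligned_length(r, 100, 400) for r in reads)
            assert int(cov.depth.sum()) == total


class TestMarkMismatches:
    def _cov(self, bases_by_read, ref):
        reads = [
            make_read(f"r{i}", start=0, cigar=f"{len(b)}M", bases=b)
            for i, b in enumerate(bases_by_read)
        ]
        iv = GenomicInterval("chrA", 0, len(ref))
        return compute_pileup(reads, iv, ref)

    def test_one_third_alt_marked_at_point_two(self):
        cov = self._cov(["A", "A", "G"], "A")
        (mark,) = mark_mismatches(cov, "A", min_fraction=0.2)
        assert mark.position == 0
        assert mark.total_mismatch_fraction == pytest.approx(1 / 3)
        assert mark.fractions == {"G": pytest.approx(1 / 3)}

    def test_ten_percent_not_marked_at_point_two(self):
        cov = self._cov(["A"] * 9 + ["G"], "A")
        assert mark_mismatches(cov, "A", min_fraction=0.2) == []

    def test_all_matching_yields_no_marks(self):
        cov = self._cov(["ACGT"] * 5, "ACGT")
        assert mark_mismatches(cov, "ACGT", min_fraction=0.01) == []

    def test_n_in_read_or_reference_is_not_evidence(self):
        cov = self._cov(["N", "N", "A"], "A")
        assert mark_mismatches(cov, "A", min_fraction=0.1) == []
        cov2 = self._cov(["G", "G"], "N")
        assert mark_mismatches(cov2, "N", min_fraction=0.1) == []

    def test_min_depth_filters_shallow_columns(self):
        cov = self._cov(["G"], "A")
        assert mark_mismatches(cov, "A", 0.2, min_depth=2) == []

    @given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_min_fraction(self, f1, f2):
        """Raising the threshold never adds marks."""
        lo, hi = sorted((f1, f2))
        cov = self._cov(["AG", "GG", "GA", "AA", "GT"], "AA")
        at_lo = {m.position for m in mark_mismatches(cov, "AA", lo)}
        at_hi = {m.position for m in mark_mismatches(cov, "AA", hi)}
        assert at_hi <= at_lo


class TestDownsample:
    region = GenomicInterval("chrA", 0, 1_000)

    def test_under_capacity_keeps_everything(self):
        reads = [make_read(f"r{i}", start=i, cigar="10M") for i in range(5)]
        cfg = DownsampleConfig(window_bp=50, max_reads_per_window=10, seed=1)
        assert downsample(reads, self.region, cfg) == reads

    def test_windows_are_independent(self):
        reads = [make_read(f"r{i}", start=i * 60, cigar="10M") for i in range(6)]
        cfg = DownsampleConfig(window_bp=50, max_reads_per_window=10, seed=1)
        assert downsample(reads, self.region, cfg) == reads

    def test_over_capacity_keeps_exactly_k_deterministically(self):
        reads = [make_read(f"r{i}", start=5, cigar="10M") for i in range(100)]
        cfg = DownsampleConfig(window_bp=50, max_reads_per_window=20, seed=3)
        kept1 = downsample(reads, self.region, cfg)
        kept2 = downsample(reads, self.region, cfg)
        assert len(kept1) == 20 and kept1 == kept2
        other = downsample(reads, self.region, DownsampleConfig(50, 20, 4))
        assert [r.name for r in other] != [r.name for r in kept1]

    def test_output_preserves_start_order(self):
        rng = random.Random(0)
        reads = sorted(
            (make_read(f"r{i}", start=rng.randrange(200), cigar="5M") for i in range(300)),
            key=lambda r: r.start,
        )
        cfg = DownsampleConfig(window_bp=50, max_reads_per_window=10, seed=0)
        kept = downsample(reads, self.region, cfg)
        assert [r.start for r in kept] == sorted(r.start for r in kept)

    def test_unsorted_input_is_a_contract_error(self):
        reads = [make_read("a", start=10), make_read("b", start=0)]
        with pytest.raises(ContractError):
            downsample(reads, self.region, DownsampleConfig())

    def test_reservoir_inclusion_is_uniform(self):
        """Each of n=200 reads lands in the k=20 reservoir with frequency
        k/n = 0.1 (checked over 400 seeds at a generous binomial band)."""
        reads = [make_read(f"r{i}", start=0, cigar="5M") for i in range(200)]
        hits = {r.name: 0 for r in reads}
        trials = 400
        for seed in range(trials):
            cfg = DownsampleConfig(window_bp=50, max_reads_per_window=20, seed=seed)
            kept = downsample(reads, self.region, cfg)
            assert len(kept) == 20
            for r in kept:
                hits[r.name] += 1
        freqs = np.array(list(hits.values())) / trials
        # 4.5 sigma band for Binomial(400, 0.1)
        tol = 4.5 * np.sqrt(0.1 * 0.9 / trials)
        assert np.all(np.abs(freqs - 0.1) < tol)

    def test_coverage_is_independent_of_downsampling(self):
        """The coverage chart is computed before reads are discarded, so the
        pileup of all reads is byte-identical whether or not the displayed
        set was thinned."""
        rng = random.Random(11)
        reads = _random_reads(rng, 150, hi=300)
        iv = GenomicInterval("chrA", 0, 500)
        tsv_before = pileup_to_tsv(compute_pileup(reads, iv, "N" * 500))
        downsample(reads, iv, DownsampleConfig(50, 3, 0))
        tsv_after = pileup_to_tsv(compute_pileup(reads, iv, "N" * 500))
        assert tsv_before == tsv_after


class TestSortReadsByBase:
    def test_variant_reads_float_to_the_top(self):
        ref = "A"
        bases = ["G", "A", "G", "A", "A"]
        reads = [
            make_read(f"r{i}", start=0, cigar="1M", bases=b)
            for i, b in enumerate(bases)
        ]
        ordered = sort_reads_by_base(reads, 0, ref)
        assert [r.bases for r in ordered] == ["G", "G", "A", "A", "A"]
        assert [r.name for r in ordered[:2]] == ["r0", "r2"]  # stable

    def test_all_reference_preserves_input_order(self):
        reads = [make_read(f"r{i}", start=0, cigar="1M", bases="A") for i in range(4)]
        assert sort_reads_by_base(reads, 0, "A") == reads

    def test_minor_variant_groups_order_by_count_then_alphabet(self):
        bases = ["T", "G", "G", "C", "A"]
        reads = [
            make_read(f"r{i}", start=0, cigar="1M", bases=b)
            for i, b in enumerate(bases)
        ]
        ordered = sort_reads_by_base(reads, 0, "A")
        assert [r.bases for r in ordered] == ["G", "G", "C", "T", "A"]

    def test_spliced_and_deleted_reads_sink(self):
        spliced = make_read("s", start=0, cigar="1M5N1M", bases="AA")
        deleted = make_read("d", start=0, cigar="1M1D1M", bases="AA")
        plain = make_read("p", start=1, cigar="1M", bases="A")
        ordered = sort_reads_by_base([spliced, deleted, plain], 1, "A")
        assert [r.name for r in ordered] == ["p", "d", "s"]


class TestPackRows:
    def test_first_fit_trace(self):
        items = [(0, 10), (5, 15), (12, 20)]
        assert pack_rows(items, min_gap_bp=1) == [0, 1, 0]

    def test_disjoint_reads_share_row_zero(self):
        assert pack_rows([(0, 5), (10, 15), (20, 25)]) == [0, 0, 0]

    def test_k_mutually_overlapping_reads_need_k_rows(self):
        items = [(i, 100 + i) for i in range(7)]
        rows = pack_rows(items, min_gap_bp=0)
        assert sorted(rows) == list(range(7))

    def test_unsorted_input_is_a_contract_error(self):
        with pytest.raises(ContractError):
            pack_rows([(10, 20), (0, 5)])

    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_zero_gap_packing_is_optimal(self, raw):
        """First-fit on start-sorted intervals uses exactly max-overlap-depth
        rows (greedy colouring of an interval graph is optimal)."""
        spans = sorted((s, s + l) for s, l in raw)
        rows = pack_rows(spans, min_gap_bp=0)
        assert max(rows) + 1 == max_overlap_depth(spans)


def test_tsv_export_positions_are_one_based():
    read = make_read("r", start=4, cigar="2M", bases="AC")
    iv = GenomicInterval("chrA", 4, 6)
    tsv = pileup_to_tsv(compute_pileup([read], iv, "AC"))
    lines = tsv.strip().split("\n")
    assert lines[1].startswith("5\t1\t1") and lines[2].startswith("6\t1\t0\t1")
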