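"""Track layout semantics: glyph generation, colors, sorting, visibility gating."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackview.formats import Feature, Segment, SignalInterval
from trackview.genome import GenomicInterval
from trackview.pileup import compute_pileup, mark_mismatches, pack_rows
from trackview.tracks import (
    CnColorScale,
    QualityOpacityPolicy,
    Viewport,
    cn_value_to_color,
    layout_alignment_track,
    layout_coverage_track,
    layout_feature_track,
    layout_numeric_track,
    layout_segment_track,
    should_load_alignments,
    sort_samples,
)

from conftest import make_read


def vp(start=0, end=1000, width=1000, chrom="chrA"):
    return Viewport(GenomicInterval(chrom, start, end), width)


class TestVisibilityGate:
    def test_small_span_loads(self):
        assert should_load_alignments(vp(0, 10_000), threshold_bp=30_000)

    def test_boundary_span_loads(self):
        assert should_load_alignments(vp(0, 30_000), threshold_bp=30_000)

    def test_one_past_threshold_does_not(self):
        assert not should_load_alignments(vp(0, 30_001), threshold_bp=30_000)


class TestPixelMapping:
    @given(st.integers(0, 999), st.integers(0, 999))
    @settings(max_examples=80, derandomize=True)
    def test_affine_and_order_preserving(self, a, b):
        v = vp(0, 1000, 640)
        if a > b:
            a, b = b, a
        assert v.x(a) <= v.x(b)

    def test_roundtrip_error_below_one_pixel_unit(self):
        v = vp(100, 5100, 500)  # 10 bases per pixel
        for pos in (100, 1234, 5099):
            back = v.interval.start + v.x(pos) * v.bases_per_pixel
            assert abs(back - pos) < v.bases_per_pixel


class TestAlignmentLayout:
    def test_matching_read_is_one_grey_body(self):
        read = make_read("r", start=10, cigar="10M", bases="A" * 10)
        glyphs = layout_alignment_track([read], [0], vp(0, 100, 100), "A" * 100)
        roles = [g.style_role for g in glyphs]
        assert roles == ["read_body"]

    def test_mismatch_rect_carries_base_role_and_full_opacity(self):
        read = make_read("r", start=0, cigar="3M", bases="AGA", quals=(30, 30, 30))
        glyphs = layout_alignment_track([read], [0], vp(0, 100, 100), "A" * 100)
        mism = [g for g in glyphs if g.style_role.startswith("mismatch")]
        assert len(mism) == 1
        assert mism[0].style_role == "mismatch_base_G" and mism[0].opacity == 1.0

    def test_low_quality_mismatch_fades_but_never_vanishes(self):
        policy = QualityOpacityPolicy(q_lo=5, q_hi=20, min_opacity=0.1)
        read = make_read("r", start=0, cigar="1M", bases="G", quals=(2,))
        (mism,) = [
            g
            for g in layout_alignment_track(
                [read], [0], vp(0, 10, 100), "A" * 10, policy
            )
            if g.style_role.startswith("mismatch")
        ]
        assert mism.opacity == 0.1
        mid = make_read("r", start=0, cigar="1M", bases="G", quals=(12,))
        (g,) = [
            g
            for g in layout_alignment_track([mid], [0], vp(0, 10, 100), "A" * 10, policy)
            if g.style_role.startswith("mismatch")
        ]
        assert g.opacity == pytest.approx((12 - 5) / 15)

    def test_spliced_read_draws_two_bodies_and_a_connector(self):
        read = make_read("r", start=100, cigar="20M100N20M", bases="A" * 40)
        v = vp(0, 400, 400)
        glyphs = layout_alignment_track([read], [0], v, "A" * 400)
        bodies = [g for g in glyphs if g.style_role == "read_body"]
        connectors = [g for g in glyphs if g.style_role == "splice_connector"]
        assert len(bodies) == 2 and len(connectors) == 1
        c = connectors[0]
        assert (c.x, c.x + c.w) == (v.x(120), v.x(220))  # spans the gap

    def test_deletion_is_a_line_without_body(self):
        read = make_read("r", start=0, cigar="5M2D5M", bases="A" * 10)
        glyphs = layout_alignment_track([read], [0], vp(0, 20, 100), "A" * 20)
        roles = sorted(g.style_role for g in glyphs)
        assert roles == ["deletion_gap", "read_body", "read_body"]

    def test_n_bases_never_highlighted(self):
        read = make_read("r", start=0, cigar="2M", bases="NG", quals=(30, 30))
        glyphs = layout_alignment_track([read], [0], vp(0, 10, 100), "AN" + "A" * 8)
        assert not any(g.style_role.startswith("mismatch") for g in glyphs)


class TestCoverageLayout:
    def _cov(self, bases_by_read, ref):
        reads = [
            make_read(f"r{i}", start=0, cigar=f"{len(b)}M", bases=b)
            for i, b in enumerate(bases_by_read)
        ]
        iv = GenomicInterval("chrA", 0, len(ref))
        return compute_pileup(reads, iv, ref), iv

    def test_uniform_depth_gives_equal_bars(self):
        cov, iv = self._cov(["AAAA", "AAAA"], "AAAA")
        glyphs = layout_coverage_track(cov, [], Viewport(iv, 4), height_px=60)
        assert len(glyphs) == 4
        assert len({g.h for g in glyphs}) == 1

    def test_marked_column_splits_proportionally(self):
        cov, iv = self._cov(["A", "A", "G"], "A")
        marks = mark_mismatches(cov, "A", 0.2)
        glyphs = layout_coverage_track(cov, marks, Viewport(iv, 1), height_px=60)
        portions = [g for g in glyphs if g.style_role == "coverage_mismatch_portion"]
        assert len(portions) == 2
        by_base = {g.payload: g.h for g in portions}
        assert by_base["A"] / by_base["G"] == pytest.approx(2.0)

    def test_empty_region_draws_nothing(self):
        cov, iv = self._cov([], "AAAA")
        assert layout_coverage_track(cov, [], Viewport(iv, 4)) == []

    def test_subpixel_aggregation_uses_max_depth(self):
        reads = [make_read("a", start=0, cigar="1M", bases="A")] * 3 + [
            make_read("b", start=1, cigar="1M", bases="A")
        ]
        iv = GenomicInterval("chrA", 0, 2)
        cov = compute_pileup(reads, iv, "AA")
        (bar,) = layout_coverage_track(cov, [], Viewport(iv, 1), height_px=60)
        assert bar.h == 60  # peak (depth 3) preserved, not mean


class TestNumericLayout:
    def test_heights_are_linear_in_value(self):
        sig = [
            SignalInterval(GenomicInterval("chrA", i * 10, (i + 1) * 10), v)
            for i, v in enumerate([1.0, 2.0, 4.0])
        ]
        glyphs = layout_numeric_track(sig, vp(0, 30, 300), height_px=80)
        hs = [g.h for g in glyphs]
        assert hs[1] / hs[0] == pytest.approx(2.0)
        assert hs[2] / hs[0] == pytest.approx(4.0)

    def test_all_zero_values_draw_zero_height(self):
        sig = [SignalInterval(GenomicInterval("chrA", 0, 10), 0.0)]
        (g,) = layout_numeric_track(sig, vp(0, 10, 100))
        assert g.h == 0

    def test_negative_values_hang_below_a_symmetric_baseline(self):
        sig = [
            SignalInterval(GenomicInterval("chrA", 0, 10), 2.0),
            SignalInterval(GenomicInterval("chrA", 10, 20), -2.0),
        ]
        up, down = layout_numeric_track(sig, vp(0, 20, 100), height_px=100)
        assert up.y == pytest.approx(0.0) and up.h == pytest.approx(50.0)
        assert down.y == pytest.approx(50.0) and down.h == pytest.approx(50.0)

    def test_fixed_range_overrides_autoscale(self):
        sig = [SignalInterval(GenomicInterval("chrA", 0, 10), 1.0)]
        (g,) = layout_numeric_track(sig, vp(0, 10, 100), height_px=100, fixed_range=(0, 4))
        assert g.h == pytest.approx(25.0)


class TestCnColors:
    def test_zero_is_neutral(self):
        assert cn_value_to_color(0.0) == (255, 255, 255)

    def test_saturation_at_cap(self):
        scale = CnColorScale(cap=1.5)
        assert cn_value_to_color(1.5, scale) == scale.positive_hue
        assert cn_value_to_color(99.0, scale) == scale.positive_hue
        assert cn_value_to_color(-99.0, scale) == scale.negative_hue

    def test_half_cap_is_the_midpoint(self):
        scale = CnColorScale(cap=2.0, neutral=(255, 255, 255), negative_hue=(0, 0, 255))
        assert cn_value_to_color(-1.0, scale) == (128, 128, 255)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_and_symmetric(self, a, b):
        scale = CnColorScale()
        lo, hi = sorted((a, b))

        def dist(c):
            return sum((x - n) ** 2 for x, n in zip(c, scale.neutral))

        assert dist(cn_value_to_color(lo, scale)) <= dist(cn_value_to_color(hi, scale))
        assert dist(cn_value_to_color(-lo, scale)) == pytest.approx(
            dist(cn_value_to_color(lo, scale)), abs=3
        )


class TestSortSamples:
    region = GenomicInterval("chrA", 0, 1_000)

    def _segments(self):
        return [
            Segment("A", GenomicInterval("chrA", 0, 1_000), -1.0),
            Segment("B", GenomicInterval("chrA", 0, 1_000), 0.5),
        ]

    def test_deletion_sorts_ascending(self):
        assert sort_samples(self._segments(), self.region, "deletion") == ["A", "B"]

    def test_amplification_sorts_descending(self):
        assert sort_samples(self._segments(), self.region, "amplification") == ["B", "A"]

    def test_score_is_length_weighted_within_region(self):
        segs = [
            # C: mean over region = (-2*100 + 0*900)/1000 = -0.2
            Segment("C", GenomicInterval("chrA", 0, 100), -2.0),
            Segment("C", GenomicInterval("chrA", 100, 1_000), 0.0),
            Segment("D", GenomicInterval("chrA", 0, 1_000), -0.5),
        ]
        assert sort_samples(segs, self.region, "deletion") == ["D", "C"]

    def test_sample_without_overlap_scores_zero_and_ties_by_name(self):
        segs = self._segments() + [Segment("Z", GenomicInterval("chrB", 0, 10), -9.0)]
        order = sort_samples(segs, self.region, "deletion")
        assert order == ["A", "Z", "B"]  # score 0 sits between -1.0 and 0.5

    def test_output_is_a_permutation_of_input_samples(self):
        segs = self._segments() * 3
        order = sort_samples(segs, self.region, "amplification")
        assert sorted(order) == ["A", "B"]


class TestSegmentLayout:
    def test_one_cell_per_intersecting_segment(self):
        segs = [Segment("S1", GenomicInterval("chrA", 0, 1_000), -1.0)]
        (cell,) = layout_segment_track(segs, ["S1"], vp(0, 1000, 500))
        assert cell.style_role == "cn_cell" and cell.payload.startswith("#")

    def test_partial_overlap_is_clipped_to_viewport(self):
        segs = [Segment("S1", GenomicInterval("chrA", 500, 2_000), 1.0)]
        v = vp(0, 1000, 1000)
        (cell,) = layout_segment_track(segs, ["S1"], v)
        assert (cell.x, cell.x + cell.w) == (v.x(500), v.x(1000))

    def test_empty_sample_order_draws_nothing(self):
        segs = [Segment("S1", GenomicInterval("chrA", 0, 10), 1.0)]
        assert layout_segment_track(segs, [], vp()) == []

    def test_rows_stack_in_given_order(self):
        segs = [
            Segment("S2", GenomicInterval("chrA", 0, 10), 1.0),
            Segment("S1", GenomicInterval("chrA", 0, 10), -1.0),
        ]
        cells = layout_segment_track(segs, ["S1", "S2"], vp(), row_height_px=12)
        assert [c.y for c in cells] == [0, 12]


class TestFeatureLayout:
    def test_feature_in_view_gets_a_box(self):
        feats = [Feature(GenomicInterval("chrA", 100, 300), "G1", None, "+")]
        glyphs = layout_feature_track(feats, vp(0, 1000, 1000))
        assert [g.style_role for g in glyphs] == ["feature_box", "label"]
        assert glyphs[1].payload == "G1 >"

    def test_feature_outside_view_draws_nothing(self):
        feats = [Feature(GenomicInterval("chrA", 5_000, 5_100), "G1")]
        assert layout_feature_track(feats, vp(0, 1000, 1000)) == []

    def test_overlapping_features_pack_into_sub_rows(self):
        feats = [
            Feature(GenomicInterval("chrA", 100, 600), "G1"),
            Feature(GenomicInterval("chrA", 400, 900), "G2"),
        ]
        glyphs = layout_feature_track(feats, vp(0, 1000, 1000), row_height_px=14)
        boxes = [g for g in glyphs if g.style_role == "feature_box"]
        assert {b.y for b in boxes} == {0, 14}

    def test_label_suppressed_when_no_pixel_room(self):
        feats = [Feature(GenomicInterval("chrA", 100, 104), "VERYLONGNAME")]
        glyphs = layout_feature_track(feats, vp(0, 1000, 100))
        assert [g.style_role for g in glyphs] == ["feature_box"]


def test_glyph_output_is_a_pure_function_of_inputs():
    read = make_read("r", start=5, cigar="10M", bases="ACGTACGTAC")
    args = ([read], [0], vp(0, 50, 200), "A" * 50)
    assert layout_alignment_track(*args) == layout_alignment_track(*args)
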