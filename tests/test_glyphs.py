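"""Glyph geometry: scaling, clipping, shading, chevrons, compounds, plots."""

import pytest
from hypothesis import given, settings, strategies as st

from annotrack import (
    Annotation,
    AnnotationGroup,
    bar_plot,
    chevron_pattern,
    compound_fragment_glyph,
    grayscale_fill,
    heatmap,
    label_with_lod,
    line_plot,
    linear_ramp,
    make_plot_annotation,
    rectangle_glyph,
    shaded_outlined_rectangle,
)
from annotrack.glyphs import chevron_pattern_id
from annotrack.style import ChartContext


class TestRectangle:
    def test_linear_scale_arithmetic(self, unit_ctx):
        a = Annotation(id="a", start=0, end=10)
        el = rectangle_glyph(a, {}, unit_ctx)
        assert el.geometry["x"] == pytest.approx(0.0)
        assert el.geometry["width"] == pytest.approx(100.0)

    def test_full_domain_annotation_spans_range(self, unit_ctx):
        a = Annotation(id="a", start=0, end=100)
        el = rectangle_glyph(a, {}, unit_ctx)
        assert el.geometry["width"] == pytest.approx(unit_ctx.range_width)

    def test_partial_visibility_clips_to_viewport(self, unit_ctx):
        a = Annotation(id="a", start=90, end=110)
        el = rectangle_glyph(a, {}, unit_ctx)
        assert el.geometry["x"] == pytest.approx(900.0)
        assert el.geometry["width"] == pytest.approx(100.0)

    def test_fully_outside_domain_is_skipped(self, unit_ctx):
        a = Annotation(id="a", start=200, end=300)
        assert rectangle_glyph(a, {}, unit_ctx) is None

    def test_clipping_never_negative_width(self, unit_ctx):
        a = Annotation(id="a", start=99, end=100)
        el = rectangle_glyph(a, {}, unit_ctx)
        assert el.geometry["width"] > 0


class TestGrayscaleShading:
    def test_youngest_is_black(self):
        assert grayscale_fill(0.0) == "rgb(0,0,0)"

    def test_oldest_is_white(self):
        assert grayscale_fill(1.0) == "rgb(255,255,255)"

    def test_midpoint_rounds_half_up(self):
        assert grayscale_fill(0.5) == "rgb(128,128,128)"

    def test_out_of_range_is_style_error(self, unit_ctx):
        a = Annotation(id="a", start=0, end=10)
        with pytest.raises(ValueError):
            shaded_outlined_rectangle(a, {"fill_shade": 1.2}, unit_ctx)

    def test_outline_carries_family_color(self, unit_ctx):
        a = Annotation(id="a", start=0, end=10)
        (el,) = shaded_outlined_rectangle(
            a, {"fill_shade": 0.5, "stroke_color": "#e7298a"}, unit_ctx
        )
        assert el.style["stroke"] == "#e7298a"
        assert el.style["fill"] == "rgb(128,128,128)"


class TestChevronPattern:
    def test_identical_triples_share_one_pattern_id(self):
        p1 = chevron_pattern("+", 8, "#000000")
        p2 = chevron_pattern("+", 8, "#000000")
        assert p1.geometry["id"] == p2.geometry["id"]

    def test_opposite_strands_differ(self):
        assert chevron_pattern("+", 8, "k").geometry["id"] != chevron_pattern(
            "-", 8, "k"
        ).geometry["id"]

    def test_distinct_triples_distinct_ids(self):
        ids = {
            chevron_pattern_id(strand, spacing, color)
            for strand in "+-"
            for spacing in (4, 8)
            for color in ("#000000", "#ff0000")
        }
        assert len(ids) == 8

    @pytest.mark.parametrize("strand, spacing", [(".", 8), ("+", 0), ("+", -2)])
    def test_invalid_inputs_rejected(self, strand, spacing):
        with pytest.raises(ValueError):
            chevron_pattern(strand, spacing, "#000000")


def fragment(gid, start, end, cstart, cend, clen):
    return Annotation(
        id=gid,
        start=start,
        end=end,
        strand="+",
        attributes={
            "consensus_start": cstart,
            "consensus_end": cend,
            "consensus_length": clen,
        },
    )


class TestCompoundGlyph:
    def test_full_length_single_member_is_just_a_rectangle(self, unit_ctx):
        g = AnnotationGroup(
            id="g",
            members=(fragment("m", 10, 20, 0, 10, 10),),
            group_kind="joined_fragments",
        )
        els = compound_fragment_glyph(g, {"fill_shade": 0.2}, unit_ctx)
        assert [e.kind for e in els] == ["rect"]

    def test_two_members_emit_one_two_segment_connector(self, unit_ctx):
        g = AnnotationGroup(
            id="g",
            members=(
                fragment("m1", 10, 20, 0, 10, 30),
                fragment("m2", 40, 60, 10, 30, 30),
            ),
            group_kind="joined_fragments",
        )
        els = compound_fragment_glyph(g, {"fill_shade": 0.2}, unit_ctx)
        connectors = [e for e in els if e.kind == "line" and e.style.get("class") == "connector"]
        assert len(connectors) == 2  # two segments = one connector
        # Vertex is horizontally centered between the facing edges and shared.
        assert connectors[0].geometry["x2"] == connectors[1].geometry["x1"]
        mid = (unit_ctx.x(20) + unit_ctx.x(40)) / 2
        assert connectors[0].geometry["x2"] == pytest.approx(mid)

    def test_connector_count_is_members_minus_one(self, unit_ctx):
        members = tuple(
            fragment(f"m{i}", 10 + 20 * i, 20 + 20 * i, 10 * i, 10 * (i + 1), 50)
            for i in range(4)
        )
        g = AnnotationGroup(id="g", members=members, group_kind="joined_fragments")
        els = compound_fragment_glyph(g, {"fill_shade": 0.2}, unit_ctx)
        connectors = [e for e in els if e.style.get("class") == "connector"]
        assert len(connectors) == 2 * (len(members) - 1)

    def test_dashed_flank_length_is_missing_bases_times_scale(self):
        # 0.1 px per base: domain [0, 10000) onto [0, 1000).
        ctx = ChartContext(0, 10_000, 0.0, 1000.0)
        g = AnnotationGroup(
            id="g",
            members=(fragment("m", 5_000, 6_000, 500, 1_500, 1_500),),
            group_kind="joined_fragments",
        )
        els = compound_fragment_glyph(g, {"fill_shade": 0.2}, ctx)
        flanks = [e for e in els if e.style.get("class") == "flank"]
        assert len(flanks) == 1  # nothing missing on the right
        (flank,) = flanks
        length_px = flank.geometry["x2"] - flank.geometry["x1"]
        assert length_px == pytest.approx(500 * ctx.zoom_scale)  # 50 px

    def test_missing_consensus_attribute_names_member(self, unit_ctx):
        bad = Annotation(id="m-bad", start=0, end=5, strand="+")
        g = AnnotationGroup(id="g", members=(bad,), group_kind="joined_fragments")
        with pytest.raises(ValueError, match="m-bad"):
            compound_fragment_glyph(g, {"fill_shade": 0.2}, unit_ctx)


class TestLabelLod:
    VARIANTS = ["AluYb8 #SINE/Alu", "AluYb8", "Alu"]

    @pytest.mark.parametrize(
        "available, expected",
        [(50, "AluYb8"), (200, "AluYb8 #SINE/Alu"), (10, ""), (36, "AluYb8"), (17, "")],
    )
    def test_enumerated_cases(self, available, expected):
        assert label_with_lod(self.VARIANTS, available, 6) == expected

    @settings(max_examples=80, derandomize=True)
    @given(a1=st.floats(0, 300), a2=st.floats(0, 300))
    def test_monotone_in_available_width(self, a1, a2):
        lo, hi = sorted((a1, a2))
        variants = ["very detailed label", "medium", "s"]
        order = {v: i for i, v in enumerate(variants + [""])}
        assert order[label_with_lod(variants, hi, 6)] <= order[
            label_with_lod(variants, lo, 6)
        ]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            label_with_lod([], 10, 6)
        with pytest.raises(ValueError):
            label_with_lod(["x"], 10, 0)


class TestPlots:
    def test_line_plot_normalizes_min_max(self, unit_ctx):
        p = make_plot_annotation("p", 0, [0.0, 5.0, 10.0])
        (el,) = line_plot(p, {}, unit_ctx, row=0)
        # y of band: row height 16; samples at 16, 8, 0.
        ys = [float(pt.split(",")[1]) for pt in el.geometry["d"].replace("M ", "").split(" L ")]
        assert ys == pytest.approx([16.0, 8.0, 0.0])

    def test_constant_values_render_at_mid_band(self, unit_ctx):
        p = make_plot_annotation("p", 0, [3.0, 3.0, 3.0])
        (el,) = line_plot(p, {}, unit_ctx, row=0)
        ys = [float(pt.split(",")[1]) for pt in el.geometry["d"].replace("M ", "").split(" L ")]
        assert ys == pytest.approx([8.0, 8.0, 8.0])

    def test_sample_x_positions_follow_scale(self):
        ctx = ChartContext(100, 103, 0.0, 300.0)
        p = make_plot_annotation("p", 100, [1.0, 2.0, 3.0])
        (el,) = line_plot(p, {}, ctx, row=0)
        xs = [float(pt.split(",")[0]) for pt in el.geometry["d"].replace("M ", "").split(" L ")]
        assert xs == pytest.approx([0.0, 100.0, 200.0])

    def test_bar_plot_one_rect_per_position(self, unit_ctx):
        p = make_plot_annotation("p", 0, [0.0, 5.0, 10.0])
        els = bar_plot(p, {}, unit_ctx, row=0)
        assert len(els) == 3
        assert all(e.kind == "rect" for e in els)


class TestHeatmap:
    def test_cells_tile_without_gaps(self, unit_ctx):
        p = make_plot_annotation("p", 0, [0.0, 1.0, 2.0])
        els = heatmap(p, {}, unit_ctx, row=0)
        assert len(els) == 3
        for left, right in zip(els, els[1:]):
            assert left.geometry["x"] + left.geometry["width"] == pytest.approx(
                right.geometry["x"]
            )

    def test_ramp_endpoints_and_midpoint_interpolation(self):
        ramp = linear_ramp("#000000", "#ff0040")
        assert ramp(0.0) == "#000000"
        assert ramp(1.0) == "#ff0040"
        # channel-wise linear interpolation with round-half-up: 255/2 -> 128
        assert ramp(0.5) == "#800020"

    def test_cells_colored_by_normalized_value(self, unit_ctx):
        ramp = linear_ramp("#000000", "#ffffff")
        p = make_plot_annotation("p", 0, [0.0, 10.0])
        els = heatmap(p, {}, unit_ctx, row=0, ramp=ramp)
        assert els[0].style["fill"] == "#000000"
        assert els[1].style["fill"] == "#ffffff"


def test_glyph_count_conservation_for_fully_visible_inputs(unit_ctx):
    annotations = [
        Annotation(id=f"a{i}", start=i * 10, end=i * 10 + 5) for i in range(10)
    ]
    els = [rectangle_glyph(a, {}, unit_ctx) for a in annotations]
    assert sum(e is not None for e in els) == len(annotations)
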