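"""Linear chart: scales, axis ticks, render determinism, semantic zoom."""

import pytest
from hypothesis import given, settings, strategies as st
from lxml import etree

from annotrack import (
    Annotation,
    ChartConfig,
    Layer,
    LinearChart,
    aggregate_by_proximity,
    axis_ticks,
    compose,
    make_plot_annotation,
    x_scale,
    x_scale_inverse,
)
from annotrack.style import ChartContext


class TestXScale:
    def test_midpoint_endpoints_and_extension(self, ctx):
        assert x_scale(ctx, 500) == pytest.approx(250.0)
        assert x_scale(ctx, 0) == pytest.approx(0.0)
        assert x_scale(ctx, 1000) == pytest.approx(500.0)
        assert x_scale(ctx, -100) == pytest.approx(-50.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        pos=st.floats(-1e6, 1e6),
        d0=st.integers(-10_000, 10_000),
        width=st.integers(1, 1_000_000),
    )
    def test_invertibility(self, pos, d0, width):
        c = ChartContext(d0, d0 + width, 3.0, 803.0)
        back = x_scale_inverse(c, x_scale(c, pos))
        assert back == pytest.approx(pos, rel=1e-9, abs=1e-9)


class TestAxisTicks:
    def test_decade_domain(self):
        assert axis_ticks(0, 1000, 11) == [i * 100 for i in range(10)]

    def test_small_domain_unit_step(self):
        assert axis_ticks(0, 7, 10) == [0, 1, 2, 3, 4, 5, 6]

    def test_nice_step_is_smallest_feasible(self):
        # Brute-force oracle over {1,2,5}*10^k candidate steps.
        def oracle(start, end, target):
            k = 0
            while True:
                for m in (1, 2, 5):
                    step = m * 10**k
                    ticks = [
                        step * i
                        for i in range(-(-start // step), (end - 1) // step + 1)
                    ]
                    if len(ticks) <= target:
                        return ticks
                k += 1

        for start, end, target in [(0, 10**6, 5), (0, 1000, 11), (37, 9123, 7), (0, 2, 2)]:
            assert axis_ticks(start, end, target) == oracle(start, end, target)

    def test_million_domain_target_five(self):
        ticks = axis_ticks(0, 10**6, 5)
        assert ticks == [0, 200_000, 400_000, 600_000, 800_000]


def simple_layers(n=3):
    annotations = tuple(
        Annotation(id=f"a{i}", start=i * 100, end=i * 100 + 50) for i in range(n)
    )
    return [Layer(name="main", data=annotations, style={"fill_color": "#1b9e77"})]


class TestRender:
    def test_double_render_byte_identical(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000))
        layers = simple_layers()
        assert chart.render(layers).svg == chart.render(layers).svg

    def test_output_is_well_formed_xml(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000))
        result = chart.render(simple_layers())
        etree.fromstring(result.svg.encode())

    def test_disjoint_annotations_one_row_indexed(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000))
        result = chart.render(simple_layers(3))
        assert len(result.element_index) == 3
        assert result.row_assignments["main"].row_count == 1

    def test_empty_payload_renders_background_and_axis_only(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000))
        result = chart.render([])
        etree.fromstring(result.svg.encode())
        assert result.element_index == {}

    def test_layers_stack_in_declaration_order(self):
        fwd = Layer(name="fwd", data=(Annotation(id="f", start=0, end=10, strand="+"),))
        rev = Layer(name="rev", data=(Annotation(id="r", start=0, end=10, strand="-"),))
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=100))
        result = chart.render([fwd, rev])
        f_el = result.glyphs["fwd"][0]
        r_el = result.glyphs["rev"][0]
        assert f_el.geometry["y"] < r_el.geometry["y"]
        assert result.svg.index("layer-fwd") < result.svg.index("layer-rev")

    def test_duplicate_layer_names_rejected(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=100))
        a = Layer(name="x", data=(Annotation(id="a", start=0, end=1),))
        b = Layer(name="x", data=(Annotation(id="b", start=2, end=3),))
        with pytest.raises(ValueError, match="unique"):
            chart.render([a, b])

    def test_invalid_payload_aborts(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=100))
        layer = Layer(name="x", data=(Annotation(id="", start=0, end=1),))
        with pytest.raises(ValueError, match="invalid payload"):
            chart.render([layer])

    def test_every_emitted_glyph_intersects_pixel_range(self):
        annotations = tuple(
            Annotation(id=f"a{i}", start=i * 40 - 100, end=i * 40 - 50)
            for i in range(10)
            if i * 40 - 100 < i * 40 - 50
        )
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=200, width=400))
        result = chart.render([Layer(name="m", data=annotations)])
        ctx = result.context
        for els in result.glyphs.values():
            for el in els:
                x0 = el.geometry["x"]
                x1 = x0 + el.geometry["width"]
                assert x1 > ctx.range_start and x0 < ctx.range_end


class TestSemanticZoom:
    def test_set_domain_validates(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000))
        with pytest.raises(ValueError):
            chart.set_domain(500, 500)

    def test_zoom_halving_doubles_px_per_unit(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000))
        before = chart.context().zoom_scale
        chart.set_domain(250, 750)
        assert chart.context().zoom_scale == pytest.approx(2 * before)

    def test_pan_preserves_px_per_unit(self):
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000))
        before = chart.context().zoom_scale
        chart.set_domain(100, 1100)
        assert chart.context().zoom_scale == before

    def test_halving_domain_exactly_doubles_glyph_widths(self):
        a = Annotation(id="a", start=400, end=437)
        layer = Layer(name="m", data=(a,))
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000, width=800))
        w1 = chart.render([layer]).glyphs["m"][0].geometry["width"]
        chart.set_domain(250, 750)
        w2 = chart.render([layer]).glyphs["m"][0].geometry["width"]
        assert w2 == 2 * w1  # bit-exact, not approximate

    def test_zoom_dependent_label_changes_across_renders(self):
        a = Annotation(id="a", start=0, end=1000)
        label = lambda ann, c: "detailed" if c.zoom_scale >= 1 else "short"
        layer = Layer(name="m", data=(a,), style={"custom_label": label})
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=2000, width=800))
        r1 = chart.render([layer])
        chart.set_domain(0, 500)
        r2 = chart.render([layer])
        from annotrack import resolve

        assert resolve(label, a, r1.context) == "short"
        assert resolve(label, a, r2.context) == "detailed"


class TestAggregationPolicy:
    def test_low_zoom_aggregates_high_zoom_does_not(self):
        annotations = tuple(
            Annotation(id=f"g{i}", start=s, end=s + 500)
            for i, s in enumerate([0, 1000, 2000, 500_000, 501_000])
        )
        policy = lambda zoom: 5000 if zoom < 0.01 else None
        layer = Layer(name="genes", data=annotations, gap_policy=policy,
                      style={"fill_color": "#2b8cbe"})
        zoomed_out = LinearChart(
            ChartConfig(domain_start=0, domain_end=1_000_000, width=800)
        )
        result = zoomed_out.render([layer])
        expected_groups = aggregate_by_proximity(list(annotations), 5000)
        assert len(result.glyphs["genes"]) == len(expected_groups) == 2
        # Members are reachable through the element index.
        assert "g0" in result.element_index

        zoomed_in = LinearChart(ChartConfig(domain_start=0, domain_end=4000, width=800))
        result_in = zoomed_in.render([layer])
        # Individual annotations again: three overlap the zoomed domain.
        assert len(result_in.glyphs["genes"]) == 3


class TestPlotsInChart:
    def test_plot_spanning_beyond_domain_is_sliced(self):
        p = make_plot_annotation("p", 0, [float(i) for i in range(100)])
        chart = LinearChart(ChartConfig(domain_start=20, domain_end=40, width=400))
        result = chart.render([Layer(name="hm", data=(p,), glyph="heatmap")])
        assert len(result.glyphs["hm"]) == 20  # one cell per visible position

    def test_heatmap_cell_count_equals_values_length(self):
        p = make_plot_annotation("p", 0, [1.0, 2.0, 3.0, 4.0])
        chart = LinearChart(ChartConfig(domain_start=0, domain_end=4, width=400))
        result = chart.render([Layer(name="hm", data=(p,), glyph="heatmap")])
        assert len(result.glyphs["hm"]) == len(p.values)


def test_compose_places_panels_into_one_document():
    chart = LinearChart(ChartConfig(domain_start=0, domain_end=1000, width=300))
    r1 = chart.render(simple_layers())
    r2 = chart.render(simple_layers())
    doc = compose([(r1, 0.0, 0.0), (r2, 0.0, 200.0)], width=300, height=400)
    tree = etree.fromstring(doc.encode())
    inner = tree.findall("{http://www.w3.org/2000/svg}svg")
    assert len(inner) == 2
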