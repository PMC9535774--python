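"""Self-contained demo figures built from seeded synthetic data.

Each demo reproduces the style of one kind of published annotation view:

* ``dfam``          — strand-separated repeat tracks: forward-strand TEs,
                      simple repeats, reverse-strand TEs, stacked in that
                      order, rectangles colored by family.
* ``repeatmasker``  — information-dense repeat track: family-colored
                      outlines, grayscale age shading, chevron strand
                      texture, compound glyphs for fragmented insertions
                      with dashed consensus flanks and LOD labels.
* ``occurrences``   — a position-specific value track (line plot over a
                      heatmap) with a highlighted sub-interval and a gene
                      annotation band below.
* ``circular``      — two concentric rings (integrations outside, gene
                      aggregates inside) with a shaded sector marking the
                      region a companion linear view would show.

All demos are deterministic in their seed.
"""

from __future__ import annotations

from .fixtures import FixtureSpec, generate_annotations, generate_plot_annotation
from .layout import aggregate_by_proximity
from .linear import ChartConfig, Layer, LinearChart, RenderResult
from .model import Annotation
from .radial import RadialChart, RadialChartConfig
from .style import ChartContext

DEMO_NAMES = ("dfam", "repeatmasker", "occurrences", "circular")


def _family_fill(a: Annotation, ctx: ChartContext) -> str:
    return str(a.attributes.get("color", "#777777"))


def _age_shade(a: Annotation, ctx: ChartContext) -> float:
    return float(a.attributes.get("age_shade", 0.5))


def _label_variants(a: Annotation, ctx: ChartContext) -> list[str]:
    family = str(a.attributes.get("family", "?"))
    cls = str(a.attributes.get("class", "?"))
    return [f"{family} #{cls}", family, family[:3]]


def demo_dfam(seed: int, width: float = 800.0) -> RenderResult:
    domain = (0, 100_000)
    fwd = generate_annotations(
        FixtureSpec(seed=seed, n=14, domain_end=domain[1], strand_probs=(1.0, 0.0, 0.0))
    )
    simple = generate_annotations(
        FixtureSpec(
            seed=seed + 1,
            n=10,
            domain_end=domain[1],
            min_length=50,
            max_length=400,
            strand_probs=(0.0, 0.0, 1.0),
        )
    )
    rev = generate_annotations(
        FixtureSpec(seed=seed + 2, n=14, domain_end=domain[1], strand_probs=(0.0, 1.0, 0.0))
    )
    chart = LinearChart(ChartConfig(domain_start=domain[0], domain_end=domain[1], width=width))
    layers = [
        Layer(name="forward-tes", data=fwd.annotations, glyph="rectangle",
              style={"fill_color": _family_fill}),
        Layer(name="simple-repeats", data=simple.annotations, glyph="rectangle",
              style={"fill_color": "#000000", "height_fraction": 0.5}),
        Layer(name="reverse-tes", data=rev.annotations, glyph="rectangle",
              style={"fill_color": _family_fill}),
    ]
    return chart.render(layers)


def demo_repeatmasker(seed: int, width: float = 800.0) -> RenderResult:
    domain = (0, 60_000)
    full = generate_annotations(
        FixtureSpec(seed=seed, n=8, domain_end=domain[1], strand_probs=(0.5, 0.5, 0.0))
    )
    frag = generate_annotations(
        FixtureSpec(
            seed=seed + 1,
            n=6,
            domain_end=domain[1],
            min_length=2_000,
            max_length=8_000,
            strand_probs=(0.5, 0.5, 0.0),
            fragment_prob=1.0,
        )
    )
    style = {
        "stroke_color": _family_fill,
        "fill_shade": _age_shade,
        "label_variants": _label_variants,
        "stroke_width": 1,
    }
    chart = LinearChart(ChartConfig(domain_start=domain[0], domain_end=domain[1], width=width))
    layers = [
        Layer(name="full-length", data=full.annotations, glyph="shaded_rectangle",
              style=style, chevrons=True),
        Layer(name="fragments", data=frag.groups, glyph="compound",
              style=style, chevrons=True),
    ]
    return chart.render(layers)


def demo_occurrences(seed: int, width: float = 800.0) -> RenderResult:
    length = 250
    walk = generate_plot_annotation(length, seed=seed, step_std=1.0, id="occurrences")
    genes = generate_annotations(
        FixtureSpec(
            seed=seed + 1, n=10, domain_end=length, min_length=10, max_length=60,
            strand_probs=(0.5, 0.5, 0.0),
        )
    )
    # The integrated sub-interval: highlighted over the value track.
    hi_start, hi_end = length // 4, length // 2
    highlight = Annotation(
        id="integrated-region", start=hi_start, end=hi_end, strand=".",
        attributes={"chrom": "phage"},
    )
    chart = LinearChart(
        ChartConfig(domain_start=0, domain_end=length, width=width, row_height=48)
    )
    layers = [
        Layer(name="frequency-heat", data=(walk,), glyph="heatmap"),
        Layer(name="frequency-line", data=(walk,), glyph="line_plot",
              style={"stroke_color": "#d95f02", "stroke_width": 1.5}),
        Layer(name="highlight", data=(highlight,), glyph="rectangle",
              style={"fill_color": "#2171b5", "opacity": 0.35, "height_fraction": 1.0}),
        Layer(name="genes", data=genes.annotations, glyph="rectangle",
              style={"fill_color": "#74a9cf", "height_fraction": 0.4}),
    ]
    return chart.render(layers)


def demo_circular(seed: int, size: float = 320.0) -> RenderResult:
    domain = (0, 4_000_000)
    integrations = generate_annotations(
        FixtureSpec(
            seed=seed, n=6, domain_end=domain[1], min_length=20_000, max_length=60_000,
            strand_probs=(0.5, 0.5, 0.0),
        )
    )
    genes = generate_annotations(
        FixtureSpec(
            seed=seed + 1, n=60, domain_end=domain[1], min_length=1_000,
            max_length=3_000, strand_probs=(0.5, 0.5, 0.0),
        )
    )
    # The inner ring shows proximity aggregates of genes, as a zoomed-out
    # circular genome view would.
    aggregates = aggregate_by_proximity(list(genes.annotations), gap_threshold=100_000)
    boxes = tuple(
        Annotation(id=g.id, start=g.start, end=g.end, strand=".",
                   attributes={"member_count": len(g.members)})
        for g in aggregates
    )
    chart = RadialChart(
        RadialChartConfig(domain_start=domain[0], domain_end=domain[1], size=size)
    )
    layers = [
        Layer(name="integrations", data=integrations.annotations, glyph="rectangle",
              style={"fill_color": "#d95f02"}),
        Layer(name="gene-aggregates", data=boxes, glyph="rectangle",
              style={"fill_color": "#2b8cbe"}),
    ]
    # Shade the first eighth of the genome: the linear view's region.
    region = (domain[0], domain[1] // 8)
    return chart.render(layers, shaded_region=region)


def render_demo(name: str, seed: int) -> RenderResult:
    if name == "dfam":
        return demo_dfam(seed)
    if name == "repeatmasker":
        return demo_repeatmasker(seed)
    if name == "occurrences":
        return demo_occurrences(seed)
    if name == "circular":
        return demo_circular(seed)
    raise ValueError(f"unknown demo {name!r}; choose from {DEMO_NAMES}")
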