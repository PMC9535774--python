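"""Linear chart: viewport state, layout orchestration, SVG emission.

A chart owns a semantic domain (the interval of sequence currently shown)
and a pixel range.  Rendering a payload of named layers is a pure function
of (payload, config, domain): every style callback is re-resolved under the
current context, layouts are fully deterministic, and floats are printed at
exactly 3 decimals, so repeated renders are byte-identical.  Semantic zoom
is expressed as "set a new domain, render again": representation (labels,
aggregation) can change, not just scale.

Layer stacking follows declaration order top-to-bottom, matching the
convention of strand-separated repeat browsers (forward-strand features,
simple repeats, reverse-strand features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

from .glyphs import (
    ColorRamp,
    DEFAULT_RAMP,
    GlyphElement,
    bar_plot,
    chevron_pattern,
    chevron_pattern_id,
    compound_fragment_glyph,
    heatmap,
    line_plot,
    rectangle_glyph,
    shaded_outlined_rectangle,
)
from .layout import RowAssignment, aggregate_by_proximity, greedy_pack
from .model import (
    Annotation,
    AnnotationGroup,
    EmptySliceError,
    PlotAnnotation,
    slice_plot_annotation,
    validate_payload,
)
from .style import ChartContext, StyleSpec, resolve_all
from .svg import SvgNode, fmt, svg_document

logger = logging.getLogger(__name__)

LayerDatum = Union[Annotation, PlotAnnotation, AnnotationGroup]
GapPolicy = Callable[[float], Optional[int]]

GLYPH_KINDS = (
    "rectangle",
    "shaded_rectangle",
    "compound",
    "group_box",
    "line_plot",
    "bar_plot",
    "heatmap",
)


@dataclass(frozen=True)
class ChartConfig:
    """Declarative chart geometry and behaviour."""

    domain_start: int
    domain_end: int
    width: float = 800.0
    height: float | None = None  # auto-sized from layout when None
    row_height: float = 16.0
    pad: float = 4.0
    axis: bool = True
    axis_height: float = 20.0
    background: str = "#ffffff"
    layer_gap: float = 4.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.domain_start >= self.domain_end:
            raise ValueError("domain start must be < end")
        if self.row_height <= 0:
            raise ValueError("row height must be > 0")


@dataclass(frozen=True)
class Layer:
    """One named band of data sharing a glyph kind and style spec.

    ``gap_policy`` maps the current zoom (px per unit) to a proximity
    aggregation threshold in semantic units, or None to render items
    individually — this is how zoomed-out views condense dense gene tracks
    into aggregate boxes.
    """

    name: str
    data: tuple[LayerDatum, ...]
    glyph: str = "rectangle"
    style: StyleSpec = field(default_factory=dict)
    gap_policy: GapPolicy | None = None
    value_domain: tuple[float, float] | None = None
    ramp: ColorRamp = DEFAULT_RAMP
    chevrons: bool = False
    chevron_spacing: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", tuple(self.data))
        if self.glyph not in GLYPH_KINDS:
            raise ValueError(f"unknown glyph kind {self.glyph!r}")


@dataclass
class RenderResult:
    """Everything a test or downstream panel needs about one render."""

    svg: str
    element_index: dict[str, list[str]]
    row_assignments: dict[str, RowAssignment]
    context: ChartContext
    glyphs: dict[str, list[GlyphElement]]
    document: SvgNode


def x_scale(ctx: ChartContext, pos: float) -> float:
    """Affine semantic-to-pixel map (no clamping)."""
    return ctx.x(pos)


def x_scale_inverse(ctx: ChartContext, px: float) -> float:
    return ctx.x_inverse(px)


def axis_ticks(domain_start: int, domain_end: int, target_count: int) -> list[int]:
    """Tick positions at multiples of a 'nice' step within [start, end).

    The step is the smallest value in {1, 2, 5} x 10^k that yields at most
    ``target_count`` ticks.
    """
    if target_count < 2:
        raise ValueError("target_count must be >= 2")

    def count(step: int) -> int:
        first = -(-domain_start // step)  # ceil division
        last = (domain_end - 1) // step
        return max(0, last - first + 1)

    k = 0
    while True:
        for m in (1, 2, 5):
            step = m * 10**k
            if count(step) <= target_count:
                first = -(-domain_start // step)
                return [step * i for i in range(first, first + count(step))]
        k += 1


def _sanitize_id(s: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_.") else "_" for c in s)


# Canonical attribute order for byte-stable output.
_ATTR_ORDER = (
    "id",
    "class",
    "x",
    "y",
    "width",
    "height",
    "x1",
    "y1",
    "x2",
    "y2",
    "d",
    "text-anchor",
    "font-size",
    "font-family",
    "fill",
    "stroke",
    "stroke-width",
    "stroke-dasharray",
    "opacity",
)


def _ordered_attrs(attrs: Mapping[str, object]) -> dict[str, object]:
    ordered: dict[str, object] = {}
    for key in _ATTR_ORDER:
        if key in attrs:
            ordered[key] = attrs[key]
    for key in sorted(attrs):
        if key not in ordered:
            ordered[key] = attrs[key]
    return ordered


def glyph_to_node(el: GlyphElement, element_id: str | None = None) -> SvgNode:
    """Convert one geometry primitive to an SVG element."""
    attrs: dict[str, object] = {}
    if element_id:
        attrs["id"] = element_id
    if el.kind == "rect":
        attrs.update(
            x=el.geometry["x"],
            y=el.geometry["y"],
            width=el.geometry["width"],
            height=el.geometry["height"],
        )
        node_tag = "rect"
    elif el.kind == "line":
        attrs.update(
            x1=el.geometry["x1"],
            y1=el.geometry["y1"],
            x2=el.geometry["x2"],
            y2=el.geometry["y2"],
        )
        node_tag = "line"
    elif el.kind == "path":
        attrs["d"] = el.geometry["d"]
        node_tag = "path"
    elif el.kind == "text":
        attrs.update(x=el.geometry["x"], y=el.geometry["y"])
        if el.geometry.get("anchor"):
            attrs["text-anchor"] = el.geometry["anchor"]
        node_tag = "text"
    elif el.kind == "pattern":
        pattern = SvgNode(
            "pattern",
            {
                "id": el.geometry["id"],
                "width": el.geometry["size"],
                "height": el.geometry["size"],
                "patternUnits": "userSpaceOnUse",
            },
        )
        pattern.add(
            SvgNode(
                "path",
                _ordered_attrs(
                    {"d": el.geometry["path"], "fill": "none", **el.style}
                ),
            )
        )
        return pattern
    else:
        raise ValueError(f"unknown glyph kind {el.kind!r}")

    attrs.update(el.style)
    node = SvgNode(
        node_tag,
        _ordered_attrs(attrs),
        text=el.geometry.get("text") if el.kind == "text" else None,
    )
    if el.tooltip:
        node.add(SvgNode("title", text=str(el.tooltip)))
    return node


class LinearChart:
    """Stateful wrapper around a viewport: holds the current domain and
    renders payloads of layers into SVG documents."""

    def __init__(self, config: ChartConfig):
        self.config = config
        self._domain = (config.domain_start, config.domain_end)

    @property
    def domain(self) -> tuple[int, int]:
        return self._domain

    def set_domain(self, start: int, end: int) -> None:
        """Replace the visible domain.  Nothing re-renders until
        :meth:`render` is called; the next render re-resolves every style
        callback under the new context (semantic zoom)."""
        if start >= end:
            raise ValueError(f"inverted domain [{start}, {end})")
        self._domain = (start, end)

    def context(self, rows_height: float | None = None) -> ChartContext:
        cfg = self.config
        return ChartContext(
            domain_start=self._domain[0],
            domain_end=self._domain[1],
            range_start=cfg.pad,
            range_end=cfg.width - cfg.pad,
            row_height=cfg.row_height,
        )

    # -- rendering ---------------------------------------------------------

    def render(self, layers: Sequence[Layer]) -> RenderResult:
        cfg = self.config
        ctx = self.context()
        names = [layer.name for layer in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"layer names must be unique, got {names}")
        self._validate_payload(layers)

        doc = svg_document(cfg.width, cfg.height if cfg.height is not None else 0)
        defs = SvgNode("defs")
        doc.add(defs)
        background = SvgNode(
            "rect",
            _ordered_attrs(
                {
                    "class": "background",
                    "x": 0.0,
                    "y": 0.0,
                    "width": cfg.width,
                    "height": 0.0,  # patched once total height is known
                    "fill": cfg.background,
                }
            ),
        )
        doc.add(background)

        y_cursor = cfg.pad
        if cfg.axis:
            doc.add(self._axis_group(ctx, y_cursor))
            y_cursor += cfg.axis_height

        element_index: dict[str, list[str]] = {}
        row_assignments: dict[str, RowAssignment] = {}
        glyphs_by_layer: dict[str, list[GlyphElement]] = {}
        pattern_ids_emitted: set[str] = set()
        counter = [0]

        for layer in layers:
            group_node = SvgNode("g", {"id": _sanitize_id(f"layer-{layer.name}")})
            elements, assignment = self._render_layer(
                layer, ctx, y_cursor, defs, pattern_ids_emitted
            )
            row_assignments[layer.name] = assignment
            glyphs_by_layer[layer.name] = elements
            for el in elements:
                counter[0] += 1
                element_id = _sanitize_id(f"{layer.name}-{el.source_id}-{counter[0]}")
                group_node.add(glyph_to_node(el, element_id))
                element_index.setdefault(el.source_id, []).append(element_id)
            doc.add(group_node)
            logger.info(
                "layer %s: %d glyphs in %d rows",
                layer.name,
                len(elements),
                assignment.row_count,
            )
            y_cursor += assignment.row_count * cfg.row_height + cfg.layer_gap

        total_height = cfg.height if cfg.height is not None else y_cursor + cfg.pad
        doc.attrs["height"] = total_height
        doc.attrs["viewBox"] = f"0 0 {fmt(cfg.width)} {fmt(total_height)}"
        background.attrs["height"] = total_height

        # Index members of aggregated/compound groups under their own ids
        # so every payload annotation overlapping the domain is findable.
        for layer in layers:
            for item in self._layer_items(layer, ctx):
                if isinstance(item, AnnotationGroup) and item.id in element_index:
                    for m in item.members:
                        element_index.setdefault(m.id, element_index[item.id])

        return RenderResult(
            svg=doc.to_svg() + "\n",
            element_index=element_index,
            row_assignments=row_assignments,
            context=ctx,
            glyphs=glyphs_by_layer,
            document=doc,
        )

    # -- internals ---------------------------------------------------------

    def _validate_payload(self, layers: Sequence[Layer]) -> None:
        # The same annotation object may back several layers (e.g. one value
        # vector drawn as both heatmap and line); only *distinct* annotations
        # sharing an id violate payload uniqueness.
        by_id: dict[str, Annotation] = {}
        annotations: list[Annotation] = []

        def _collect(a: Annotation) -> None:
            prev = by_id.get(a.id)
            if prev is not None and prev == a:
                return
            by_id[a.id] = a
            annotations.append(a)

        for layer in layers:
            for item in layer.data:
                if isinstance(item, AnnotationGroup):
                    for m in item.members:
                        _collect(m)
                else:
                    _collect(item)
        report = validate_payload(annotations)
        if not report.ok:
            raise ValueError(
                "invalid payload: " + "; ".join(report.violations)
            )

    def _layer_items(self, layer: Layer, ctx: ChartContext) -> list[LayerDatum]:
        """Apply the layer's zoom-dependent aggregation policy, if any."""
        if layer.gap_policy is None:
            return list(layer.data)
        threshold = layer.gap_policy(ctx.zoom_scale)
        if threshold is None:
            return list(layer.data)
        annotations = [a for a in layer.data if isinstance(a, Annotation)]
        return list(aggregate_by_proximity(annotations, threshold))

    def _render_layer(
        self,
        layer: Layer,
        ctx: ChartContext,
        y_offset: float,
        defs: SvgNode,
        pattern_ids_emitted: set[str],
    ) -> tuple[list[GlyphElement], RowAssignment]:
        items = self._layer_items(layer, ctx)
        visible = [
            it
            for it in items
            if it.start < ctx.domain_end and ctx.domain_start < it.end
        ]
        assignment = greedy_pack(visible)
        elements: list[GlyphElement] = []
        for item in sorted(visible, key=lambda a: (a.start, a.end, a.id)):
            row = assignment[item.id]
            elements.extend(
                self._render_item(
                    layer, item, ctx, row, y_offset, defs, pattern_ids_emitted
                )
            )
        return elements, assignment

    def _render_item(
        self,
        layer: Layer,
        item: LayerDatum,
        ctx: ChartContext,
        row: int,
        y_offset: float,
        defs: SvgNode,
        pattern_ids_emitted: set[str],
    ) -> list[GlyphElement]:
        glyph = layer.glyph

        if isinstance(item, AnnotationGroup):
            if item.group_kind == "joined_fragments" or glyph == "compound":
                pattern_refs = {}
                if layer.chevrons:
                    for m in item.members:
                        ref = self._ensure_pattern(
                            m, layer, ctx, defs, pattern_ids_emitted
                        )
                        if ref:
                            pattern_refs[m.id] = ref
                style = resolve_all(layer.style, item.members[0], ctx)
                return compound_fragment_glyph(
                    item, style, ctx, row, y_offset, pattern_refs=pattern_refs
                )
            # proximity aggregate: one envelope box over the group span
            envelope = Annotation(
                id=item.id,
                start=item.start,
                end=item.end,
                strand=".",
                attributes={"member_count": len(item.members)},
            )
            style = resolve_all(layer.style, envelope, ctx)
            el = rectangle_glyph(envelope, style, ctx, row, y_offset)
            return [el] if el else []

        if isinstance(item, PlotAnnotation) and glyph in ("line_plot", "bar_plot", "heatmap"):
            try:
                p = (
                    item
                    if ctx.domain_start <= item.start and item.end <= ctx.domain_end
                    else slice_plot_annotation(item, ctx.domain_start, ctx.domain_end)
                )
            except EmptySliceError:
                return []
            style = resolve_all(layer.style, p, ctx)
            if glyph == "line_plot":
                return line_plot(p, style, ctx, row, y_offset, layer.value_domain)
            if glyph == "bar_plot":
                return bar_plot(p, style, ctx, row, y_offset, layer.value_domain)
            return heatmap(p, style, ctx, row, y_offset, layer.value_domain, layer.ramp)

        style = resolve_all(layer.style, item, ctx)
        if glyph == "shaded_rectangle":
            ref = self._ensure_pattern(item, layer, ctx, defs, pattern_ids_emitted)
            return shaded_outlined_rectangle(
                item, style, ctx, row, y_offset, pattern_ref=ref
            )
        el = rectangle_glyph(item, style, ctx, row, y_offset)
        return [el] if el else []

    def _ensure_pattern(
        self,
        a: Annotation,
        layer: Layer,
        ctx: ChartContext,
        defs: SvgNode,
        pattern_ids_emitted: set[str],
    ) -> str | None:
        if not layer.chevrons or a.strand not in ("+", "-"):
            return None
        style = resolve_all(layer.style, a, ctx)
        spacing = float(style.get("chevron_spacing", layer.chevron_spacing))
        color = str(style.get("stroke_color", "#000000"))
        pid = chevron_pattern_id(a.strand, spacing, color)
        if pid not in pattern_ids_emitted:
            defs.add(glyph_to_node(chevron_pattern(a.strand, spacing, color)))
            pattern_ids_emitted.add(pid)
        return pid

    def _axis_group(self, ctx: ChartContext, y_top: float) -> SvgNode:
        cfg = self.config
        group = SvgNode("g", {"id": "axis"})
        y_line = y_top + cfg.axis_height - 6.0
        group.add(
            SvgNode(
                "line",
                _ordered_attrs(
                    {
                        "x1": ctx.range_start,
                        "y1": y_line,
                        "x2": ctx.range_end,
                        "y2": y_line,
                        "stroke": "#444444",
                        "stroke-width": 1,
                    }
                ),
            )
        )
        target = max(2, int(cfg.width // 100))
        for tick in axis_ticks(ctx.domain_start, ctx.domain_end, target):
            xt = ctx.x(tick)
            group.add(
                SvgNode(
                    "line",
                    _ordered_attrs(
                        {
                            "x1": xt,
                            "y1": y_line,
                            "x2": xt,
                            "y2": y_line + 4.0,
                            "stroke": "#444444",
                            "stroke-width": 1,
                        }
                    ),
                )
            )
            group.add(
                SvgNode(
                    "text",
                    _ordered_attrs(
                        {
                            "x": xt,
                            "y": y_line - 3.0,
                            "text-anchor": "middle",
                            "font-size": 9,
                            "fill": "#444444",
                        }
                    ),
                    text=str(tick),
                )
            )
        return group


def compose(
    panels: Sequence[tuple[RenderResult, float, float]],
    width: float,
    height: float,
) -> str:
    """Place several rendered panels into one document.

    Each panel's document is embedded as a nested <svg> at (x, y); this is
    how linear, circular, and plot views combine into a multi-panel figure.
    """
    doc = svg_document(width, height)
    for result, x, y in panels:
        inner = result.document
        nested = SvgNode("svg", dict(inner.attrs))
        nested.attrs["x"] = x
        nested.attrs["y"] = y
        nested.children = inner.children
        doc.add(nested)
    return doc.to_svg() + "\n"
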