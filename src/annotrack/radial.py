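"""Circular chart: annotations as arcs on concentric rings.

Suited to whole bacterial genomes: each declared layer occupies one ring
(no row packing — circular support is intentionally light), and a shaded
sector can mark the sub-region currently shown in a companion linear chart,
the circular counterpart of a brush.

Convention: angle 0 at 12 o'clock, increasing clockwise, one full turn per
domain width.  Pixel coordinates of a point at radius r and angle theta are
(cx + r*sin(theta), cy - r*cos(theta)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .glyphs import GlyphElement
from .linear import Layer, RenderResult, _ordered_attrs, _sanitize_id, glyph_to_node
from .layout import RowAssignment
from .model import Annotation, validate_payload
from .style import ChartContext, resolve_all
from .svg import SvgNode, fmt, svg_document

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class RadialContext:
    """Geometry of a circular viewport."""

    center_x: float
    center_y: float
    outer_radius: float
    ring_thickness: float
    domain_start: int
    domain_end: int
    ring_gap: float = 4.0

    def __post_init__(self) -> None:
        if self.domain_end <= self.domain_start:
            raise ValueError("domain must have positive width")
        if self.outer_radius <= 0 or self.ring_thickness <= 0:
            raise ValueError("radii must be positive")

    @property
    def domain_width(self) -> int:
        return self.domain_end - self.domain_start

    def ring_radii(self, ring_index: int) -> tuple[float, float]:
        """(inner, outer) radius of a ring; ring 0 is outermost."""
        outer = self.outer_radius - ring_index * (self.ring_thickness + self.ring_gap)
        inner = outer - self.ring_thickness
        if inner <= 0:
            raise ValueError(f"ring {ring_index} does not fit inside the chart")
        return inner, outer


def angle_scale(rctx: RadialContext, pos: float) -> float:
    """Semantic position -> radians clockwise from 12 o'clock."""
    return (pos - rctx.domain_start) / rctx.domain_width * TWO_PI


def _point(rctx: RadialContext, radius: float, theta: float) -> tuple[float, float]:
    return (
        rctx.center_x + radius * math.sin(theta),
        rctx.center_y - radius * math.cos(theta),
    )


def _arc(radius: float, a: tuple[float, float], b: tuple[float, float], large: bool, sweep: int) -> str:
    return (
        f"A {fmt(radius)},{fmt(radius)} 0 {1 if large else 0} {sweep} "
        f"{fmt(b[0])},{fmt(b[1])}"
    )


def _annular_sector_path(
    rctx: RadialContext, r_in: float, r_out: float, t0: float, t1: float
) -> str:
    """SVG path for the region between two radii and two angles."""
    large = (t1 - t0) > math.pi
    o0 = _point(rctx, r_out, t0)
    o1 = _point(rctx, r_out, t1)
    i1 = _point(rctx, r_in, t1)
    i0 = _point(rctx, r_in, t0)
    parts = [f"M {fmt(o0[0])},{fmt(o0[1])}", _arc(r_out, o0, o1, large, 1)]
    if r_in > 0:
        parts.append(f"L {fmt(i1[0])},{fmt(i1[1])}")
        parts.append(_arc(r_in, i1, i0, large, 0))
    else:
        parts.append(f"L {fmt(rctx.center_x)},{fmt(rctx.center_y)}")
    parts.append("Z")
    return " ".join(parts)


def _full_ring_path(rctx: RadialContext, r_in: float, r_out: float) -> str:
    """A full circle is degenerate in arc syntax, so it is drawn as two
    half-circle segments per radius."""
    top_o = _point(rctx, r_out, 0.0)
    bot_o = _point(rctx, r_out, math.pi)
    parts = [
        f"M {fmt(top_o[0])},{fmt(top_o[1])}",
        _arc(r_out, top_o, bot_o, False, 1),
        _arc(r_out, bot_o, top_o, False, 1),
    ]
    if r_in > 0:
        top_i = _point(rctx, r_in, 0.0)
        bot_i = _point(rctx, r_in, math.pi)
        parts.append(f"M {fmt(top_i[0])},{fmt(top_i[1])}")
        parts.append(_arc(r_in, top_i, bot_i, False, 0))
        parts.append(_arc(r_in, bot_i, top_i, False, 0))
    parts.append("Z")
    return " ".join(parts)


def arc_glyph(
    a: Annotation, ring_index: int, style: dict, rctx: RadialContext
) -> GlyphElement | None:
    """Annular-sector mark for one annotation on one ring."""
    if not (rctx.domain_start <= a.start and a.end <= rctx.domain_end):
        logger.warning("annotation %r outside radial domain; skipped", a.id)
        return None
    r_in, r_out = rctx.ring_radii(ring_index)
    t0 = angle_scale(rctx, a.start)
    t1 = angle_scale(rctx, a.end)
    if t1 - t0 >= TWO_PI - 1e-12:
        d = _full_ring_path(rctx, r_in, r_out)
    else:
        d = _annular_sector_path(rctx, r_in, r_out, t0, t1)
    return GlyphElement(
        kind="path",
        geometry={"d": d, "theta0": t0, "theta1": t1, "r_in": r_in, "r_out": r_out},
        style={
            "fill": style.get("fill_color", "#000000"),
            "stroke": style.get("stroke_color", "none"),
            "stroke-width": style.get("stroke_width", 0),
            "opacity": style.get("opacity", 1.0),
            "fill-rule": "evenodd",
        },
        source_id=a.id,
        tooltip=style.get("tooltip"),
    )


def sector_shading(
    rctx: RadialContext,
    region_start: int,
    region_end: int,
    style: dict | None = None,
) -> GlyphElement:
    """Shaded sector (center to outer radius) marking a sub-region —
    the circular rendering of the linear chart's current domain."""
    if region_start >= region_end:
        raise ValueError(f"inverted region [{region_start}, {region_end})")
    if region_start < rctx.domain_start or region_end > rctx.domain_end:
        raise ValueError("region must lie within the radial domain")
    style = style or {}
    t0 = angle_scale(rctx, region_start)
    t1 = angle_scale(rctx, region_end)
    if t1 - t0 >= TWO_PI - 1e-12:
        d = _full_ring_path(rctx, 0.0, rctx.outer_radius)
    else:
        d = _annular_sector_path(rctx, 0.0, rctx.outer_radius, t0, t1)
    return GlyphElement(
        kind="path",
        geometry={"d": d, "theta0": t0, "theta1": t1},
        style={
            "fill": style.get("fill_color", "#cccccc"),
            "stroke": "none",
            "stroke-width": 0,
            "opacity": style.get("opacity", 0.6),
        },
        source_id="sector-shading",
    )


@dataclass(frozen=True)
class RadialChartConfig:
    domain_start: int
    domain_end: int
    size: float = 320.0  # square viewport edge, px
    ring_thickness: float = 14.0
    margin: float = 10.0
    background: str = "#ffffff"


class RadialChart:
    """Renders layers onto concentric rings (outermost ring first)."""

    def __init__(self, config: RadialChartConfig):
        self.config = config

    def radial_context(self) -> RadialContext:
        cfg = self.config
        half = cfg.size / 2.0
        return RadialContext(
            center_x=half,
            center_y=half,
            outer_radius=half - cfg.margin,
            ring_thickness=cfg.ring_thickness,
            domain_start=cfg.domain_start,
            domain_end=cfg.domain_end,
        )

    def render(
        self,
        layers: Sequence[Layer],
        shaded_region: tuple[int, int] | None = None,
    ) -> RenderResult:
        cfg = self.config
        rctx = self.radial_context()
        # Style callbacks receive the same context type as linear charts;
        # the pixel range maps the domain onto the outer circumference.
        ctx = ChartContext(
            domain_start=cfg.domain_start,
            domain_end=cfg.domain_end,
            range_start=0.0,
            range_end=TWO_PI * rctx.outer_radius,
        )
        annotations = [a for layer in layers for a in layer.data if isinstance(a, Annotation)]
        report = validate_payload(annotations)
        if not report.ok:
            raise ValueError("invalid payload: " + "; ".join(report.violations))

        doc = svg_document(cfg.size, cfg.size)
        doc.add(SvgNode("defs"))
        doc.add(
            SvgNode(
                "rect",
                _ordered_attrs(
                    {
                        "class": "background",
                        "x": 0.0,
                        "y": 0.0,
                        "width": cfg.size,
                        "height": cfg.size,
                        "fill": cfg.background,
                    }
                ),
            )
        )

        element_index: dict[str, list[str]] = {}
        glyphs: dict[str, list[GlyphElement]] = {}
        counter = 0

        # Sector shading renders beneath the ring glyphs.
        if shaded_region is not None:
            shade = sector_shading(rctx, *shaded_region)
            counter += 1
            eid = f"shade-{counter}"
            doc.add(glyph_to_node(shade, eid))
            element_index.setdefault(shade.source_id, []).append(eid)
            glyphs["__shading__"] = [shade]

        for ring_index, layer in enumerate(layers):
            group_node = SvgNode("g", {"id": _sanitize_id(f"ring-{layer.name}")})
            layer_glyphs: list[GlyphElement] = []
            for a in sorted(
                (a for a in layer.data if isinstance(a, Annotation)),
                key=lambda a: (a.start, a.end, a.id),
            ):
                style = resolve_all(layer.style, a, ctx)
                el = arc_glyph(a, ring_index, style, rctx)
                if el is None:
                    continue
                counter += 1
                eid = _sanitize_id(f"{layer.name}-{el.source_id}-{counter}")
                group_node.add(glyph_to_node(el, eid))
                element_index.setdefault(el.source_id, []).append(eid)
                layer_glyphs.append(el)
            doc.add(group_node)
            glyphs[layer.name] = layer_glyphs
            logger.info("ring %s: %d arcs", layer.name, len(layer_glyphs))

        return RenderResult(
            svg=doc.to_svg() + "\n",
            element_index=element_index,
            row_assignments={
                layer.name: RowAssignment(
                    rows={a.id: 0 for a in layer.data}, row_count=1
                )
                for layer in layers
            },
            context=ctx,
            glyphs=glyphs,
            document=doc,
        )
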