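"""Glyph vocabulary: annotations + resolved styles -> pixel geometry.

Each function converts one annotation (or group, or value vector) into
:class:`GlyphElement` primitives in pixel coordinates.  The vocabulary
covers the marks used by repeat- and phage-annotation tracks:

* plain rectangles colored by feature family;
* outlined rectangles whose grayscale interior encodes inferred age
  (shade 0 = youngest = black, shade 1 = oldest = white) with a repeating
  chevron texture indicating strand;
* compound glyphs for fragmented transposable-element insertions: fragment
  rectangles joined by angled connectors, flanked by dashed lines whose
  length shows the missing portion of the family consensus;
* level-of-detail text labels that show as much detail as the available
  pixel width permits;
* line/bar plots and heatmaps for position-specific value vectors.

Glyph functions receive *resolved* styles (concrete values, no callbacks)
from the style layer, keeping this module free of resolution logic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .model import Annotation, AnnotationGroup, PlotAnnotation
from .style import ChartContext
from .svg import fmt

logger = logging.getLogger(__name__)

Style = Mapping[str, object]
ColorRamp = Callable[[float], str]

# Default per-character width as a fraction of font size: a deterministic,
# portable stand-in for font metrics (documented as approximate).
CHAR_WIDTH_FACTOR = 0.6


@dataclass
class GlyphElement:
    """One geometry primitive in pixel coordinates.

    ``kind`` is one of rect | line | path | text | pattern; geometry keys
    depend on the kind.  ``tooltip`` becomes a static description element
    (native viewer tooltip) in the output document.
    """

    kind: str
    geometry: dict[str, object]
    style: dict[str, object] = field(default_factory=dict)
    source_id: str = ""
    tooltip: str | None = None


def _clip_x(x: float, width: float, ctx: ChartContext) -> tuple[float, float] | None:
    """Intersect an x-extent with the viewport; None when fully outside."""
    lo = max(x, ctx.range_start)
    hi = min(x + width, ctx.range_end)
    if hi <= lo:
        return None
    if lo == x and hi == x + width:
        # Fully visible: keep the original width so scale laws (e.g. halving
        # the domain exactly doubling widths) stay bit-exact.
        return x, width
    return lo, hi - lo


def _row_band(ctx: ChartContext, row: int, y_offset: float, height_fraction: float) -> tuple[float, float]:
    """(y, height) of the glyph band for a row, vertically centered."""
    rh = ctx.row_height
    h = rh * height_fraction
    y = y_offset + row * rh + (rh - h) / 2.0
    return y, h


def rectangle_glyph(
    a: Annotation,
    style: Style,
    ctx: ChartContext,
    row: int = 0,
    y_offset: float = 0.0,
) -> GlyphElement | None:
    """The basic annotation mark: a filled rectangle spanning [start, end).

    Geometry is clipped to the viewport; an annotation fully outside the
    domain yields no element (logged at debug level).
    """
    if not a.overlaps(ctx.domain_start, ctx.domain_end):
        logger.debug("annotation %r outside domain; skipped", a.id)
        return None
    x = ctx.x(a.start)
    # Width as length * zoom keeps the scale law exact: halving the domain
    # width doubles a glyph's pixel width bit-for-bit (power-of-two scaling
    # commutes with IEEE rounding), which a subtraction of scaled endpoints
    # would not guarantee.
    width = (a.end - a.start) * ctx.zoom_scale
    clipped = _clip_x(x, width, ctx)
    if clipped is None:
        logger.debug("annotation %r clipped to nothing; skipped", a.id)
        return None
    x, width = clipped
    y, h = _row_band(ctx, row, y_offset, float(style.get("height_fraction", 0.8)))
    return GlyphElement(
        kind="rect",
        geometry={"x": x, "y": y, "width": width, "height": h},
        style={
            "fill": style.get("fill_color", "#000000"),
            "stroke": style.get("stroke_color", "none"),
            "stroke-width": style.get("stroke_width", 0),
            "opacity": style.get("opacity", 1.0),
        },
        source_id=a.id,
        tooltip=style.get("tooltip"),  # type: ignore[arg-type]
    )


def grayscale_fill(fill_shade: float) -> str:
    """Map an age shade in [0, 1] to a grayscale color.

    0 is the youngest feature and renders black; 1 is the oldest and
    renders white.  Gray level = round(255 * shade), round-half-up.
    """
    if not 0.0 <= fill_shade <= 1.0:
        raise ValueError(f"fill_shade must be in [0, 1], got {fill_shade}")
    level = int(math.floor(255 * fill_shade + 0.5))
    return f"rgb({level},{level},{level})"


def shaded_outlined_rectangle(
    a: Annotation,
    style: Style,
    ctx: ChartContext,
    row: int = 0,
    y_offset: float = 0.0,
    pattern_ref: str | None = None,
) -> list[GlyphElement]:
    """Age-shaded, family-outlined rectangle, optionally strand-textured.

    The outline carries the family color; the interior is grayscale by
    ``fill_shade`` (younger = darker).  When ``pattern_ref`` names a chevron
    pattern, a second rectangle filled with the pattern is layered on top.
    """
    shade = style.get("fill_shade")
    if shade is None:
        raise ValueError(f"annotation {a.id!r}: shaded rectangle requires fill_shade")
    base_style = dict(style)
    base_style["fill_color"] = grayscale_fill(float(shade))  # validates range
    base_style.setdefault("stroke_width", 1)
    base = rectangle_glyph(a, base_style, ctx, row, y_offset)
    if base is None:
        return []
    elements = [base]
    if pattern_ref is not None:
        overlay = GlyphElement(
            kind="rect",
            geometry=dict(base.geometry),
            style={"fill": f"url(#{pattern_ref})", "stroke": "none", "stroke-width": 0},
            source_id=a.id,
        )
        elements.append(overlay)
    return elements


def _sanitize_token(s: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in s)


def chevron_pattern_id(strand: str, spacing: float, color: str) -> str:
    name = {"+": "fwd", "-": "rev"}[strand]
    return f"chevron-{name}-{fmt(float(spacing))}-{_sanitize_token(color)}"


def chevron_pattern(strand: str, spacing: float, color: str) -> GlyphElement:
    """Reusable tiled chevron texture indicating strand.

    Chevrons point rightward for "+" and leftward for "-".  The pattern id
    is deterministic in (strand, spacing, color) so identical patterns are
    defined once and referenced many times.  Unstranded features must use
    an untextured glyph instead.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"chevron texture requires strand '+' or '-', got {strand!r}")
    if not spacing > 0:
        raise ValueError(f"chevron spacing must be > 0, got {spacing}")
    s = float(spacing)
    if strand == "+":
        # One rightward-pointing chevron per tile: \ then / shapes a '>'.
        d = f"M 0,0 L {fmt(s / 2)},{fmt(s / 2)} L 0,{fmt(s)}"
    else:
        d = f"M {fmt(s)},0 L {fmt(s / 2)},{fmt(s / 2)} L {fmt(s)},{fmt(s)}"
    return GlyphElement(
        kind="pattern",
        geometry={"id": chevron_pattern_id(strand, s, color), "size": s, "path": d},
        style={"stroke": color, "stroke-width": 1},
    )


def compound_fragment_glyph(
    g: AnnotationGroup,
    style: Style,
    ctx: ChartContext,
    row: int = 0,
    y_offset: float = 0.0,
    pattern_refs: Mapping[str, str] | None = None,
) -> list[GlyphElement]:
    """Compound glyph for a fragmented insertion.

    One rectangle per fragment; consecutive fragments are joined by two
    angled line segments meeting at a raised vertex; dashed horizontal
    extensions flank the group where consensus sequence is missing, at one
    semantic unit per missing consensus base (then clipped).  A left-side
    text label slot is filled from ``label_variants`` when provided.
    """
    if g.group_kind != "joined_fragments":
        raise ValueError(f"group {g.id!r}: compound glyph requires joined_fragments")
    for m in g.members:
        for key in ("consensus_start", "consensus_end", "consensus_length"):
            if key not in m.attributes:
                raise ValueError(f"member {m.id!r}: missing attribute {key!r}")

    elements: list[GlyphElement] = []
    frac = float(style.get("height_fraction", 0.8))
    y, h = _row_band(ctx, row, y_offset, frac)
    y_mid = y + h / 2.0
    line_style = {
        "stroke": style.get("stroke_color", "#000000"),
        "stroke-width": style.get("stroke_width", 1),
    }

    for m in g.members:
        ref = (pattern_refs or {}).get(m.id)
        elements.extend(
            shaded_outlined_rectangle(m, style, ctx, row, y_offset, pattern_ref=ref)
        )

    # Angled connectors: n - 1 pairs of segments, vertex centered between
    # facing edges and raised half a row height above the glyph midline.
    for left, right in zip(g.members, g.members[1:]):
        x1 = ctx.x(left.end)
        x2 = ctx.x(right.start)
        xv = (x1 + x2) / 2.0
        yv = y_mid - ctx.row_height / 2.0
        for (ax, ay, bx, by) in ((x1, y_mid, xv, yv), (xv, yv, x2, y_mid)):
            elements.append(
                GlyphElement(
                    kind="line",
                    geometry={"x1": ax, "y1": ay, "x2": bx, "y2": by},
                    style=dict(line_style, **{"class": "connector"}),
                    source_id=g.id,
                )
            )

    # Dashed consensus extensions: missing bases on the left are those
    # before the first fragment's consensus_start; on the right, those after
    # the last fragment's consensus_end.
    first, last = g.members[0], g.members[-1]
    missing_left = int(first.attributes["consensus_start"])
    missing_right = int(last.attributes["consensus_length"]) - int(
        last.attributes["consensus_end"]
    )
    dash_style = dict(line_style, **{"stroke-dasharray": style.get("dash", "4,3"), "class": "flank"})
    for missing, x_anchor, sign in (
        (missing_left, g.start, -1),
        (missing_right, g.end, +1),
    ):
        if missing <= 0:
            continue
        x_a = ctx.x(x_anchor)
        x_b = ctx.x(x_anchor + sign * missing)
        lo, hi = min(x_a, x_b), max(x_a, x_b)
        lo = max(lo, ctx.range_start)
        hi = min(hi, ctx.range_end)
        if hi <= lo:
            continue
        elements.append(
            GlyphElement(
                kind="line",
                geometry={"x1": lo, "y1": y_mid, "x2": hi, "y2": y_mid},
                style=dash_style,
                source_id=g.id,
            )
        )

    variants = style.get("label_variants")
    if variants:
        font_size = float(style.get("font_size", 10))
        char_w = font_size * CHAR_WIDTH_FACTOR
        x_label = ctx.x(g.start - max(missing_left, 0)) - 4.0
        available = x_label - ctx.range_start
        text = label_with_lod(list(variants), available, char_w)  # type: ignore[arg-type]
        if text:
            elements.append(
                GlyphElement(
                    kind="text",
                    geometry={"x": x_label, "y": y_mid + font_size * 0.35, "anchor": "end"},
                    style={
                        "fill": style.get("text_color", "#000000"),
                        "font-size": font_size,
                    },
                    source_id=g.id,
                    tooltip=None,
                )
            )
            elements[-1].geometry["text"] = text
    return elements


def label_with_lod(
    variants: Sequence[str], available_px: float, char_width_px: float
) -> str:
    """Pick the most detailed label variant that fits the available width.

    Variants are ordered most -> least detailed; the implicit final
    fallback is the empty string.  Width is estimated as
    ``len(variant) * char_width_px``.
    """
    if not variants:
        raise ValueError("variants must be non-empty")
    if not char_width_px > 0:
        raise ValueError("char_width_px must be > 0")
    for v in variants:
        if len(v) * char_width_px <= available_px:
            return v
    return ""


def _normalize(values: Sequence[float], domain: tuple[float, float] | None) -> list[float]:
    """Min-max normalization to [0, 1]; a degenerate domain (min == max)
    maps every sample to mid-band, a visually neutral result."""
    if domain is None:
        lo, hi = min(values), max(values)
    else:
        lo, hi = domain
    if hi <= lo:
        return [0.5] * len(values)
    return [min(1.0, max(0.0, (v - lo) / (hi - lo))) for v in values]


def line_plot(
    p: PlotAnnotation,
    style: Style,
    ctx: ChartContext,
    row: int = 0,
    y_offset: float = 0.0,
    value_domain: tuple[float, float] | None = None,
) -> list[GlyphElement]:
    """Connected line through one sample per position.

    Sample i sits at x = scale(start + i); values map linearly onto the
    row's pixel band with the domain maximum at the top.
    """
    y_top = y_offset + row * ctx.row_height
    band = ctx.row_height
    norms = _normalize(p.values, value_domain)
    points = [
        (ctx.x(p.start + i), y_top + (1.0 - n) * band) for i, n in enumerate(norms)
    ]
    d = "M " + " L ".join(f"{fmt(x)},{fmt(y)}" for x, y in points)
    return [
        GlyphElement(
            kind="path",
            geometry={"d": d},
            style={
                "fill": "none",
                "stroke": style.get("stroke_color", "#000000"),
                "stroke-width": style.get("stroke_width", 1),
            },
            source_id=p.id,
        )
    ]


def bar_plot(
    p: PlotAnnotation,
    style: Style,
    ctx: ChartContext,
    row: int = 0,
    y_offset: float = 0.0,
    value_domain: tuple[float, float] | None = None,
) -> list[GlyphElement]:
    """One bar per position, height proportional to the normalized value."""
    y_top = y_offset + row * ctx.row_height
    band = ctx.row_height
    cell_w = ctx.zoom_scale
    norms = _normalize(p.values, value_domain)
    fill = style.get("fill_color", "#000000")
    elements = []
    for i, n in enumerate(norms):
        bar_h = n * band
        elements.append(
            GlyphElement(
                kind="rect",
                geometry={
                    "x": ctx.x(p.start + i),
                    "y": y_top + band - bar_h,
                    "width": cell_w,
                    "height": bar_h,
                },
                style={"fill": fill, "stroke": "none", "stroke-width": 0},
                source_id=f"{p.id}:{i}",
            )
        )
    return elements


def _parse_hex(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)


def linear_ramp(from_color: str = "#ffffff", to_color: str = "#08306b") -> ColorRamp:
    """Two-endpoint linear color ramp, channel-wise with round-half-up."""
    lo = _parse_hex(from_color)
    hi = _parse_hex(to_color)

    def ramp(t: float) -> str:
        t = min(1.0, max(0.0, t))
        rgb = tuple(int(math.floor(a + (b - a) * t + 0.5)) for a, b in zip(lo, hi))
        return "#{:02x}{:02x}{:02x}".format(*rgb)

    return ramp


DEFAULT_RAMP = linear_ramp()


def heatmap(
    p: PlotAnnotation,
    style: Style,
    ctx: ChartContext,
    row: int = 0,
    y_offset: float = 0.0,
    value_domain: tuple[float, float] | None = None,
    ramp: ColorRamp = DEFAULT_RAMP,
) -> list[GlyphElement]:
    """One colored cell per position, tiling [start, end) with no gaps."""
    y_top = y_offset + row * ctx.row_height
    band = ctx.row_height
    cell_w = ctx.zoom_scale
    norms = _normalize(p.values, value_domain)
    return [
        GlyphElement(
            kind="rect",
            geometry={
                "x": ctx.x(p.start + i),
                "y": y_top,
                "width": cell_w,
                "height": band,
            },
            style={"fill": ramp(n), "stroke": "none", "stroke-width": 0},
            source_id=f"{p.id}:{i}",
        )
        for i, n in enumerate(norms)
    ]
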