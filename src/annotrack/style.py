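"""Callback-driven style resolution.

Every glyph style property accepts either a constant or a callback of
``(annotation, chart_context)``.  Callbacks are re-evaluated at every
render, which is what makes semantic zoom work: re-rendering under a new
domain re-resolves every property, so e.g. a label callback can return more
detail when more pixels per base are available.

Callbacks must be pure (side-effect-free functions of their arguments);
rendering the same chart state twice therefore yields identical documents.
Resolved values are validated eagerly against the property's declared value
kind — a bad callback fails at render time with the annotation id and
property name, not silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Mapping, Union

from .model import Annotation

StyleValue = Any
StyleEntry = Union[StyleValue, Callable[[Annotation, "ChartContext"], StyleValue]]
StyleSpec = Mapping[str, StyleEntry]


@dataclass(frozen=True)
class ChartContext:
    """Snapshot of viewport state passed to style callbacks.

    ``zoom_scale`` is pixels per semantic unit; semantic zoom means this
    changes when the domain changes, and styles resolve differently.
    """

    domain_start: int
    domain_end: int
    range_start: float
    range_end: float
    row_height: float = 16.0

    def __post_init__(self) -> None:
        if self.domain_end <= self.domain_start:
            raise ValueError("domain must have positive width")
        if self.range_end <= self.range_start:
            raise ValueError("pixel range must have positive width")

    @property
    def domain_width(self) -> int:
        return self.domain_end - self.domain_start

    @property
    def range_width(self) -> float:
        return self.range_end - self.range_start

    @property
    def zoom_scale(self) -> float:
        """Pixels per semantic unit; always > 0."""
        return self.range_width / self.domain_width

    def x(self, pos: float) -> float:
        """Affine semantic-to-pixel map; no clamping, so out-of-view
        positions extend linearly beyond the range."""
        return (
            (pos - self.domain_start) / self.domain_width * self.range_width
            + self.range_start
        )

    def x_inverse(self, px: float) -> float:
        return (
            (px - self.range_start) / self.range_width * self.domain_width
            + self.domain_start
        )


class StyleError(ValueError):
    """A style entry failed to resolve; names the annotation and property."""

    def __init__(self, annot_id: str, prop: str, message: str):
        self.annot_id = annot_id
        self.prop = prop
        super().__init__(f"style {prop!r} for annotation {annot_id!r}: {message}")


def _is_color(v: Any) -> bool:
    return isinstance(v, str) and bool(v)


def _is_unit(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool) and 0.0 <= v <= 1.0


def _is_positive(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool) and v > 0


def _is_nonneg(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool) and v >= 0


def _is_str_seq(v: Any) -> bool:
    return (
        isinstance(v, (list, tuple))
        and len(v) > 0
        and all(isinstance(s, str) for s in v)
    )


# Value-kind validators per recognized property.  Unknown properties pass
# through unvalidated so callers can thread custom data to custom glyphs.
_VALIDATORS: dict[str, tuple[Callable[[Any], bool], str]] = {
    "fill_color": (_is_color, "non-empty color string"),
    "stroke_color": (_is_color, "non-empty color string"),
    "text_color": (_is_color, "non-empty color string"),
    "stroke_width": (_is_nonneg, "number >= 0 (px)"),
    "opacity": (_is_unit, "number in [0, 1]"),
    "fill_shade": (_is_unit, "number in [0, 1]"),
    "chevron_spacing": (_is_positive, "number > 0 (px)"),
    "label_variants": (_is_str_seq, "non-empty sequence of strings"),
    "height_fraction": (_is_unit, "number in (0, 1]"),
    "font_size": (_is_positive, "number > 0 (px)"),
    "dash": (_is_color, "SVG dasharray string"),
}


def resolve(
    spec_entry: StyleEntry, a: Annotation, ctx: ChartContext, prop: str = "<anonymous>"
) -> StyleValue:
    """Resolve one style entry for one glyph.

    Constants are returned as-is; callables are invoked with
    ``(annotation, context)``.  Either way the result is validated against
    the property's declared value kind.
    """
    if callable(spec_entry):
        try:
            value = spec_entry(a, ctx)
        except Exception as exc:
            raise StyleError(a.id, prop, f"callback raised {exc!r}") from exc
    else:
        value = spec_entry
    validator = _VALIDATORS.get(prop)
    if validator is not None:
        check, expected = validator
        if not check(value):
            raise StyleError(a.id, prop, f"expected {expected}, got {value!r}")
    return value


def resolve_all(
    spec: StyleSpec, a: Annotation, ctx: ChartContext, defaults: StyleSpec | None = None
) -> dict[str, StyleValue]:
    """Resolve a full style spec (with optional defaults) for one glyph."""
    merged: dict[str, StyleEntry] = dict(defaults or {})
    merged.update(spec)
    return {prop: resolve(entry, a, ctx, prop) for prop, entry in merged.items()}
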