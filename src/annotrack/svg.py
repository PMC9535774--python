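"""Minimal deterministic SVG document model.

Rendering is tested against golden files, so serialization must be
byte-stable: attributes are written in insertion order, every float is
printed with exactly 3 decimals, and text is XML-escaped.  Well-formedness
is checked in the test suite with an independent XML parser.
"""

from __future__ import annotations

from typing import Iterable, Union
from xml.sax.saxutils import escape, quoteattr

Numeric = Union[int, float]


def fmt(value: object) -> str:
    """Canonical attribute formatting: floats at exactly 3 decimals."""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.3f}"
    return str(value)


class SvgNode:
    """One XML element; children render in insertion order."""

    def __init__(self, tag: str, attrs: dict[str, object] | None = None, text: str | None = None):
        self.tag = tag
        self.attrs: dict[str, object] = dict(attrs or {})
        self.text = text
        self.children: list[SvgNode] = []

    def add(self, child: "SvgNode") -> "SvgNode":
        self.children.append(child)
        return child

    def extend(self, children: Iterable["SvgNode"]) -> None:
        self.children.extend(children)

    def to_svg(self, indent: int = 0) -> str:
        pad = "  " * indent
        attrs = "".join(f" {k}={quoteattr(fmt(v))}" for k, v in self.attrs.items())
        if not self.children and self.text is None:
            return f"{pad}<{self.tag}{attrs}/>"
        parts = [f"{pad}<{self.tag}{attrs}>"]
        if self.text is not None:
            parts[0] += escape(self.text)
        if self.children:
            parts.extend(child.to_svg(indent + 1) for child in self.children)
            parts.append(f"{pad}</{self.tag}>")
        else:
            parts[0] += f"</{self.tag}>"
        return "\n".join(parts)


def svg_document(width: Numeric, height: Numeric) -> SvgNode:
    return SvgNode(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": width,
            "height": height,
            "viewBox": f"0 0 {fmt(width)} {fmt(height)}",
        },
    )
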