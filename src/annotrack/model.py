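"""Core annotation data model.

Every renderer in this package consumes the same minimal abstraction of a
sequence feature: an identifier, a start coordinate, and an end coordinate,
optionally augmented with a strand and an open mapping of auxiliary
attributes (score, family name, consensus coordinates, ...).  Features that
carry one numeric value per sequence position (confidence traces, coverage,
integration frequencies) extend this with a value vector.

Coordinates are 0-based, half-open ``[start, end)`` throughout the package:
this matches BED natively and makes overlap tests uniform (two intervals
overlap iff ``a.start < b.end and b.start < a.end``; touching intervals do
not overlap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

AttrValue = Union[str, int, float]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class Annotation:
    """An interval feature on a sequence.

    ``start``/``end`` are 0-based half-open.  ``attributes`` is an open
    mapping so that parsers and callers can attach arbitrary auxiliary data
    (e.g. ``score``, ``family``, ``consensus_start``) that style callbacks
    later consume.
    """

    id: str
    start: int
    end: int
    strand: str = "."
    attributes: Mapping[str, AttrValue] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open overlap test against ``[start, end)``."""
        return self.start < end and start < self.end


@dataclass(frozen=True)
class PlotAnnotation(Annotation):
    """An annotation carrying one numeric value per position in [start, end)."""

    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


@dataclass(frozen=True)
class AnnotationGroup:
    """An ordered collection of annotations rendered as one unit.

    ``joined_fragments`` groups become compound glyphs (fragment rectangles
    joined by angled connectors, flanked by dashed consensus extensions);
    ``proximity_aggregate`` groups become single aggregate boxes at low zoom.
    Members are kept sorted by start and must not overlap one another.
    """

    id: str
    members: tuple[Annotation, ...]
    group_kind: str  # "joined_fragments" | "proximity_aggregate"

    def __post_init__(self) -> None:
        members = tuple(sorted(self.members, key=lambda a: (a.start, a.end, a.id)))
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError(f"group {self.id!r}: members must be non-empty")
        if self.group_kind not in ("joined_fragments", "proximity_aggregate"):
            raise ValueError(f"group {self.id!r}: unknown kind {self.group_kind!r}")
        if self.group_kind == "joined_fragments":
            # Fragments of one insertion occupy disjoint genome intervals;
            # connectors between overlapping rectangles would be degenerate.
            # Proximity aggregates conserve their members verbatim and may
            # contain overlaps (they render as one envelope box anyway).
            for a, b in zip(members, members[1:]):
                if a.start < b.end and b.start < a.end:
                    raise ValueError(
                        f"group {self.id!r}: members {a.id!r} and {b.id!r} overlap"
                    )

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...]


def validate_annotation(a: Annotation) -> ValidationReport:
    """Check every model invariant on one annotation.

    Never raises: the report lists all violations, not just the first.
    Payload-level uniqueness of ids is checked separately by
    :func:`validate_payload` because parsers may legitimately produce
    duplicate names before deduplication.
    """
    violations: list[str] = []
    if not a.id:
        violations.append("empty id")
    if not (a.start < a.end):
        violations.append(f"start < end required (got [{a.start}, {a.end}))")
    if a.strand not in STRANDS:
        violations.append(f"strand must be one of {STRANDS} (got {a.strand!r})")
    if isinstance(a, PlotAnnotation):
        if len(a.values) != a.end - a.start:
            violations.append(
                f"values length {len(a.values)} != interval length {a.end - a.start}"
            )
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in a.values):
            violations.append("values contain undefined entries (None/NaN)")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def validate_payload(annotations: Iterable[Annotation]) -> ValidationReport:
    """Validate a whole rendering payload: per-annotation invariants plus
    uniqueness of ids across the payload."""
    violations: list[str] = []
    seen: set[str] = set()
    for a in annotations:
        report = validate_annotation(a)
        violations.extend(f"{a.id!r}: {v}" for v in report.violations)
        if a.id in seen:
            violations.append(f"duplicate id {a.id!r}")
        seen.add(a.id)
    return ValidationReport(ok=not violations, violations=tuple(violations))


class EmptySliceError(ValueError):
    """Raised when a slice interval does not intersect the annotation."""


def slice_plot_annotation(p: PlotAnnotation, s: int, e: int) -> PlotAnnotation:
    """Restrict ``p`` to the intersection of ``[s, e)`` with its own span.

    Used to magnify a brushed sub-interval: the returned annotation spans
    the intersection and carries the corresponding contiguous sub-sequence
    of values.  The id gains a deterministic ``[start:end)`` slice tag.
    """
    if s >= e:
        raise ValueError(f"slice requires s < e (got [{s}, {e}))")
    lo = max(s, p.start)
    hi = min(e, p.end)
    if lo >= hi:
        raise EmptySliceError(
            f"slice [{s}, {e}) is disjoint from {p.id!r} [{p.start}, {p.end})"
        )
    offset = lo - p.start
    return PlotAnnotation(
        id=f"{p.id}[{lo}:{hi})",
        start=lo,
        end=hi,
        strand=p.strand,
        attributes=dict(p.attributes),
        values=p.values[offset : offset + (hi - lo)],
    )


def sort_annotations(annotations: Iterable[Annotation]) -> list[Annotation]:
    """Canonical total order used everywhere layout determinism matters."""
    return sorted(annotations, key=lambda a: (a.start, a.end, a.id))


def make_plot_annotation(
    id: str,
    start: int,
    values: Sequence[float],
    strand: str = ".",
    attributes: Mapping[str, AttrValue] | None = None,
) -> PlotAnnotation:
    """Convenience constructor: the end coordinate follows from the values."""
    return PlotAnnotation(
        id=id,
        start=start,
        end=start + len(values),
        strand=strand,
        attributes=dict(attributes or {}),
        values=tuple(values),
    )
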