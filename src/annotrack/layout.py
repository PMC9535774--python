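"""Row layout and proximity aggregation for annotation tracks.

Annotations sharing a track are packed into horizontal rows so that no two
glyphs in a row overlap.  The packer is the classic left-endpoint greedy
interval-graph coloring, which is optimal: the number of rows it uses
equals the maximum number of intervals covering any single point (checked
independently by :func:`max_overlap_depth`, a sweep-line oracle).

For zoomed-out display, nearby annotations can be condensed into
``proximity_aggregate`` groups rendered as a single box; the gap threshold
is a semantic (sequence-coordinate) distance, chosen by the chart from its
zoom level, keeping this module pure.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .model import Annotation, AnnotationGroup, sort_annotations

Placeable = Union[Annotation, AnnotationGroup]


@dataclass(frozen=True)
class RowAssignment:
    """Maps each annotation id to a row index; rows are 0-based from the top."""

    rows: Mapping[str, int]
    row_count: int

    def __getitem__(self, annot_id: str) -> int:
        return self.rows[annot_id]


def greedy_pack(annotations: Sequence[Placeable]) -> RowAssignment:
    """Assign annotations to rows by left-endpoint greedy packing.

    Items are processed in (start, end, id) order and each is placed in the
    lowest-index row whose rightmost occupied coordinate is <= its start
    (half-open semantics: touching intervals share a row).  This uses the
    minimum possible number of rows.  Fully deterministic: the total order
    on inputs makes layout, and hence the rendered document, reproducible.
    """
    items = sorted(annotations, key=lambda a: (a.start, a.end, a.id))
    ids = [a.id for a in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in layout input: {dupes}")

    rows: dict[str, int] = {}
    # Min-heap of (rightmost_end, row_index) plus a pool of freed rows keeps
    # placement O(n log n) while still choosing the lowest-index free row.
    active: list[tuple[int, int]] = []  # (end, row)
    free_rows: list[int] = []
    next_row = 0
    for a in items:
        while active and active[0][0] <= a.start:
            _, freed = heapq.heappop(active)
            heapq.heappush(free_rows, freed)
        if free_rows:
            row = heapq.heappop(free_rows)
        else:
            row = next_row
            next_row += 1
        rows[a.id] = row
        heapq.heappush(active, (a.end, row))
    return RowAssignment(rows=rows, row_count=next_row)


def max_overlap_depth(annotations: Iterable[Placeable]) -> int:
    """Maximum number of intervals simultaneously covering any point.

    Event sweep: +1 at each start, -1 at each end, with ends processed
    before starts at equal coordinates (half-open intervals that touch do
    not overlap).  Serves as the independent optimality oracle for
    :func:`greedy_pack`.
    """
    events: list[tuple[int, int]] = []
    for a in annotations:
        events.append((a.start, 1))
        events.append((a.end, -1))
    # Sorting by (coordinate, delta) puts -1 before +1 at ties.
    events.sort()
    depth = 0
    best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return best


def aggregate_by_proximity(
    annotations: Sequence[Annotation], gap_threshold: int
) -> list[AnnotationGroup]:
    """Condense annotations into groups of near neighbours.

    After sorting by start, a new group begins whenever the gap between the
    next annotation's start and the running group's maximum end exceeds
    ``gap_threshold`` (semantic units).  Singleton groups are allowed; the
    union of members over all groups equals the input.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be >= 0")
    ordered = sort_annotations(annotations)
    groups: list[AnnotationGroup] = []
    current: list[Annotation] = []
    current_end = 0
    for a in ordered:
        if current and a.start - current_end > gap_threshold:
            groups.append(_make_group(current, len(groups)))
            current = []
        current.append(a)
        current_end = max(current_end, a.end) if len(current) > 1 else a.end
    if current:
        groups.append(_make_group(current, len(groups)))
    return groups


def _make_group(members: list[Annotation], index: int) -> AnnotationGroup:
    return AnnotationGroup(
        id=f"agg-{index}", members=tuple(members), group_kind="proximity_aggregate"
    )
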