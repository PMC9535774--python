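"""Readers and writers for standard annotation formats.

BED (3-12 columns, tab-separated, 0-based half-open) is read and written
directly.  GFF3 (9 columns, 1-based inclusive, percent-encoded attributes)
is read through :mod:`gffutils`' line-level parser and converted to the
internal 0-based half-open convention: internal start = printed start - 1,
internal end = printed end.

Parsing is strict by default: a malformed line raises :class:`FormatError`
carrying its 1-based line number.  Lenient mode skips malformed lines with
a logged warning, which suits dirty real-world inputs; tests use strict
mode for determinism.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Iterator, Union

from gffutils.feature import feature_from_line

from .model import Annotation, AttrValue

logger = logging.getLogger(__name__)

# Standard BED column names beyond chrom/start/end, in order.
_BED_OPTIONAL = (
    "name",
    "score",
    "strand",
    "thickStart",
    "thickEnd",
    "itemRgb",
    "blockCount",
    "blockSizes",
    "blockStarts",
)

TextSource = Union[str, IO[str], Iterable[str]]


class FormatError(ValueError):
    """A line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        prefix = f"line {line_number}: " if line_number is not None else ""
        super().__init__(prefix + message)


def _iter_lines(source: TextSource) -> Iterator[str]:
    if isinstance(source, str):
        yield from source.splitlines()
    else:
        for line in source:
            yield line.rstrip("\n")


def _parse_int(token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"non-integer {what}: {token!r}") from None


def _parse_comma_list(token: str, what: str) -> tuple[int, ...]:
    # BED block lists conventionally allow a trailing comma.
    items = [t for t in token.rstrip(",").split(",") if t != ""]
    return tuple(_parse_int(t, what) for t in items)


def parse_bed_record(line: str, ordinal: int) -> Annotation:
    """Parse one BED data line into an Annotation.

    BED is already 0-based half-open, so coordinates are copied verbatim.
    The name column becomes the id (``bed-<ordinal>`` when absent); the
    chromosome and every further column are kept in ``attributes`` under
    their standard BED names.
    """
    cols = line.rstrip("\r").split("\t")
    if len(cols) < 3:
        raise FormatError(f"BED requires >= 3 tab-separated columns, got {len(cols)}")
    if len(cols) > 12:
        raise FormatError(f"BED allows <= 12 columns, got {len(cols)}")
    chrom = cols[0]
    start = _parse_int(cols[1], "chromStart")
    end = _parse_int(cols[2], "chromEnd")
    if start >= end:
        raise FormatError(f"start < end required (got [{start}, {end}))")

    attributes: dict[str, AttrValue] = {"chrom": chrom}
    annot_id = f"bed-{ordinal}"
    strand = "."
    for name, token in zip(_BED_OPTIONAL, cols[3:]):
        if name == "name":
            annot_id = token
        elif name == "strand":
            if token not in ("+", "-", "."):
                raise FormatError(f"invalid strand {token!r}")
            strand = token
        elif name == "score":
            try:
                attributes["score"] = int(token)
            except ValueError:
                try:
                    attributes["score"] = float(token)
                except ValueError:
                    raise FormatError(f"non-numeric score: {token!r}") from None
        elif name == "blockCount":
            attributes["blockCount"] = _parse_int(token, "blockCount")
        elif name in ("blockSizes", "blockStarts"):
            attributes[name] = _parse_comma_list(token, name)
        elif name in ("thickStart", "thickEnd"):
            attributes[name] = _parse_int(token, name)
        else:
            attributes[name] = token

    count = attributes.get("blockCount")
    if count is not None:
        for key in ("blockSizes", "blockStarts"):
            lst = attributes.get(key)
            if lst is not None and len(lst) != count:
                raise FormatError(
                    f"blockCount {count} != {key} length {len(lst)}"
                )
    return Annotation(id=annot_id, start=start, end=end, strand=strand, attributes=attributes)


def _skip_bed(line: str) -> bool:
    stripped = line.strip()
    return (
        not stripped
        or stripped.startswith("#")
        or stripped.startswith("track")
        or stripped.startswith("browser")
    )


def parse_bed(source: TextSource, strict: bool = True) -> list[Annotation]:
    """Parse a BED stream; ``track``/``browser``/``#`` lines and blanks are
    skipped.  Ordinals (used for defaulted ids) count data lines only."""
    annotations: list[Annotation] = []
    ordinal = 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if _skip_bed(line):
            continue
        try:
            annotations.append(parse_bed_record(line, ordinal))
        except FormatError as exc:
            if strict:
                raise FormatError(str(exc), line_number=lineno) from None
            logger.warning("skipping malformed BED line %d: %s", lineno, exc)
            continue
        ordinal += 1
    return annotations


def parse_gff3_record(line: str, ordinal: int = 0) -> Annotation:
    """Parse one 9-column GFF3 data line into an Annotation.

    Printed coordinates are 1-based inclusive; internally they become
    0-based half-open via (start - 1, end).  The id comes from the ID
    attribute, then Name, then ``gff-<ordinal>``.  seqid, source, type,
    score and all attributes (percent-decoded) are retained.
    """
    cols = line.rstrip("\r").split("\t")
    if len(cols) != 9:
        raise FormatError(f"GFF3 requires 9 tab-separated columns, got {len(cols)}")
    try:
        feature = feature_from_line(line)
    except Exception as exc:  # gffutils raises a mix of error types
        raise FormatError(f"unparseable GFF3 line: {exc}") from None
    printed_start = _parse_int(cols[3], "start")
    printed_end = _parse_int(cols[4], "end")
    if printed_start > printed_end:
        raise FormatError(f"start <= end required (got {printed_start} > {printed_end})")

    attributes: dict[str, AttrValue] = {
        "seqid": feature.seqid,
        "source": feature.source,
        "type": feature.featuretype,
    }
    if feature.score not in (".", "", None):
        try:
            attributes["score"] = float(feature.score)
        except ValueError:
            attributes["score"] = feature.score
    if feature.frame not in (".", "", None):
        attributes["phase"] = feature.frame
    for key in feature.attributes:
        vals = feature.attributes[key]
        attributes[key] = vals[0] if len(vals) == 1 else ",".join(vals)

    annot_id = attributes.get("ID") or attributes.get("Name") or f"gff-{ordinal}"
    strand = feature.strand if feature.strand in ("+", "-") else "."
    return Annotation(
        id=str(annot_id),
        start=printed_start - 1,
        end=printed_end,
        strand=strand,
        attributes=attributes,
    )


def parse_gff3(source: TextSource, strict: bool = True) -> list[Annotation]:
    """Parse a GFF3 stream in file order.

    ``#`` comments and ``##`` directives are skipped; a ``##FASTA``
    directive terminates parsing.  Parent attributes are retained verbatim;
    no feature hierarchy is assembled.
    """
    annotations: list[Annotation] = []
    ordinal = 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        stripped = line.strip()
        if stripped == "##FASTA":
            break
        if not stripped or stripped.startswith("#"):
            continue
        try:
            annotations.append(parse_gff3_record(line, ordinal))
        except FormatError as exc:
            if strict:
                raise FormatError(str(exc), line_number=lineno) from None
            logger.warning("skipping malformed GFF3 line %d: %s", lineno, exc)
            continue
        ordinal += 1
    return annotations


def write_bed(annotations: Iterable[Annotation]) -> str:
    """Serialize annotations as BED text.

    Emits the maximal uniform column count supported by every record so the
    output is rectangular.  Every annotation must carry ``chrom`` in its
    attributes.  Round trip: ``parse_bed(write_bed(A))`` reproduces ids,
    coordinates and strands exactly (missing scores are written as 0, the
    conventional BED filler).
    """
    annotations = list(annotations)
    if not annotations:
        return ""

    def n_columns(a: Annotation) -> int:
        # Columns 1-6 are always emittable: id is always known, score
        # defaults to the conventional filler 0 and strand to ".".
        if "chrom" not in a.attributes:
            raise ValueError(f"annotation {a.id!r} has no chrom attribute")
        n = 6
        for i, key in enumerate(_BED_OPTIONAL[3:], start=7):
            if key not in a.attributes:
                break
            n = i
        return n

    width = min(n_columns(a) for a in annotations)

    lines = []
    for a in annotations:
        cols: list[str] = [str(a.attributes["chrom"]), str(a.start), str(a.end)]
        for key in _BED_OPTIONAL[: width - 3]:
            if key == "name":
                cols.append(a.id)
            elif key == "strand":
                cols.append(a.strand)
            elif key == "score":
                cols.append(str(a.attributes.get("score", 0)))
            elif key in ("blockSizes", "blockStarts"):
                cols.append(",".join(str(v) for v in a.attributes[key]) + ",")
            else:
                cols.append(str(a.attributes[key]))
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"
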