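"""Seeded synthetic annotation generator for tests and demos.

All randomness flows through one named, versioned generator: numpy's
``default_rng`` (PCG64).  Given the same :class:`FixtureSpec` (including
seed), the output is bit-identical across runs, which is what makes
golden-file testing of rendered documents possible.

The generator emulates the shape of repeat- and phage-annotation data —
interval features with strands, family labels, age shades, and fragmented
insertions carrying consensus coordinates — not any particular genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Annotation, AnnotationGroup, PlotAnnotation, make_plot_annotation

# A small qualitative palette for family coloring in demos.
FAMILY_PALETTE = (
    "#1b9e77",
    "#d95f02",
    "#7570b3",
    "#e7298a",
    "#66a61e",
    "#e6ab02",
)

FAMILY_NAMES = ("AluYb8", "L1MC3", "MIR3", "LTR12C", "HERVK9", "Tigger1")
FAMILY_CLASSES = ("SINE/Alu", "LINE/L1", "SINE/MIR", "LTR/ERV1", "LTR/ERVK", "DNA/TcMar")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic annotation set."""

    seed: int
    n: int
    domain_start: int = 0
    domain_end: int = 100_000
    min_length: int = 200
    max_length: int = 3_000
    strand_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # +, -, .
    fragment_prob: float = 0.0  # probability an item is a fragmented group
    max_fragments: int = 3

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.min_length < 1:
            raise ValueError("min length must be >= 1")
        if self.min_length > self.max_length:
            raise ValueError("min length must be <= max length")
        if self.min_length > self.domain_end - self.domain_start:
            raise ValueError("min length exceeds domain width: spec infeasible")
        if not 0.0 <= self.fragment_prob <= 1.0:
            raise ValueError("fragment_prob must be in [0, 1]")
        total = sum(self.strand_probs)
        if any(p < 0 for p in self.strand_probs) or abs(total - 1.0) > 1e-9:
            raise ValueError("strand probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class FixtureSet:
    annotations: tuple[Annotation, ...]
    groups: tuple[AnnotationGroup, ...] = field(default_factory=tuple)


def generate_annotations(spec: FixtureSpec) -> FixtureSet:
    """Draw ``spec.n`` annotations (plus fragmented groups) within the domain.

    Lengths are uniform over [min_length, max_length]; strands follow the
    stated probabilities; every item carries chrom, family, class, score and
    an ``age_shade`` in [0, 1].  With probability ``fragment_prob`` an item
    is emitted as a ``joined_fragments`` group whose members carry mutually
    consistent consensus coordinates
    (consensus_start < consensus_end <= consensus_length).
    """
    rng = np.random.default_rng(spec.seed)
    annotations: list[Annotation] = []
    groups: list[AnnotationGroup] = []
    width = spec.domain_end - spec.domain_start

    for i in range(spec.n):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        length = min(length, width)
        start = spec.domain_start + int(rng.integers(0, width - length + 1))
        end = start + length
        strand = ("+", "-", ".")[
            int(rng.choice(3, p=np.asarray(spec.strand_probs)))
        ]
        fam = int(rng.integers(0, len(FAMILY_NAMES)))
        base_attrs = {
            "chrom": "chr1",
            "family": FAMILY_NAMES[fam],
            "class": FAMILY_CLASSES[fam],
            "color": FAMILY_PALETTE[fam],
            "score": int(rng.integers(0, 1001)),
            "age_shade": round(float(rng.uniform()), 4),
        }

        if strand != "." and rng.uniform() < spec.fragment_prob:
            groups.append(
                _fragment_group(rng, f"frag{spec.seed}-{i}", start, end, strand, base_attrs)
            )
        else:
            annotations.append(
                Annotation(
                    id=f"syn{spec.seed}-{i}", start=start, end=end, strand=strand,
                    attributes=base_attrs,
                )
            )
    return FixtureSet(annotations=tuple(annotations), groups=tuple(groups))


def _fragment_group(
    rng: np.random.Generator,
    group_id: str,
    start: int,
    end: int,
    strand: str,
    attrs: dict,
) -> AnnotationGroup:
    """Split [start, end) into 2..max disjoint fragments with gaps, and give
    them consistent coordinates on a synthetic family consensus."""
    n_frag = int(rng.integers(2, 4))
    length = end - start
    if length < 2 * n_frag:
        spans = [(start, end)]
    else:
        # Cut points partition the span into fragments separated by gaps.
        cuts = np.sort(
            rng.choice(np.arange(1, length), size=2 * n_frag - 1, replace=False)
        )
        bounds = [start] + [start + int(c) for c in cuts] + [end]
        spans = [(bounds[2 * k], bounds[2 * k + 1]) for k in range(n_frag)]

    covered = sum(e - s for s, e in spans)
    consensus_length = covered + int(rng.integers(0, covered + 1))
    lead = int(rng.integers(0, consensus_length - covered + 1))
    members = []
    cpos = lead
    for j, (s, e) in enumerate(spans):
        frag_len = e - s
        members.append(
            Annotation(
                id=f"{group_id}.{j}",
                start=s,
                end=e,
                strand=strand,
                attributes={
                    **attrs,
                    "consensus_start": cpos,
                    "consensus_end": cpos + frag_len,
                    "consensus_length": consensus_length,
                },
            )
        )
        cpos += frag_len
    return AnnotationGroup(
        id=group_id, members=tuple(members), group_kind="joined_fragments"
    )


def generate_plot_annotation(
    length: int,
    seed: int,
    step_std: float = 1.0,
    id: str = "walk",
    start: int = 0,
) -> PlotAnnotation:
    """Reflected Gaussian random walk kept >= 0, one value per position.

    Stands in for position-specific score tracks (confidence traces,
    integration frequencies).  ``step_std`` 0 degenerates to a constant
    series.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_std, size=length) if step_std > 0 else np.zeros(length)
    values = np.abs(np.cumsum(steps) + 5.0 * step_std)
    if step_std == 0:
        values = np.full(length, 1.0)
    return make_plot_annotation(id=id, start=start, values=[float(v) for v in values])
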