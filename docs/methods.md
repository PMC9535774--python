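# Methods and conventions

This note documents the model behind `annotrack`, the defaults it ships
with, and the design choices made where more than one reasonable convention
exists. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model

All coordinates are 0-based, half-open `[start, end)` integers, internally
and in every module. This matches BED natively, makes overlap a single
uniform predicate (`a.start < b.end and b.start < a.end`), and means
touching intervals never overlap (they may share a layout row). GFF3's
printed 1-based inclusive coordinates are converted on read
(`internal_start = printed_start - 1`, `internal_end = printed_end`) and
recovered on the way back by `(start + 1, end)`; a single-base GFF3 feature
has internal length 1. The 0-based half-open choice is a package convention,
not something the annotation formats force — GTF-style tooling often picks
the opposite — but one convention has to hold everywhere for layout and
clipping arithmetic to be shared.

## Parsing

BED accepts 3–12 tab-separated columns; `track`/`browser`/`#`/blank lines
are skipped, and ordinals for defaulted ids (`bed-<n>`) count data lines
only. The score column is kept as a number in attributes without clamping to
0–1000 — scores feed style callbacks, and clamping would lose information.
GFF3 record-level parsing (column handling, attribute percent-decoding)
delegates to `gffutils`; no Parent/ID hierarchy is assembled, because the
rendering abstraction is flat intervals and any grouping is a styling
concern. Parsing is strict by default (a malformed line raises with its
1-based line number); a lenient mode skips bad lines with a logged warning
for dirty real-world inputs. Id uniqueness is enforced at payload assembly,
not at parse or construction time, since files legitimately repeat names.

## Row layout

Tracks pack annotations into rows with left-endpoint greedy interval-graph
coloring over the total order `(start, end, id)`: each item takes the
lowest-index row whose rightmost occupied coordinate is ≤ its start. For
interval graphs this greedy coloring is optimal, so `row_count` always
equals the sweep-line maximum overlap depth — the test suite re-checks this
equality against an independent sweep implementation on randomized inputs.
The total order, rather than input order, is what makes the rendered
document a pure function of the payload.

Proximity aggregation (for zoomed-out views) walks start-sorted annotations
and opens a new group whenever the gap to the running group's maximum end
exceeds a threshold in semantic units. The chart supplies the threshold from
its zoom level via a layer's `gap_policy`; layout itself stays pixel-free.
Group count is monotone non-increasing in the threshold and the member
multiset is always conserved. Proximity groups may contain mutually
overlapping members (real gene clusters do); only `joined_fragments` groups
require disjoint members, because their connectors are drawn between facing
fragment edges.

## Styling

Each style property takes a constant or a callback
`(annotation, chart_context)`; callbacks must be pure and are re-evaluated
on every render, which is the whole mechanism behind semantic zoom.
Resolution validates eagerly against per-property value kinds (colors are
non-empty strings, `opacity`/`fill_shade` lie in [0, 1], `chevron_spacing`
is positive, …) and a failure names the annotation and property rather than
silently coercing. The callback signature is deliberately minimal — no
extra injection points — so chart state reaches styles only through the
context snapshot (domain, pixel range, row height, zoom scale).

## Glyph conventions

* **Age shading.** The interior gray level of an outlined repeat rectangle
  is `round(255 × fill_shade)` (round-half-up), with shade 0 = youngest =
  black and 1 = oldest = white. How alignment quality maps to a shade is the
  caller's model; the library consumes a precomputed `fill_shade`.
* **Chevron texture.** Strand is indicated by a tiled chevron pattern
  (rightward for `+`, leftward for `-`; unstranded features stay
  untextured). Pattern ids are deterministic in `(strand, spacing, color)`,
  so a document defines each distinct pattern exactly once however many
  glyphs reference it.
* **Compound glyphs.** A fragmented insertion renders one rectangle per
  fragment; consecutive fragments are joined by two line segments meeting at
  a vertex centered between the facing edges and raised half a row height
  above the glyph midline (the vertex height is a fixed convention chosen
  for determinism). Dashed flanks mark missing consensus sequence at one
  semantic unit per missing consensus base, then clip to the viewport; the
  1:1 scale is a convention, since only the *presence* of missing sequence
  is semantically required.
* **Labels.** Level-of-detail labels pick the most detailed variant whose
  estimated width `len(text) × char_width` fits the available pixels, with
  an implicit empty-string fallback. Character width defaults to 0.6 × font
  size — a deterministic, portable approximation used instead of font
  metrics, documented as approximate.
* **Plots.** Value vectors are min–max normalized onto the row band (domain
  maximum at the top); a degenerate domain (all values equal) renders at
  mid-band to avoid division by zero with a visually neutral result.
  Heatmap cells tile `[start, end)` gaplessly, one cell per base, colored by
  a ramp; the default ramp interpolates white → `#08306b` channel-wise with
  round-half-up. Plot annotations extending past the domain are sliced to it
  before glyph generation, so emitted geometry always intersects the
  viewport.
* **Tooltips.** Static per-glyph `<title>` elements (native viewer
  tooltips), not scripted popups — the informational content without a
  browser runtime.

## Charts and determinism

Rendering is a pure function of (payload, config, domain). Element order is
fixed — defs, background, axis, then per-layer glyph groups in declaration
order (top-to-bottom stacking, e.g. forward TEs / simple repeats / reverse
TEs) — attributes are written in a canonical order, and floats are printed
with exactly 3 decimals, so two renders of the same state are byte-identical
and golden-file tests are meaningful. Axis tick steps are the smallest value
in {1, 2, 5}×10^k producing at most the target tick count, placed at
multiples of the step within the half-open domain.

Two numerical details keep the scale laws exact rather than approximate:
glyph width is computed as `length × zoom_scale` (power-of-two rescaling of
the domain then changes widths bit-exactly, e.g. halving the domain doubles
them), and clipping returns the original extent untouched when a glyph is
fully visible. `x_scale` is affine with no clamping; its inverse recovers
positions to ~1e-15 relative error, well inside the 1e-9 contract.

Interactive behaviours are out of scope by design; zooming and panning are
expressed as `set_domain` + re-render, which captures the re-evaluation
semantics deterministically offline.

## Circular charts

Angle 0 sits at 12 o'clock and increases clockwise — the dominant convention
in circular genome plots — with one full turn per domain width, so
`angle_scale(domain_end) − angle_scale(domain_start)` is exactly 2π. Each
layer occupies one ring (no row packing; circular support is deliberately
light), annotations render as annular-sector paths (large-arc flag set
beyond π; full-circle features split into two half arcs, since a single-path
full circle is degenerate in SVG arc syntax), and a shaded center-to-rim
sector marks a sub-region — typically the domain currently shown in a
companion linear chart. Selection highlighting is just another style
callback keyed on an attribute flag.

## Synthetic data generator

All test and demo inputs come from a seeded generator built on numpy's
`default_rng` (PCG64), the package's single named PRNG; identical specs give
bit-identical output, which is what makes golden-file demo tests possible.
Defaults emulate the shape of a dense repeat-annotation region: a 100 kb
domain, feature lengths uniform on [200, 3000] bases, strands 45/45/10 %
(+/−/unstranded), uniformly distributed family labels from a six-family
palette, scores uniform on [0, 1000], and age shades uniform on [0, 1].
Fragmented insertions split a span into 2–3 disjoint fragments with
internally consistent consensus coordinates
(`consensus_start < consensus_end ≤ consensus_length`). Value tracks are
reflected Gaussian random walks kept non-negative (constant when the step
deviation is 0), standing in for position-specific score traces.

What the generator does *not* emulate: real repeat length distributions are
heavy-tailed and family-dependent, real annotations cluster and nest far
more than uniform placement does, and real consensus coverage correlates
with age. Passing tests therefore demonstrate the renderer's contracts
(layout optimality, determinism, clipping, round-trips) on data of realistic
shape and density — they do not validate any biological inference, of which
the package makes none.

## Problem sizes

The test suite and acceptance script use 1000 annotations for round-trip
checks, 200 random interval sets (up to 500 intervals each) for layout
optimality, 40 randomized aggregation scenarios, and demo figures of 6–60
features or 250-position value tracks — sizes at which every property the
package guarantees is already fully exercised while the whole suite runs in
seconds.

## CLI configuration schema

`annotrack render --config FILE` accepts a YAML mapping with chart keys
(`width`, `height`, `row_height`, `pad`, `axis`, `axis_height`,
`background`, `layer_gap`), an optional `style` mapping of constants, an
optional `glyph` kind, and `strand_split: true` to split input into
forward/unstranded/reverse layers. Callbacks are programmatic-only:
serializing code in config files invites injection and non-determinism.

## Known limitations

No GTF/BigBed/tabix input, no gene-model hierarchy, no arrowed exon glyphs
or synteny ribbons, no font shaping (label widths are estimates), no raster
export, and no in-browser interactivity. Layer heights assume one row band
per plot track; multi-row plot layouts need explicit row-height choices by
the caller.
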