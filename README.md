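# annotrack

Deterministic, scriptable SVG rendering of biological sequence annotations.

Genome and protein annotations — genes, transposable-element (TE) calls,
repeat fragments, phage integrations, per-position confidence scores — are
usually drawn as horizontal tracks of glyphs over a coordinate axis.
`annotrack` is a small toolkit for building such figures offline, aimed at
pipeline authors and tool developers who need precise control over glyph
semantics and byte-stable output (golden-file testable, diff-able in version
control) rather than an interactive browser.

The toolkit is organised around a minimal abstraction: an annotation is an
identifier plus a half-open interval `[start, end)` (0-based, BED-style),
optionally with a strand, an open attribute mapping, and — for
position-specific data — one numeric value per base. Everything else is
composed from that:

* **IO** — readers for BED (3–12 columns) and GFF3 (with the 1-based
  inclusive → 0-based half-open conversion), and a BED writer that
  round-trips exactly.
* **Layout** — annotations sharing a track are packed into rows by
  left-endpoint greedy interval-graph coloring, which is provably optimal:
  the number of rows equals the maximum interval overlap depth. Nearby
  features can be condensed into proximity groups for zoomed-out views.
* **Styling** — every glyph property (`fill_color`, `fill_shade`,
  `opacity`, `label_variants`, …) accepts either a constant or a callback
  `(annotation, chart_context) -> value`, re-evaluated at every render.
  Re-rendering under a new domain is therefore *semantic* zoom: labels,
  aggregation and colors can all respond to the zoom scale.
* **Glyphs** — rectangles colored by family; age-shaded outlined rectangles
  (grayscale interior: shade 0 = youngest = black, 1 = oldest = white) with
  chevron strand texture; compound glyphs for fragmented TE insertions
  (fragment rectangles joined by angled connectors, dashed flanks showing
  missing consensus sequence, level-of-detail text labels); line/bar plots
  and heatmaps for value vectors.
* **Charts** — a linear chart with axis, layer stacking and an element
  index, and a circular chart (arcs on concentric rings, plus a shaded
  sector marking the region a companion linear view shows). Panels compose
  into one document.

## Worked example

```python
from annotrack import (Annotation, ChartConfig, Layer, LinearChart,
                       greedy_pack, max_overlap_depth, parse_bed)

bed = """chr1\t100\t2600\tAluYb8\t610\t+
chr1\t2000\t4400\tL1MC3\t540\t-
chr1\t4200\t5800\tMIR3\t300\t+
"""
annotations = parse_bed(bed)
assignment = greedy_pack(annotations)
print("rows used:", assignment.row_count, "| sweep-line depth:", max_overlap_depth(annotations))
print("row of each:", {a.id: assignment[a.id] for a in annotations})

chart = LinearChart(ChartConfig(domain_start=0, domain_end=6000, width=600))
layer = Layer(
    name="tes",
    data=tuple(annotations),
    style={"fill_color": lambda a, c: "#1b9e77" if a.strand == "+" else "#d95f02"},
)
result = chart.render([layer])
print("SVG bytes:", len(result.svg))
print("indexed glyphs:", sorted(result.element_index))
print("px per base:", result.context.zoom_scale)
```

prints

```
rows used: 2 | sweep-line depth: 2
row of each: {'AluYb8': 0, 'L1MC3': 1, 'MIR3': 0}
SVG bytes: 1936
indexed glyphs: ['AluYb8', 'L1MC3', 'MIR3']
px per base: 0.09866666666666667
```

`AluYb8` and `L1MC3` overlap (both cover bases 2000–2600), so they occupy
two rows — exactly the sweep-line overlap depth — while `MIR3` reuses row 0.
The strand callback colored forward features green and reverse features
orange, and `result.svg` holds the finished document; rendering the same
payload again yields the identical bytes.

## Command line

```sh
annotrack render --bed features.bed --out track.svg --width 800 --domain 0:100000
annotrack render --demo repeatmasker --seed 7 --out demo.svg
```

`--demo {dfam,repeatmasker,occurrences,circular}` renders built-in synthetic
figures: strand-separated TE tracks, an information-dense repeat track with
compound glyphs, a position-specific value plot with heatmap, and a circular
genome chart with sector shading. `--config` accepts a declarative YAML file
(chart geometry and style constants; callbacks are programmatic-only).

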