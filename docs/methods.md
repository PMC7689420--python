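# Methods

## What the package computes

volcanokit reproduces, as a desk-scale library and CLI, the computational
core of an interactive volcano-plot service for comparative genome- and
proteome-wide screens: reading effect-size/significance tables, three-way
threshold classification, distance-based hit ranking, annotated figure
rendering, and lossless (de)serialization of the complete plot state to a
shareable URL.

A point is a pair (x, y) with x the effect size (log2 fold change, 0 = no
change) and y the significance (−log10 p-value, larger = more
significant). Classification against thresholds (fc_low, fc_high, sig):

* increased ⇔ x > fc_high and y > sig
* decreased ⇔ x < fc_low and y > sig
* unchanged otherwise.

Comparisons are strict: a point exactly on a dashed threshold line is
unchanged, so the lines are unambiguous separators. This was a genuinely
open choice (either convention classifies "the data"); strictness was
chosen and is asserted by the boundary tests.

Hit ranking scores each point by its distance from the origin (0, 0):

| criterion | score |
|---|---|
| manhattan (default) | \|x\| + \|y\| |
| euclidean | √(x² + y²) |
| fold_change | \|x\| |
| significance | y |

`significance` uses y as-is rather than \|y\|: y is −log10 p and
non-negative by construction, so malformed negative values sink to the
bottom instead of masquerading as strong hits. Ranking sorts the
direction-eligible records (increased, decreased, or their union
"significant") by descending score with a *stable* sort, so ties keep
their input order — reproducible without injecting arbitrary secondary
keys — and keeps the top n (default 10). Because the sort is a total
stable order, top-k is always a prefix of top-(k+1); the suite checks
this nesting property and checks every criterion against an independent
brute-force "score everything, full sort, take prefix" oracle.

Manual annotation is exact name matching after case-folding and
whitespace trimming. Substring matching was rejected deliberately: on
gene symbols it produces surprising multi-hits (a query for one symbol
also catching its paralogs). Unmatched queries warn rather than fail, so
a stale gene list never blocks a plot. Manual picks merge into the hit
table after the ranked block, without duplication.

## Data input

Text tables (CSV/TXT) are delimiter-sniffed over the first 10 lines among
comma, tab and semicolon: the candidate whose per-line field count is
most consistent with the first line wins, with ties broken in the fixed
order comma > tab > semicolon (determinism over cleverness). A header row
is mandatory — column selection presupposes named columns. Duplicate
headers are suffixed `_2`, `_3`, … deterministically; short rows are
padded with empty cells, long rows rejected. `.xlsx` workbooks are read
via openpyxl with by-name sheet selection (first sheet when unspecified);
legacy `.xls` needs an engine this package does not carry and is rejected
with a clear message. A configurable size guard (default 10 Mb, the
standalone-app limit) rejects oversized inputs before parsing. Remote
CSVs are fetched over http/https with a single attempt and no
authentication.

Column mapping coerces the chosen x/y columns to floats. Rows with
non-coercible or non-finite values are dropped — not errored — and the
count is surfaced as `n_dropped`, because screen exports routinely
contain `NaN` and blank cells and the plot must still appear. Infinite
significance (p = 0 gives y = ∞) is treated as non-finite and dropped by
default; `cap_infinite=` opts into clamping instead. Dropping is the
conservative, reportable default since no capping rule is inherent to
the data. Row conservation (kept + dropped = source rows) is a tested
invariant.

## Share-URL codec

The state URL grammar (docs/share-url-grammar.md) was fixed from two
published example URLs that serve as exact decode vectors in the test
suite. Fields whose semantics those examples cannot pin down — the
data-section mode code, the five layout head fields, the rotation token,
section tails — are carried as typed-opaque strings and re-emitted
byte-identically, so sharing never corrupts a URL produced elsewhere.
Both observed arity variants (vis with or without the criterion token;
layout with or without axis-scale tags) decode; the encoder emits the
scale tags exactly when the state carries them, which is what makes
`decode ∘ encode ∘ decode == decode` hold on both vectors — emitting only
the newer, tag-less variant would silently drop the tags of the older
one.

Assumptions recorded: of the two trailing layout numbers (`600;800`) the
first is taken as height and the second as width; the four label-section
integers map to title/axis-title/tick/point-label font sizes; a rotation
token `Y` is read as the 90°-rotated layout. All three are preserved
verbatim on round-trip regardless of interpretation. Color codes 1
(grey/red/blue) and 2 (grey/blue/green) are the two documented palettes;
other codes (code 3 appears in one vector) round-trip faithfully but fall
back to palette 1 with a warning rather than inventing a palette.

## Rendering

The figure is a matplotlib scatter (one collection per category, giving
the legend for free), dashed lines at the three cutoffs, and text labels
for the hit table. With `rotated=True` the effect size moves to the
vertical axis and the significance to the horizontal one. Default style
values (dot size 4, alpha 0.8, 600×800 px canvas at 100 dpi, font sizes
24/24/18/6 pt) are the defaults observed in the example URLs.

Label placement is a bounded greedy repulsion in axes-fraction space:
boxes sized from text length start above-right of their anchor, each
sweep pushes every overlapping pair apart along the axis needing the
smaller displacement (a fixed 10⁻³ sideways nudge breaks exactly
coincident centers deterministically), clamps boxes into the axes, and
the pass stops at convergence or after `max_iter` (default 100) sweeps.
Unresolved overlaps after the budget are permitted and visible in the
returned placements; the tests verify zero overlaps by exhaustive
pairwise box intersection at the default figure size. The algorithm is
deliberately simple: deterministic given input order and dependency-free.

Exports: PNG (bitmap at the styled pixel dimensions), PDF (vector), and
a standalone interactive HTML document. The HTML is a hand-written SVG in
which every record is a circle with a native `<title>` tooltip showing
its name and coordinates rounded to 3 decimals — hover works in any
browser with zero JavaScript. Other formats (e.g. SVG files) are
explicitly unsupported.

## Synthetic screens

The generator emulates only the *shape* of screen exports — a majority of
null points near the origin plus a minority of strong hits — not their
biology. Nulls draw x ~ Normal(0, noise_scale) and y ~ Exp(1) truncated
below `sig_shape` (inverse-CDF sampling, so the same seed is
byte-reproducible); hits draw |x| ~ effect_scale + Exp(1) with the sign
of their direction and y ~ sig_shape + Exp(1). Defaults (n = 1000, 5%
increased, 5% decreased, effect_scale 3, noise_scale 0.5, sig_shape 4)
put the two populations strictly on opposite sides of the default 1.5/2
cutoffs, so ground-truth categories are exactly recoverable — which is
what makes the pipeline-closure and planted-hit-recovery tests sharp.
Planted names go to the strongest increased hits first (then decreased),
making "name the top hit GNAS" deterministic. What passing these tests
does **not** show: robustness to correlated noise, p-value miscalibration,
count-level artifacts, or any other feature of real screens the generator
does not model.

## Problem sizes and tolerances

All tests and the acceptance script run on one CPU in well under their
budgets: ranking properties use 100–200 points over 20 seeds, the codec
round-trip uses the two published vectors plus 1000 randomly generated
states, the default-annotation check uses a 10,000-point screen, and
label placement uses 25 random anchors. Numeric comparisons are exact
where the computation is exact (decoding, counting, sorting) and use
pytest's default approx tolerance only for float round-trips through
CSV/XLSX.

## Known limitations

* No p-value computation, multiple-testing correction or enrichment
  statistics — the tool ranks values computed upstream.
* The HTML export offers hover only; no brushing, zooming or server.
* Remote fetch is single-attempt http/https without authentication.
* Opaque URL fields are preserved, not interpreted; a state produced by
  other software with meaningful values in those fields will round-trip
  but those meanings are not acted upon.
* Legacy `.xls` input is rejected; JSON/Parquet are out of scope.
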