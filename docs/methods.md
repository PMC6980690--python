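# Methods

This note records the models, conventions and numerical choices behind
`traceviz`, and what its synthetic data do and do not establish about
real measurements.

## Canonical data model

All input converges on a tidy table of records
`(time, value, object_id, condition_id)`. Within a condition an
`(object_id, time)` pair occurs at most once; times are finite; values
are finite or explicitly missing (NaN). Missing cells found in wide
input are *kept* as missing records rather than dropped, so heatmaps
can show gaps and record counts stay predictable
(n_records = n_times × n_objects per condition).

Conventions chosen where the behavior was genuinely open:

- Wide-file condition labels are the file basename with the extension
  stripped (cosmetic; the full name minus `.csv`/`.xlsx` is what users
  mean by "the file").
- Object ids colliding across condition files are disambiguated by
  prefixing the condition (`ctrl:A`, `drug:A`); ids unique anyway are
  left untouched.
- Header sanitizing replaces spaces with underscores; duplicate names
  after replacement get numeric suffixes (`a_b`, `a_b_2`). The map is
  idempotent, so re-reading an already-sanitized file changes nothing.
- XLSX input reads the first worksheet only. Decimal separator is the
  period; the field separator is the comma (RFC 4180).
- Exported tidy CSV writes floats with `%.17g`, and re-import parses
  with Python's correctly-rounded `float()`, so write→read is an exact
  identity on IEEE doubles (pandas' fast CSV float path is not
  correctly rounded and is deliberately bypassed).

## Normalization

All methods operate per object, within its condition; conditions never
share baselines. With I(t) the object's raw values and I₀ the
*arithmetic mean* of its non-missing values in the baseline window
(inclusive on both ends, in time units — not sample indices):

| method       | map                         | error conditions            |
|--------------|-----------------------------|-----------------------------|
| `none`       | identity                    | —                           |
| `fold`       | I / I₀                      | empty window; I₀ = 0        |
| `delta_fold` | (I − I₀) / I₀               | empty window; I₀ = 0        |
| `div_max`    | I / max(I)                  | max = 0 or undefined        |
| `minmax`     | (I − min) / (max − min)     | constant trace (max = min)  |

The mean (not median) was chosen for I₀ as the plainest reading of "a
baseline value"; with a quiet pre-stimulus window the two coincide for
practical purposes. `div_max` and `minmax` are deliberately two
distinct methods — dividing by the maximum preserves the baseline
offset, min–max scaling removes it — because the two maps answer
different questions and conflating them hides that.

## Summary statistics

Per condition and per distinct time point, the mean over non-missing
object values and the 95% CI of the mean,
mean ± t₀.₉₇₅,ₙ₋₁ · s/√n, with s the sample standard deviation
(ddof = 1). For n = 1 the interval is undefined and reported as NaN
(and line plots warn instead of drawing an empty ribbon). The
t-interval is the standard small-sample choice and matches what
`mean_cl_normal`-style plot summaries compute; a bootstrap alternative
was considered out of scope. Times are grouped by exact numeric
equality — no interpolation across unequal grids, so mismatched grids
simply yield per-time n that varies.

## Color

Qualitative palettes: Okabe–Ito (8 colors, default) and Paul Tol's
bright (7), muted (10) and light (9) schemes, stored as uppercase hex.
When objects outnumber colors the palette recycles
(`color[i mod n_colors]`), which is honest about the limit of
qualitative coloring rather than inventing indistinguishable hues. User
color strings accept hex codes and names; names resolve through the
CSS/X11 extended table, an R-compatibility table for X11 numbered
variants (`turquoise2` → `#00E5EE`), and programmatic `greyN`/`grayN`
(N ∈ 0…100). Heatmaps always use the perceptually uniform viridis map;
qualitative palettes are not accepted there.

## Displays

- **Lines**: one polyline per object; optional per-condition mean line
  and translucent CI ribbon on top; thickness and alpha of the data and
  statistics layers are independent.
- **Small multiples**: ceil(√m) columns and ceil(m/cols) rows — an
  approximately square grid — with shared x/y limits so panels are
  comparable.
- **Heatmap (lasagna)**: rows = objects in sort order (first row on
  top), columns = times ascending, one *global* color scale across all
  objects (a per-object scale would make rows incomparable, defeating
  the display's purpose), masked cells for missing values, colorbar
  alongside.
- **Sorting**: by per-object maximum, by integrated response
  (trapezoidal area on the object's own time grid — no resampling), or
  alphabetically; ties break lexicographically so orders are total and
  deterministic.
- **Direct labels** sit in the right margin at each trace's final
  value. Overlaps are resolved by a 1-D scheme: process labels from
  highest desired position down (stable for ties, so coincident labels
  keep input order top-to-bottom), push each label below its
  predecessor by at least one label height, then shift the chain back
  inside the axis bounds. This is a deliberate simplification of
  published force-based label repulsion: it guarantees the only
  property that matters here (pairwise separation ≥ label height with
  stable order) in one pass.
- **Treatment annotations**: `bar` draws a filled rectangle in a strip
  above the axes with the label text over it; `box` a translucent
  full-height span; `bar_and_box` both. Intervals outside the plotted
  range are clipped (partial) or skipped (fully outside) with warnings.
- PNG output is pixel-exact: figures are sized at width/100 ×
  height/100 inches and rendered at 100 dpi.

## Plot-state query strings

The entire user-facing state serializes to
`group=field;field;…` joined by `&`, groups ordered
`data, vis, layout, color, label, stim`. Fields are positional; empty
fields keep their positions; list-valued fields use commas; spaces
travel as `%20` (and `%` as `%25`, making encoding lossless). Decoding
tolerates a leading `?`, a full URL, and trailing `&.`, `&` or `.` —
query strings quoted in running text tend to pick up sentence
punctuation, and a bare trailing period is ambiguous with a decimal
point only for a field that would be malformed anyway. Unknown groups
are preserved verbatim (with a warning) so decode→encode is lossless
even on extended inputs.

Mapped positions: `data[3]`=normalization method, `data[4]`=baseline
window; `vis[0]`=display mode, `vis[1]`=data alpha (0 hides raw
traces), `vis[2]`/`vis[3]`=show mean/CI, `vis[4]`=stat alpha;
`layout[1]`=hide-grid flag, `layout[9]`/`layout[10]`=width/height in
px; `label[3]`/`label[4]`=axis titles; `stim` as below. Positions not
listed are carried opaquely. Booleans encode as `TRUE` (decoding also
accepts `T`); an empty field is false.

The `stim` group is `enabled;style;boundaries;labels;colors`:
boundaries are a flat comma list paired in order into intervals
(b₁,b₂), (b₃,b₄), …; the i-th label and color attach to the i-th
interval, defaulting to empty text and grey. An odd trailing boundary
is dropped with a warning — the documented resolution of an ambiguity
that real-world state strings exhibit.

## Clustering

Objects must share a time grid; time points missing for any object are
dropped for all (with a warning) before the objects × timepoints matrix
is built. Distances are Euclidean (via scipy's `pdist`) or classic DTW:
local cost |aᵢ − bⱼ|, symmetric match/insert/delete steps, no window,
no path normalization — the textbook dynamic program, implemented
directly since the simplest variant is the point. The agglomeration is
Ward.D2 — the minimum-variance criterion applied to *unsquared*
distances — which is exactly scipy's `linkage(method="ward")` on a
condensed distance matrix; cut heights are nondecreasing and the cut at
k relabels clusters by first appearance so assignments are
deterministic and contiguous from 1.

Validation indices, all oriented higher-is-better:

- **Calinski–Harabasz**: CH = [B/(k−1)] / [W/(m−k)] with B and W the
  between-/within-cluster sums of squared centroid distances. Edge
  conventions: W = 0 with B > 0 → +∞ (perfectly tight clusters);
  B = 0 (all points identical) → 0.
- **Mean silhouette width**, computed from the distance matrix (so it
  is meaningful for DTW too); singleton clusters contribute 0.
- **Dunn index**: minimum between-cluster distance over maximum
  within-cluster diameter; zero diameter → +∞.

CH and silhouette are cross-checked against scikit-learn in the test
suite; scikit-learn is never the implementation. The scan reports the
full (index, k) table and the argmax-k per index, ties resolved toward
the smallest k (the more parsimonious model). A CVI is a summary
statistic of the data: its argmax need not reflect underlying biology,
which is why the table, not just the winner, is part of the output.

Clustering runs on whatever values are current — i.e. after any
normalization, mirroring the pipeline order. This matters: clustering
raw traces lets cell-to-cell magnitude differences dominate the
distances, whereas clustering min–max-scaled traces groups by response
*shape* (timing, kinetics). Shape is usually what cluster analysis of
signaling dynamics is after.

## Synthetic data

The generator emulates a perturbation–response time-lapse experiment:

    value(t) = b · (1 + A · f(t)) + ε(t)

with f(t) a rise–plateau–decay shape — zero before t_on, saturating
exponential rise (τ_rise) to a plateau, exponential decay (τ_decay)
after t_off — A ~ lognormal(0, σ_A) per object (positive, right-skewed
response magnitudes) and ε ~ N(0, σ_ε²) i.i.d. per sample. Defaults: 10
objects per condition, grid 0–240 every 5 time units, b = 1, t_on = 60,
t_off = 140, τ_rise = 15, τ_decay = 30, σ_A = 0.3, σ_ε = 0.05 (5% of
baseline) — magnitudes representative of ratiometric biosensor
recordings. Given a seed, output is byte-identical across runs.

`generate_clustered_traces(c, separation)` produces c groups whose
*activation windows* are spread across the grid proportionally to
`separation`: at separation 0 the archetypes coincide (recovery is at
chance), at separation 1 the windows barely overlap. Amplitude
heterogeneity stays lognormal *within* every group. A consequence worth
stating plainly: on raw traces each group forms a ray (baseline +
A·shape, A varying), and variance-ratio criteria like CH reward
splitting rays, so the CH argmax overshoots the group count even though
the partition at the true k is essentially perfect. After min–max
scaling the amplitude dimension collapses and all three indices recover
the true k reliably — the package's recovery experiments therefore
cluster shape-normalized traces, which is also the recommended practice.

What the synthetic data do **not** emulate: photobleaching and drift,
heteroscedastic or temporally correlated noise, missing stretches from
segmentation dropouts, unequal time grids across objects, and
cell-cycle or spatial covariates. Passing recovery tests show the
clustering machinery is correct under the stated model, not that any
particular biological data set has c clusters.

## Numerical and interface choices

- Baseline windows, annotation intervals and time grids are in the
  data's own time units throughout; nothing is frame-indexed.
- The figure-introspection test surface (artists tagged by gid, raster
  arrays, grid geometry) deliberately avoids pixel comparisons, which
  are brittle across matplotlib versions.
- Cluster-number recovery experiments use 100 runs of 3 groups × 10
  objects × 49 time points — small enough to run in seconds, large
  enough that a ≥95% success criterion is meaningful.
- The CLI logs stages to stderr and reserves stdout for the encoded
  state string, so shell pipelines can capture the "clone" directly.

## Known limitations

- DTW is the classic O(nm) dynamic program without banding; for very
  long series (>10³ points) pairwise matrices get slow.
- The label scheme is 1-D: it never moves labels horizontally.
- Decoding state strings from other tools preserves unknown fields but
  cannot interpret them; only the positions documented above map onto
  settings.
- No multi-sheet XLSX, no autodetection of wide vs tidy layout (an
  explicit flag is required), no interactive display.
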