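# Methods

## Model

A horizon track displays a per-pixel-column value series over a genomic
region. Three exact transforms define the encoding; everything else in
the package is plumbing around them.

**Coordinate mapping.** A chart context pins the region `[start, end)`
on one chromosome and a column count `w`; the per-column step is the
rational `step = (end − start)/w`. Column `c` covers
`[start + round(c·step), start + round((c+1)·step))` with round-half-up,
computed in exact rational arithmetic, so the columns tile the region
with no gaps or overlaps and the last column absorbs any remainder. All
coordinates are 0-based half-open (the BED convention); 1-based numbers
appear only in rendered axis labels. If `w` exceeds the region length,
`w` is clamped to one column per base (with a warning) rather than
permitting zero-length columns.

**Binning.** Records may overlap, be unsorted, and extend beyond the
region (clipped; other chromosomes ignored). Aggregators: `mean` is the
overlap-base-weighted mean — each base takes the mean of its covering
records, the column averages over *covered* bases — computed by a
boundary sweep so it is exact, order-free, and never materializes
per-base arrays; `max`/`min` take the extremum over records overlapping
the column; `sum` spreads `value × overlap / column_length`. Columns
with no covered base follow the gap policy: `zero` by default (for
depth, absence of coverage *is* depth 0), or `missing` (blank column).
`mean` is the default because read depth is an intensive quantity.

**Band decomposition.** With extent `V`, bands `n`, band unit `u = V/n`:
`s = min(|v|, V)/u`, `fill_i = clamp(s − i, 0, 1)`, sign from `sgn(v)`,
`clipped` when `|v| > V`. The inverse is `sign · u · Σ fill_i`, equal to
`clamp(v, −V, V)` to float round-off. Structural invariant: at most one
partial band, everything below it full, everything above empty. A
missing value maps to an all-empty stack carrying a distinct flag.

**Rendering.** One rectangle per non-empty band per column, all anchored
at the track baseline, heights `fill_i × track_height` rounded to whole
pixels, painted in band order so darker bands overlay lighter ones.
Runs of columns with identical quantized stacks merge into single
rectangles (pixel-identical, smaller files). The SVG is built from
sorted, integer-only geometry with no timestamps or generated ids, so
identical inputs give byte-identical documents. `decode_track_values`
inverts the drawing using only rectangle geometry and palette colors;
its error bound is one vertical pixel, i.e. `u / track_height` in value
units (the acceptance measurements put the worst case at ~0.5 px, the
rounding bound).

## Data backends

The in-memory source loads a whole file and answers overlap queries
from per-chromosome arrays sorted by start. The scalable path is a
sidecar *linear binning index* over a start-sorted file: fixed bins
(16 384 bp default) each store the smallest byte offset of any
overlapping record. Because the file is start-sorted, per-bin offsets
are non-decreasing, so a region query seeks to the first present bin's
offset and scans forward until a record starts at or past the region
end. The sidecar is little-endian with magic `HZBIDX01`, the bin size,
and the indexed file's size and CRC-32 (queries against a changed file
raise a staleness error) followed by per-chromosome sparse bin tables.
The HTTP service wraps indexed files behind `GET /v1/samples` and
`GET /v1/data/{sample}?chrom=&start=&end=`, returning compact JSON rows;
the client source satisfies the same query contract as the file sources,
and charts built from either are byte-identical. The server uses the
standard library's threading HTTP server — the payloads are small,
bounded by the query region, and need no framework.

## Tunable parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| `n_bands` | 4 | — | The classic horizon trade-off between height compression and hue discriminability. |
| `extent` | global max \|value\| across tracks | value units | A shared extent keeps tracks cross-comparable, which multi-sample QC requires; per-track extent is available by flag. |
| `mode` | `mirror` | — | Mirroring halves vertical space; `offset` (negatives hanging from the top edge) is implemented but non-default. |
| palettes | 4 greens / 4 blues, light→dark | — | Hue encodes sign; non-negative signals therefore show a single hue family. Ramps are resampled by piecewise-linear RGB interpolation so every band count gets distinct shades (distinct colors per band are required for geometric decoding). |
| `track_height_px` | 20 | px | Desk-scale default; decode precision is `extent/(n_bands·height)` per pixel. |
| gutter / label column / axis | 2 px / 80 px / 18 px | px | Layout constants; chart height is `n_tracks·(track_height+gutter)` plus the axis. |
| index `bin_size_bp` | 16 384 | bp | Power of two in the tabix tradition; small enough that a query scans only a few records, large enough to keep sidecars tiny. |

## Synthetic cohort

The simulator emulates the multi-sample WGS QC scenario: 24 samples,
chr17:1,100,000–1,200,000, mean depth 30, 100 bp windows (1 000 records
per sample). Window value = `mean_depth × dropout multiplier ×
per-sample factor + N(0, noise_sd)`, truncated at 0; windows partially
overlapping a dropout interpolate the multiplier by overlap fraction.
Defaults chosen once: noise SD 3 (a 10 % coefficient of variation on
window-mean depth, typical of WGS window summaries), dropout multiplier
0.2, low-sample factor 0.3. The demo cohort places two shared dropouts
(20–25 kb and 60–68 kb into the region) and makes sample 10 the low one.

What it does *not* model: read-level Poisson sampling, GC or mappability
bias, insert-size structure, alignment artifacts. Passing tests
demonstrate that the pipeline is correct and that defects of the
simulated kind are recoverable from rendered output — not that real
sequencing noise looks Gaussian.

## Numerical choices and degenerate inputs

- Column boundaries and the region/width arithmetic use `fractions.Fraction`;
  region-string coordinates (`1.1M`) parse through `decimal.Decimal`, so
  no float rounding enters coordinate handling.
- Binned `mean` agrees with the per-base brute-force oracle to ≤ 1e-9
  relative (sweep summation order differs); `max`/`min` agree exactly.
- Zero-valued and missing columns both draw nothing; they are
  distinguishable in the `ValueSeries` (and by gap policy) but not from
  chart geometry alone — a documented display limitation.
- Values beyond ±extent saturate the top band and draw a thin 1 px tick
  at the track's top edge.
- An all-zero/empty chart keeps a valid config by falling back to
  extent 1.
- Empty BED files index to a valid empty sidecar; a query with no
  overlapping bin returns without touching the data file.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale instances
chosen to exercise every code path while staying quick: 10⁵ random
round-trip pairs, 500 fuzzed binning cases on regions up to 10 kb,
3 000-record files with 200 random queries for backend agreement,
64-column charts for decode checks, and the full 24 × 1 000-record
cohort for the end-to-end demo. The whole suite runs in well under a
minute on one CPU.

## Known limitations

- Gzip-compressed BED files are supported by the parser but not by the
  linear index (offsets address uncompressed bytes only); index plain
  files.
- Chromosome names are not normalized (`chr17` ≠ `17`), and one chart
  covers one region on one chromosome.
- PNG output rasterizes rectangles only (labels and axis text are
  skipped); SVG is the primary, golden-testable format.
- The HTTP service is a plain localhost tool: no TLS, authentication or
  CORS policy.
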