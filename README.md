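# horizonbed

Horizon-chart rendering of multi-sample genomic signal tracks.

## The problem

Sequencing studies routinely need to eyeball a quantitative signal —
read depth above all — across *many* samples at once, for example to
spot failed libraries or systematically underrepresented regions during
quality control. Conventional line or area tracks spend vertical space
proportional to the value range per track, so a 24-sample cohort quickly
outgrows a screen. A **horizon chart** is an area chart compressed in
three steps that together preserve graphical perception while dividing
the required height by `2·n` for `n` bands:

1. **Banding.** The value range `[0, V]` is cut into `n` bands of height
   `V/n`; the fill color darkens with the band index, so magnitude is
   encoded by hue intensity as well as height.
2. **Mirroring.** Negative values are flipped above the baseline in a
   contrasting hue (greens for positive, blues for negative here) —
   exactly half the vertical space of a two-sided chart.
3. **Collapsing.** All bands are drawn anchored at the baseline and
   overplotted, a further `n`-fold reduction: each track needs only
   `V/n` worth of pixels.

Formally, with clamp value (*extent*) `V` and band unit `u = V/n`, a
value `v` maps to the band stack

```
s        = min(|v|, V) / u
fill_i   = clamp(s − i, 0, 1),   i = 0 … n−1
sign     = sgn(v)
```

and the transform is invertible: `sign · u · Σ fill_i = clamp(v, −V, V)`.
That invertibility is what makes a rendered chart *checkable* — rectangle
heights measured off the SVG reconstruct the binned input values.

`horizonbed` applies this to genomic coordinates: the x-axis is a
chromosomal region instead of time, values come from BED/BedGraph files,
and a chart *context* (region + pixel budget) maps base positions to
pixel columns. Data reaches the chart through interchangeable backends:
an in-memory BED source for small files, or an indexed HTTP *bedserver*
(a single-level, tabix-style linear binning index: 16 kb bins → smallest
file offset of an overlapping record) for data too large to load.

## Worked example

Decompose values with 4 bands and extent 100 (band unit 25), then invert
(`examples/01_band_decomposition.py`):

```
value     0.0 -> sign +0, fills (0.0, 0.0, 0.0, 0.0), clipped=False -> reconstructs to 0.0
value    37.5 -> sign +1, fills (1.0, 0.5, 0.0, 0.0), clipped=False -> reconstructs to 37.5
value   -37.5 -> sign -1, fills (1.0, 0.5, 0.0, 0.0), clipped=False -> reconstructs to -37.5
value   130.0 -> sign +1, fills (1.0, 1.0, 1.0, 1.0), clipped=True  -> reconstructs to 100.0
```

37.5 fills the first band and half the second; −37.5 is the same stack
mirrored into the negative hue; 130 exceeds the extent, saturates all
bands and is flagged clipped, reconstructing to the clamp value.

Render the full QC scenario — 24 simulated whole-genome samples at 30×
over chr17:1.1M–1.2M, two shared dropout holes, one globally
low-coverage sample (`examples/03_multisample_qc_chart.py`):

```
simulated 24 samples over chr17:1100000-1200000
low-coverage sample: sample_10
wrote qc_chart.svg (3327249 bytes, 24 tracks)
```

The 24 tracks occupy `24 × (20 + 2) = 528` vertical pixels regardless of
the depth scale. In the image, the shared dropouts appear as pale
vertical stripes in *every* track and `sample_10` is a uniformly pale
track — the two defects this visualization exists to expose.

The same chart from the command line, or via the server:

```sh
horizonbed simulate --samples 24 --region chr17:1.1M-1.2M --depth 30 \
    --low-sample 9 --dropout 1120000-1125000:0.2 --seed 1 --out cohort/
horizonbed render --region chr17:1.1M-1.2M --width 800 cohort/*.bed -o qc.svg
horizonbed serve cohort/ --port 8765 &
horizonbed render --region chr17:1.1M-1.2M --width 800 \
    --server http://127.0.0.1:8765 -o qc_from_server.svg
```

`qc.svg` and `qc_from_server.svg` are byte-identical: sources are
interchangeable and rendering is fully deterministic.

See `examples/` for runnable scripts covering each capability
(decomposition, binning, end-to-end chart, indexed/HTTP sources, and
spot-checking a rendered chart against its input).

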