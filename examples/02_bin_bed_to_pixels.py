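"""Parse a small BedGraph and bin it to per-pixel values.

The chart context maps a genomic region onto a fixed number of pixel
columns; binning reduces the interval records falling in each column to
one value (overlap-weighted mean by default, the right reduction for an
intensive signal like read depth).
"""

import io

from horizonbed import ChartContext, bin_records, parse_bed, parse_region

bedgraph = io.StringIO(
    "track name=depth\n"
    "chrA\t0\t400\t10\n"
    "chrA\t400\t600\t30\n"
    "chrA\t600\t1000\t10\n"
)
result = parse_bed(bedgraph)
print(f"parsed {len(result)} records ({result.skipped} header/comment lines skipped)")

ctx = ChartContext(parse_region("chrA:0-1000"), width_px=4)
series = bin_records(result.records, ctx, aggregator="mean")
for col, value in enumerate(series.values):
    iv = ctx.pixel_to_interval(col)
    print(f"column {col}: {iv} -> {value:.1f}")

# Each of the 4 columns covers 250 bp.  Columns fully inside one record
# take its value (10); columns 1 and 2 straddle the value-30 stretch at
# bases 400-600, so they blend 10 and 30 in proportion to overlap:
# (150*10 + 100*30) / 250 = 18.
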