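"""High-level pipeline: source -> binning -> horizon -> SVG.

Glue used by the CLI, the examples and tests.  Any object with the source
query contract (``samples()`` and ``query(SourceQuery)``) can feed a
chart, so in-memory files and a remote bedserver are interchangeable and
produce byte-identical documents over the same data.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .binning import ValueSeries, bin_records
from .genomic_model import ChartContext
from .horizon import HorizonConfig, auto_extent
from .render import TrackSpec, compose_chart
from .sources import SourceQuery

logger = logging.getLogger("horizonbed")


def build_series(
    source,
    samples: Sequence[str],
    ctx: ChartContext,
    aggregator: str = "mean",
    gap_policy: str = "zero",
) -> list[ValueSeries]:
    """Query and bin one series per sample over the chart context."""
    series = []
    for sid in samples:
        records = source.query(SourceQuery(sid, ctx.region))
        s = bin_records(records, ctx, aggregator, gap_policy, label=sid)
        logger.info(
            "track %s: %d records -> %d columns", sid, len(records), ctx.width_px
        )
        series.append(s)
    return series


def chart_from_source(
    source,
    ctx: ChartContext,
    samples: Optional[Sequence[str]] = None,
    n_bands: int = 4,
    extent: Optional[float] = None,
    per_track_extent: bool = False,
    mode: str = "mirror",
    aggregator: str = "mean",
    gap_policy: str = "zero",
    positive_palette: Optional[tuple[str, ...]] = None,
    negative_palette: Optional[tuple[str, ...]] = None,
    axis: bool = True,
) -> str:
    """Render a multi-track horizon chart; returns the SVG text.

    ``extent=None`` selects the shared default: the global max |binned
    value| over all tracks, keeping tracks cross-comparable.
    ``per_track_extent=True`` scales each track to its own maximum
    instead.
    """
    ids = list(samples) if samples is not None else source.samples()
    series = build_series(source, ids, ctx, aggregator, gap_policy)
    if extent is None and not per_track_extent:
        extent = auto_extent(series)
        logger.info("auto extent: %g", extent)
    tracks = []
    for s in series:
        track_extent = (
            (s.max_abs() or 1.0) if per_track_extent else float(extent)
        )
        cfg = HorizonConfig(
            n_bands=n_bands,
            extent=track_extent,
            mode=mode,
            positive_palette=positive_palette,
            negative_palette=negative_palette,
            track_height_px=ctx.track_height_px,
        )
        tracks.append(TrackSpec(series=s, cfg=cfg, label=s.label))
    return compose_chart(tracks, ctx, axis=axis)
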