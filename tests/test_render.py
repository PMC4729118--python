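"""SVG rendering: determinism, layout arithmetic, decode faithfulness."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest

from horizonbed.binning import ValueSeries, bin_records
from horizonbed.genomic_model import ChartContext, GenomicRegion
from horizonbed.horizon import HorizonConfig
from horizonbed.render import (
    AXIS_HEIGHT_PX,
    CompositionError,
    GUTTER_PX,
    LABEL_WIDTH_PX,
    TrackSpec,
    chart_height,
    compose_chart,
    decode_track_values,
    render_track,
)

NS = "{http://www.w3.org/2000/svg}"


def make_ctx(width=64, height=20, length=6400):
    return ChartContext(
        GenomicRegion("chrA", 0, length), width_px=width, track_height_px=height
    )


def series_of(values, ctx, label="t"):
    return ValueSeries(ctx, list(values), label)


class TestRenderTrack:
    def test_constant_full_scale_is_single_darkest_rect(self):
        ctx = make_ctx()
        cfg = HorizonConfig(n_bands=4, extent=10.0, track_height_px=20)
        frag = render_track(TrackSpec(series_of([10.0] * 64, ctx), cfg))
        rects = ET.fromstring(frag).findall("rect")
        # merged into one full-width rect per band, all full height
        assert len(rects) == 4
        assert {r.get("fill") for r in rects} == set(cfg.positive_palette)
        assert all(int(r.get("height")) == 20 for r in rects)
        assert all(int(r.get("width")) == 64 for r in rects)

    def test_all_missing_series_draws_nothing(self):
        ctx = make_ctx()
        cfg = HorizonConfig(n_bands=4, extent=10.0, track_height_px=20)
        frag = render_track(TrackSpec(series_of([None] * 64, ctx), cfg))
        assert ET.fromstring(frag).findall("rect") == []

    def test_bands_anchored_at_baseline(self):
        ctx = make_ctx(width=1, length=100)
        cfg = HorizonConfig(n_bands=4, extent=100.0, track_height_px=20)
        frag = render_track(TrackSpec(series_of([37.5], ctx), cfg), y=0)
        rects = ET.fromstring(frag).findall("rect")
        by_color = {r.get("fill"): r for r in rects}
        full = by_color[cfg.positive_palette[0]]
        half = by_color[cfg.positive_palette[1]]
        assert (int(full.get("y")), int(full.get("height"))) == (0, 20)
        assert (int(half.get("y")), int(half.get("height"))) == (10, 10)

    def test_clipped_columns_get_a_tick(self):
        ctx = make_ctx(width=4, length=400)
        cfg = HorizonConfig(n_bands=2, extent=5.0, track_height_px=20)
        frag = render_track(TrackSpec(series_of([1.0, 9.0, 1.0, 1.0], ctx), cfg))
        ticks = [
            r
            for r in ET.fromstring(frag).findall("rect")
            if r.get("class") == "clip"
        ]
        assert len(ticks) == 1
        assert int(ticks[0].get("x")) == LABEL_WIDTH_PX + 1

    def test_offset_mode_hangs_negatives_from_top(self):
        ctx = make_ctx(width=1, length=100)
        cfg = HorizonConfig(n_bands=2, extent=10.0, mode="offset", track_height_px=20)
        frag = render_track(TrackSpec(series_of([-4.0], ctx), cfg), y=0)
        rects = ET.fromstring(frag).findall("rect")
        assert len(rects) == 1
        assert int(rects[0].get("y")) == 0  # anchored at top edge
        assert rects[0].get("fill") == cfg.negative_palette[0]


class TestComposeChart:
    def test_multi_track_layout_height(self):
        # 24 tracks of height 20, gutter 2, no axis -> 528
        ctx = make_ctx(width=10, height=20, length=1000)
        cfg = HorizonConfig(n_bands=4, extent=1.0, track_height_px=20)
        tracks = [
            TrackSpec(series_of([0.5] * 10, ctx, f"s{i}"), cfg) for i in range(24)
        ]
        svg = compose_chart(tracks, ctx, axis=False)
        root = ET.fromstring(svg)
        assert int(root.get("height")) == 24 * (20 + GUTTER_PX) == 528
        assert chart_height(24, 20) == 528

    def test_single_track_height(self):
        ctx = make_ctx(width=10, length=1000)
        cfg = HorizonConfig(extent=1.0, track_height_px=20)
        svg = compose_chart(
            [TrackSpec(series_of([0.1] * 10, ctx), cfg)], ctx, axis=False
        )
        assert int(ET.fromstring(svg).get("height")) == 20 + GUTTER_PX

    def test_axis_adds_fixed_height_and_labels(self):
        ctx = ChartContext(
            GenomicRegion("chr17", 1_100_000, 1_200_000), 100, track_height_px=20
        )
        cfg = HorizonConfig(extent=1.0, track_height_px=20)
        svg = compose_chart(
            [TrackSpec(series_of([0.1] * 100, ctx), cfg)], ctx, axis=True
        )
        root = ET.fromstring(svg)
        assert int(root.get("height")) == 20 + GUTTER_PX + AXIS_HEIGHT_PX
        texts = [t.text for t in root.iter(f"{NS}text")]
        assert any(t and t.startswith("chr17:") for t in texts)

    def test_determinism_byte_identical(self):
        ctx = make_ctx()
        cfg = HorizonConfig(n_bands=4, extent=10.0, track_height_px=20)
        vals = list(np.linspace(-12, 12, 64))
        tracks = [TrackSpec(series_of(vals, ctx, "s"), cfg)]
        assert compose_chart(tracks, ctx) == compose_chart(tracks, ctx)

    def test_zero_tracks_rejected(self):
        with pytest.raises(CompositionError):
            compose_chart([], make_ctx())

    def test_width_mismatch_rejected(self):
        ctx = make_ctx(width=64)
        other = make_ctx(width=32)
        cfg = HorizonConfig(extent=1.0, track_height_px=20)
        with pytest.raises(CompositionError):
            compose_chart(
                [TrackSpec(series_of([0.0] * 32, other), cfg)], ctx
            )

    def test_height_independent_of_value_range(self):
        # density property: height depends on track count, not data scale
        ctx = make_ctx(width=10, length=1000)
        for scale in (1.0, 1e3, 1e6):
            cfg = HorizonConfig(extent=scale, track_height_px=20)
            svg = compose_chart(
                [TrackSpec(series_of([scale / 3] * 10, ctx), cfg)], ctx, axis=False
            )
            assert int(ET.fromstring(svg).get("height")) == 22


class TestDecodeFaithfulness:
    @pytest.mark.parametrize("n_bands", [1, 3, 4])
    def test_decoded_heights_recover_clamped_values(self, n_bands, rng):
        """Measuring drawn rectangles inverts to the clamped binned value
        within one vertical-pixel quantum — the mechanical spot-check of a
        rendered chart against its input."""
        h = 20
        extent = 50.0
        ctx = make_ctx(width=64, height=h)
        cfg = HorizonConfig(n_bands=n_bands, extent=extent, track_height_px=h)
        values = list(np.round(rng.uniform(-70, 70, 64), 3))
        svg = compose_chart(
            [TrackSpec(series_of(values, ctx, "t"), cfg)], ctx, axis=False
        )
        decoded = decode_track_values(svg, 0, cfg, 64)
        quantum = cfg.band_unit / h  # one vertical pixel in value units
        for v, d in zip(values, decoded):
            clamped = max(-extent, min(extent, v))
            assert abs(d - clamped) <= quantum + 1e-9

    def test_decode_through_binning_pipeline(self, rng):
        from conftest import random_records

        region = GenomicRegion("chrA", 0, 6400)
        records = random_records(rng, region, 200)
        ctx = ChartContext(region, width_px=64, track_height_px=25)
        series = bin_records(records, ctx, "mean")
        extent = max(abs(v) for v in series.values if v is not None)
        cfg = HorizonConfig(n_bands=4, extent=extent, track_height_px=25)
        svg = compose_chart([TrackSpec(series, cfg)], ctx, axis=False)
        decoded = decode_track_values(svg, 0, cfg, 64)
        quantum = cfg.band_unit / 25
        for v, d in zip(series.values, decoded):
            assert abs(d - max(-extent, min(extent, v))) <= quantum + 1e-9
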