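"""Static SVG rendering of horizon tracks.

Output is plain SVG text built deterministically: no timestamps, no random
ids, all geometry in whole pixels — identical inputs give byte-identical
documents, which makes golden tests and source-equivalence checks exact.

Per pixel column the renderer draws one rectangle per non-empty band, all
anchored at the track baseline; band i's height is fills[i] x track
height (full bands span the whole track).  Bands are painted bottom-first
so darker (higher-index) bands overlay lighter ones — the darkest visible
top edge encodes the value.  Runs of adjacent columns with identical
quantized stacks are merged into single rectangles, a pure optimization
with a pixel-identical result.

:func:`decode_track_values` inverts the geometry: it measures the drawn
rectangle heights straight from the SVG and reconstructs the clamped
per-column values, so a rendered chart can be spot-checked against the
raw input mechanically.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional, Sequence

from .binning import ValueSeries
from .genomic_model import ChartContext
from .horizon import BandStack, HorizonConfig, band_color, decompose

LABEL_WIDTH_PX = 80
GUTTER_PX = 2
AXIS_HEIGHT_PX = 18
BACKGROUND = "#ffffff"
CLIP_TICK_COLOR = "#1a1a1a"


class CompositionError(ValueError):
    """Chart-level layout error (zero tracks, width mismatch)."""


@dataclass(frozen=True)
class TrackSpec:
    """One track of a chart: a binned series plus its display config."""

    series: ValueSeries
    cfg: HorizonConfig
    label: str = ""

    def display_label(self) -> str:
        return self.label or self.series.label


def _quantize_stack(stack: BandStack, height_px: int) -> tuple[int, tuple[int, ...]]:
    """Integer pixel height per band (round-half-up); key for run merging."""
    heights = tuple(
        int(f * height_px + 0.5) if f < 1.0 else height_px for f in stack.fills
    )
    return stack.sign, heights


def render_track(
    track: TrackSpec, x: int = LABEL_WIDTH_PX, y: int = 0
) -> str:
    """Render one track as an SVG ``<g>`` fragment at offset (x, y)."""
    series, cfg = track.series, track.cfg
    h = cfg.track_height_px
    stacks = [decompose(v, cfg) for v in series.values]
    keys = [
        None if st.missing else (_quantize_stack(st, h), st.clipped)
        for st in stacks
    ]
    parts: list[str] = [f'<g class="track">']
    c = 0
    width = len(keys)
    while c < width:
        key = keys[c]
        c1 = c + 1
        while c1 < width and keys[c1] == key:
            c1 += 1
        if key is not None:
            (sign, heights), clipped = key
            run_w = c1 - c
            for i, bh in enumerate(heights):
                if bh <= 0:
                    continue
                color = band_color(stacks[c], i, cfg)
                if color is None:
                    continue
                if cfg.mode == "offset" and sign < 0:
                    ry = y  # negatives hang from the top edge
                else:
                    ry = y + h - bh
                parts.append(
                    f'<rect x="{x + c}" y="{ry}" width="{run_w}" '
                    f'height="{bh}" fill="{color}"/>'
                )
            if clipped:
                parts.append(
                    f'<rect x="{x + c}" y="{y}" width="{c1 - c}" height="1" '
                    f'fill="{CLIP_TICK_COLOR}" class="clip"/>'
                )
        c = c1
    parts.append("</g>")
    return "".join(parts)


def _nice_tick_step(span: int, target_ticks: int = 5) -> int:
    """1/2/5 x 10^k step giving roughly target_ticks ticks."""
    raw = max(span // max(target_ticks, 1), 1)
    mag = 10 ** (len(str(raw)) - 1)
    for mult in (1, 2, 5, 10):
        if mult * mag >= raw:
            return mult * mag
    return 10 * mag


def _axis_fragment(ctx: ChartContext, x: int, y: int) -> str:
    region = ctx.region
    parts = [
        f'<g class="axis" font-family="monospace" font-size="10">',
        f'<line x1="{x}" y1="{y}" x2="{x + ctx.width_px}" y2="{y}" '
        f'stroke="#333333" stroke-width="1"/>',
    ]
    step = _nice_tick_step(region.length())
    first = ((region.start + step - 1) // step) * step
    pos = first
    while pos < region.end:
        col = (pos - region.start) * ctx.width_px // region.length()
        px = x + col
        # axis labels are 1-based display coordinates
        label = f"{region.chrom}:{pos + 1:,}"
        parts.append(
            f'<line x1="{px}" y1="{y}" x2="{px}" y2="{y + 4}" '
            f'stroke="#333333" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{px}" y="{y + 14}" text-anchor="middle" '
            f'fill="#333333">{label}</text>'
        )
        pos += step
    parts.append("</g>")
    return "".join(parts)


def chart_height(
    n_tracks: int, track_height_px: int, axis: bool = False,
    gutter_px: int = GUTTER_PX,
) -> int:
    return n_tracks * (track_height_px + gutter_px) + (
        AXIS_HEIGHT_PX if axis else 0
    )


def compose_chart(
    tracks: Sequence[TrackSpec], ctx: ChartContext, axis: bool = True
) -> str:
    """Compose tracks into a complete standalone SVG document.

    Tracks stack vertically with a fixed gutter; a left label column holds
    sample names; the optional axis draws chrom:pos ticks at round genomic
    positions along the bottom.
    """
    if not tracks:
        raise CompositionError("a chart needs at least one track")
    for t in tracks:
        if t.series.ctx.width_px != ctx.width_px:
            raise CompositionError(
                f"track {t.display_label()!r} width "
                f"{t.series.ctx.width_px} != chart width {ctx.width_px}"
            )
    heights = {t.cfg.track_height_px for t in tracks}
    h = max(heights)
    total_h = chart_height(len(tracks), h, axis)
    total_w = LABEL_WIDTH_PX + ctx.width_px
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{total_w}" '
        f'height="{total_h}" viewBox="0 0 {total_w} {total_h}">',
        f'<rect x="0" y="0" width="{total_w}" height="{total_h}" '
        f'fill="{BACKGROUND}"/>',
    ]
    y = 0
    for t in tracks:
        label = _escape(t.display_label())
        if label:
            parts.append(
                f'<text x="{LABEL_WIDTH_PX - 6}" '
                f'y="{y + t.cfg.track_height_px - 5}" text-anchor="end" '
                f'font-family="monospace" font-size="10" '
                f'fill="#333333">{label}</text>'
            )
        parts.append(render_track(t, x=LABEL_WIDTH_PX, y=y))
        y += h + GUTTER_PX
    if axis:
        parts.append(_axis_fragment(ctx, LABEL_WIDTH_PX, y + 2))
    parts.append("</svg>")
    return "".join(parts)


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def decode_track_values(
    svg_text: str,
    track_index: int,
    cfg: HorizonConfig,
    width_px: int,
) -> list[Optional[float]]:
    """Measure a rendered track and reconstruct its per-column values.

    Reads only rectangle geometry and fill colors (no metadata): for each
    column, band heights are divided by the track height to recover fills,
    the palette identifies the sign, and the stack is summed back to a
    value.  Columns with no band rectangles decode to 0.0 when the track
    drew nothing there (missing and zero are indistinguishable from
    geometry alone, a documented limitation).  Accuracy is limited by the
    1-px height quantization.
    """
    root = ET.fromstring(svg_text)
    ns = "{http://www.w3.org/2000/svg}"
    groups = [g for g in root.iter(f"{ns}g") if g.get("class") == "track"]
    if track_index >= len(groups):
        raise IndexError(
            f"track {track_index} not in document ({len(groups)} tracks)"
        )
    pos_idx = {c: i for i, c in enumerate(cfg.positive_palette)}
    neg_idx = {c: i for i, c in enumerate(cfg.negative_palette)}
    h = cfg.track_height_px
    band_h: list[dict[int, int]] = [dict() for _ in range(width_px)]
    sign_of: list[int] = [0] * width_px
    for rect in groups[track_index].iter(f"{ns}rect"):
        if rect.get("class") == "clip":
            continue
        color = rect.get("fill")
        if color in pos_idx:
            sign, band = 1, pos_idx[color]
        elif color in neg_idx:
            sign, band = -1, neg_idx[color]
        else:
            continue
        x0 = int(rect.get("x")) - LABEL_WIDTH_PX
        w = int(rect.get("width"))
        bh = int(rect.get("height"))
        for c in range(x0, x0 + w):
            if 0 <= c < width_px:
                band_h[c][band] = bh
                sign_of[c] = sign
    out: list[Optional[float]] = []
    for c in range(width_px):
        fills = sum(band_h[c].get(i, 0) / h for i in range(cfg.n_bands))
        out.append(sign_of[c] * cfg.band_unit * fills)
    return out


def rasterize_png(svg_text: str, out_path: str) -> None:
    """Best-effort PNG rasterization of a chart (rectangles only).

    Charts are pure axis-aligned rectangles plus text; this draws the
    rectangles with Pillow and skips text.  Requires Pillow.
    """
    from PIL import Image, ImageDraw  # lazy: optional feature

    root = ET.fromstring(svg_text)
    ns = "{http://www.w3.org/2000/svg}"
    w = int(root.get("width"))
    h = int(root.get("height"))
    img = Image.new("RGB", (w, h), BACKGROUND)
    draw = ImageDraw.Draw(img)
    for rect in root.iter(f"{ns}rect"):
        x0 = int(rect.get("x"))
        y0 = int(rect.get("y"))
        rw = int(rect.get("width"))
        rh = int(rect.get("height"))
        draw.rectangle([x0, y0, x0 + rw - 1, y0 + rh - 1], fill=rect.get("fill"))
    img.save(out_path, format="PNG")
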