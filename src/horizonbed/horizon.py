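"""Horizon band decomposition — the heart of the method.

A horizon chart derives from a filled line chart in three moves: slice the
value range into ``n_bands`` bands of height ``extent / n_bands`` each and
darken the color with the band index; *mirror* negative values above the
baseline in a contrasting hue (halving the needed vertical space); and
*collapse* all bands onto the baseline (a further ``n_bands``-fold
reduction).  The decomposition is invertible: a band stack reconstructs
exactly the clamped input value, which is what makes spot-checking a
rendered chart against the raw input mechanical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

# Light -> dark ramps.  Positive defaults are greens (read depth and other
# non-negative signals show only green hues); negatives are blues.
GREENS_4 = ("#c7e9c0", "#74c476", "#31a354", "#006d2c")
BLUES_4 = ("#c6dbef", "#6baed6", "#2171b5", "#08306b")

PALETTES = {
    "greens": GREENS_4,
    "blues": BLUES_4,
    "oranges": ("#fdd0a2", "#fd8d3c", "#d94801", "#7f2704"),
    "purples": ("#dadaeb", "#9e9ac8", "#6a51a3", "#3f007d"),
}


def _hex_to_rgb(c: str) -> tuple[int, int, int]:
    return int(c[1:3], 16), int(c[3:5], 16), int(c[5:7], 16)


def _rgb_to_hex(rgb: tuple[float, float, float]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*(round(x) for x in rgb))


def _resample_palette(base: Sequence[str], n: int) -> tuple[str, ...]:
    """n colors spread light -> dark along the ramp.

    Piecewise-linear RGB interpolation through the anchor colors, so
    every band gets a distinct shade for any reasonable band count.
    """
    if n == 1:
        return (base[-1],)
    anchors = [_hex_to_rgb(c) for c in base]
    out = []
    for i in range(n):
        t = i * (len(anchors) - 1) / (n - 1)
        k = min(int(t), len(anchors) - 2)
        f = t - k
        a, b = anchors[k], anchors[k + 1]
        out.append(_rgb_to_hex(tuple(a[j] + f * (b[j] - a[j]) for j in range(3))))
    return tuple(out)


@dataclass(frozen=True)
class HorizonConfig:
    """Display parameters for one horizon track.

    ``extent`` is the clamp value V: inputs map within [-V, +V] and larger
    magnitudes saturate the top band (flagged as clipped).  ``mode`` is
    ``mirror`` (negatives flipped over the baseline, the default) or
    ``offset`` (negatives hang from the top edge).
    """

    n_bands: int = 4
    extent: float = 1.0
    mode: str = "mirror"
    positive_palette: Optional[tuple[str, ...]] = None
    negative_palette: Optional[tuple[str, ...]] = None
    track_height_px: int = 20

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not (self.extent > 0) or not math.isfinite(self.extent):
            raise ValueError("extent must be a positive finite number")
        if self.mode not in ("mirror", "offset"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.track_height_px < 2:
            raise ValueError("track_height_px must be >= 2")
        if self.positive_palette is None:
            object.__setattr__(
                self, "positive_palette", _resample_palette(GREENS_4, self.n_bands)
            )
        if self.negative_palette is None:
            object.__setattr__(
                self, "negative_palette", _resample_palette(BLUES_4, self.n_bands)
            )
        for name in ("positive_palette", "negative_palette"):
            pal = getattr(self, name)
            if len(pal) != self.n_bands:
                raise ValueError(
                    f"{name} has {len(pal)} entries, expected {self.n_bands}"
                )

    @property
    def band_unit(self) -> float:
        """Value-range height of one band."""
        return self.extent / self.n_bands


@dataclass(frozen=True)
class BandStack:
    """Per-column decomposition result: signed per-band fill fractions.

    Structure: all bands below the value are full (fill 1), at most one
    band is partially filled, all bands above are empty.  ``sign`` is the
    sign of the input value (0 for zero or missing); ``clipped`` marks
    inputs beyond the extent; ``missing`` distinguishes absent data from a
    true zero.
    """

    sign: int
    fills: tuple[float, ...]
    clipped: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be -1, 0 or 1, got {self.sign}")
        partial_seen = False
        for i, f in enumerate(self.fills):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fill {f} outside [0, 1] at band {i}")
            if partial_seen and f > 0:
                raise ValueError(
                    "invalid stack: a non-empty band above a partial one"
                )
            if f < 1.0:
                partial_seen = True
        if self.sign == 0 and any(f != 0 for f in self.fills):
            raise ValueError("sign 0 requires all fills 0")


def decompose(value: Optional[float], cfg: HorizonConfig) -> BandStack:
    """Map one value to its band stack.

    With band unit u = extent / n_bands, the scaled magnitude
    s = min(|value|, extent) / u fills band i by clamp(s - i, 0, 1).
    Missing input yields an all-empty stack flagged missing.
    """
    n = cfg.n_bands
    if value is None:
        return BandStack(0, (0.0,) * n, missing=True)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r}")
    mag = abs(value)
    s = min(mag, cfg.extent) / cfg.band_unit
    fills = tuple(min(max(s - i, 0.0), 1.0) for i in range(n))
    sign = 0 if value == 0 else (1 if value > 0 else -1)
    if all(f == 0.0 for f in fills):
        sign = 0 if value == 0 else sign  # zero-width fills keep the sign
    return BandStack(sign, fills, clipped=mag > cfg.extent)


def reconstruct(stack: BandStack, cfg: HorizonConfig) -> Optional[float]:
    """Invert :func:`decompose`: sign x band_unit x sum(fills).

    For any finite v, ``reconstruct(decompose(v)) == clamp(v, -extent,
    +extent)`` up to float round-off; a missing stack returns ``None``.
    """
    if len(stack.fills) != cfg.n_bands:
        raise ValueError(
            f"stack has {len(stack.fills)} bands, config expects {cfg.n_bands}"
        )
    if stack.missing:
        return None
    return stack.sign * cfg.band_unit * sum(stack.fills)


def band_color(
    stack: BandStack, band_index: int, cfg: HorizonConfig
) -> Optional[str]:
    """Color of one band of a stack, or ``None`` if that band is empty.

    Positive stacks draw from the positive palette, negative stacks from
    the negative one — sign is encoded purely by hue.
    """
    if not (0 <= band_index < cfg.n_bands):
        raise IndexError(f"band index {band_index} out of range")
    if stack.fills[band_index] <= 0:
        return None
    if stack.sign > 0:
        return cfg.positive_palette[band_index]
    if stack.sign < 0:
        return cfg.negative_palette[band_index]
    return None


def vertical_span(mode: str, n_bands: int, band_height_px: int) -> int:
    """Plot-area height (px) needed at equal per-pixel value resolution.

    ``pre_mirror`` (positive bands above the baseline, negative below)
    needs 2 x n_bands x band_height; ``mirror`` folds negatives up,
    needing n_bands x band_height — exactly half.  Collapsing then reduces
    the one-sided span a further n_bands-fold (``collapsed`` mode).
    """
    if band_height_px < 1:
        raise ValueError("band_height_px must be >= 1")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if mode == "pre_mirror":
        return 2 * n_bands * band_height_px
    if mode == "mirror":
        return n_bands * band_height_px
    if mode == "collapsed":
        return band_height_px
    raise ValueError(f"unknown mode {mode!r}")


def auto_extent(series_list: Sequence["object"]) -> float:
    """Global max |value| over a set of series — the default shared extent.

    A shared extent keeps tracks cross-comparable, which is what the
    multi-sample QC use case needs.  Returns 1.0 when every value is 0 or
    missing so the config stays valid.
    """
    m = 0.0
    for s in series_list:
        m = max(m, s.max_abs())
    return m if m > 0 else 1.0
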