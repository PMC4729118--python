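"""Genomic coordinates and the chart *context*.

A chart context couples a genomic region with a horizontal pixel budget,
fixing the mapping between base positions and pixel columns.  All
coordinates are 0-based, half-open, matching the BED convention; 1-based
numbers appear only in rendered axis labels.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction


class RegionParseError(ValueError):
    """Raised when a region string cannot be interpreted."""


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name, non-empty.  No normalization is attempted
        (``chr17`` and ``17`` are distinct names).
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        Exclusive end, ``> start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_SUFFIX = {"k": 1_000, "K": 1_000, "m": 1_000_000, "M": 1_000_000, "g": 1_000_000_000, "G": 1_000_000_000}

_COORD_RE = re.compile(r"^(\d+(?:\.\d+)?)([kKmMgG]?)$")


def _parse_coord(text: str) -> int:
    """Parse one coordinate: optional comma/underscore separators, k/M/G suffix."""
    cleaned = text.replace(",", "").replace("_", "")
    m = _COORD_RE.match(cleaned)
    if m is None:
        raise RegionParseError(f"cannot parse coordinate {text!r}")
    number, suffix = m.groups()
    scale = _SUFFIX.get(suffix, 1)
    value = Decimal(number) * scale  # exact decimal arithmetic
    if value != value.to_integral_value():
        raise RegionParseError(
            f"coordinate {text!r} does not resolve to a whole base position"
        )
    return int(value)


def parse_region(text: str) -> GenomicRegion:
    """Parse a ``chrom:start-end`` region string to a 0-based half-open region.

    Accepts comma or underscore digit separators and ``k``/``M``/``G``
    multiplier suffixes, so ``chr17:1.1M-1.2M``, ``chr17:1,100,000-1,200,000``
    and ``chr17:1100000-1200000`` all denote the same region.
    """
    head, sep, tail = text.rpartition(":")
    if not sep or not head:
        raise RegionParseError(f"region {text!r} is not of the form chrom:start-end")
    lo, sep2, hi = tail.partition("-")
    if not sep2:
        raise RegionParseError(f"region {text!r} lacks a start-end span")
    start = _parse_coord(lo)
    end = _parse_coord(hi)
    try:
        return GenomicRegion(head, start, end)
    except ValueError as exc:
        raise RegionParseError(str(exc)) from exc


@dataclass(frozen=True)
class ChartContext:
    """Region plus pixel geometry: the scope of one chart.

    ``width_px`` is primary; the per-column step in bases is derived as
    ``region.length / width_px`` and kept exact as a fraction.  When the
    requested width exceeds the region length, the width is clamped to one
    column per base (with a warning) so no column covers zero bases.
    """

    region: GenomicRegion
    width_px: int
    track_height_px: int = 20
    step_bp: Fraction = field(init=False)

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        if self.track_height_px < 2:
            raise ValueError("track_height_px must be >= 2")
        if self.width_px > self.region.length():
            warnings.warn(
                f"width_px {self.width_px} exceeds region length "
                f"{self.region.length()}; clamping to one column per base",
                UserWarning,
                stacklevel=2,
            )
            object.__setattr__(self, "width_px", self.region.length())
        object.__setattr__(
            self, "step_bp", Fraction(self.region.length(), self.width_px)
        )

    def _boundary(self, col: int) -> int:
        # round-half-up on col * step; exact in rational arithmetic
        x = col * self.step_bp
        return self.region.start + int(x + Fraction(1, 2))

    def pixel_to_interval(self, col: int) -> GenomicRegion:
        """Genomic sub-interval covered by pixel column ``col``.

        Column intervals tile the region exactly: no gaps, no overlaps,
        and each column covers at least one base.
        """
        if not (0 <= col < self.width_px):
            raise IndexError(
                f"column {col} out of range for width {self.width_px}"
            )
        return GenomicRegion(
            self.region.chrom, self._boundary(col), self._boundary(col + 1)
        )

    def interval_to_pixels(self, iv: GenomicRegion) -> range:
        """Half-open range of pixel columns whose intervals overlap ``iv``.

        Returns an empty range when ``iv`` does not overlap the context
        region; a chromosome mismatch is an error.
        """
        if iv.chrom != self.region.chrom:
            raise ValueError(
                f"chromosome mismatch: {iv.chrom} vs context {self.region.chrom}"
            )
        if not iv.overlaps(self.region):
            return range(0)
        # first column whose end > iv.start: boundary(c+1) > iv.start
        # columns are monotone; binary search on the exact boundaries
        lo, hi = 0, self.width_px - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if self._boundary(mid + 1) > iv.start:
                hi = mid
            else:
                lo = mid + 1
        first = lo
        # last column whose start < iv.end
        lo, hi = first, self.width_px - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self._boundary(mid) < iv.end:
                lo = mid
            else:
                hi = mid - 1
        return range(first, lo + 1)
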