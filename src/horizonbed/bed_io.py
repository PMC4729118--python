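"""Reading and writing BED / BedGraph interval files.

Two dialects carry the signal value:

* 4-column BedGraph — ``chrom start end value`` (value in column 4);
* 5+-column BED — value taken from the score field (column 5).

Auto-detection picks per line by column count.  Files may be plain text or
gzip-compressed (detected by the magic bytes or a ``.gz`` suffix).
Coordinates are 0-based half-open.  Records need not be sorted or
non-overlapping; that is the binning layer's concern.  Negative values are
legal (horizon charts render sign with hue).
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

_COMMENT_PREFIXES = ("#", "track", "browser")


class BedParseError(ValueError):
    """A malformed data line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class BedRecord:
    """One genomic interval with a numeric signal value (e.g. read depth)."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value {self.value!r}")


@dataclass
class ParseResult:
    """Records in file order plus bookkeeping counts."""

    records: list[BedRecord]
    skipped: int  # comment / blank / header lines

    def __iter__(self) -> Iterator[BedRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _is_comment(line: str) -> bool:
    return any(line.startswith(p) for p in _COMMENT_PREFIXES)


def parse_bed_lines(lines: Iterable[str], dialect: str = "auto") -> ParseResult:
    """Parse an iterable of text lines into BED records.

    Every input line is accounted for: it becomes a record, a counted
    skip (blank/comment/header), or raises :class:`BedParseError` naming
    its line number — nothing is dropped silently.
    """
    if dialect not in ("auto", "bedgraph", "bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[BedRecord] = []
    skipped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or _is_comment(line):
            skipped += 1
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise BedParseError(
                f"expected >= 4 columns, got {len(fields)}", lineno
            )
        if dialect == "bedgraph" or (dialect == "auto" and len(fields) == 4):
            value_col = 3
        else:  # bed6-style: score column
            if len(fields) < 5:
                raise BedParseError(
                    "bed6 dialect requires a score column (>= 5 columns)", lineno
                )
            value_col = 4
        chrom = fields[0]
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError:
            raise BedParseError(
                f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", lineno
            ) from None
        try:
            value = float(fields[value_col])
        except ValueError:
            raise BedParseError(
                f"non-numeric value {fields[value_col]!r}", lineno
            ) from None
        if not math.isfinite(value):
            raise BedParseError(f"non-finite value {fields[value_col]!r}", lineno)
        if start < 0:
            raise BedParseError(f"negative start {start}", lineno)
        if start >= end:
            raise BedParseError(f"start {start} >= end {end}", lineno)
        records.append(BedRecord(chrom, start, end, value))
    return ParseResult(records, skipped)


def _open_text(path: Union[str, PathLike]) -> IO[str]:
    p = Path(path)
    with open(p, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b" or p.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(p, "rb"), encoding="utf-8")
    return open(p, "r", encoding="utf-8")


def parse_bed(
    source: Union[str, PathLike, IO[str]], dialect: str = "auto"
) -> ParseResult:
    """Parse a BED/BedGraph file (path or open text stream)."""
    if hasattr(source, "read"):
        return parse_bed_lines(source, dialect)  # type: ignore[arg-type]
    with _open_text(source) as fh:
        return parse_bed_lines(fh, dialect)


def format_value(v: float) -> str:
    """Render a value compactly but losslessly (round-trips via float())."""
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def write_bed(records: Iterable[BedRecord], stream: IO[str]) -> int:
    """Write records as 4-column BedGraph lines; returns the count written.

    ``parse_bed`` applied to the output reproduces the input exactly.
    """
    n = 0
    for rec in records:
        stream.write(
            f"{rec.chrom}\t{rec.start}\t{rec.end}\t{format_value(rec.value)}\n"
        )
        n += 1
    return n


def write_bed_file(records: Iterable[BedRecord], path: Union[str, PathLike]) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        return write_bed(records, fh)
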