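"""Data backends answering region queries.

Two interchangeable source kinds feed the chart layer:

* :class:`BedFileSource` / :class:`DirectorySource` — load whole BED files
  into memory and answer overlap queries from sorted per-chromosome
  arrays; simple and fine for desk-scale data.
* the indexed path (:func:`build_index` + :func:`indexed_query`) — a
  sidecar *linear binning index* over a start-sorted BED file: the genome
  is cut into fixed-size bins (16 kb default) and each bin stores the
  smallest file offset of any record overlapping it, so a region query
  seeks once and scans forward until records start past the region.  This
  is the tabix idea reduced to a single level, and it is what the HTTP
  service (see :mod:`horizonbed.service`) uses to stay scalable.

Index sidecar layout (little-endian), version 1, extension ``.hzidx``:

====================  ======================================
magic                 8 bytes ``HZBIDX01``
bin_size              uint32
file_size             uint64  (of the indexed BED file)
crc32                 uint32  (of the indexed BED file bytes)
n_chroms              uint32
per chromosome        name_len uint16, name (utf-8),
                      n_entries uint32, then n_entries x
                      (bin_number uint32, offset uint64)
====================  ======================================

Entries are sparse (only bins some record overlaps) and offsets are
non-decreasing in bin number because the file is start-sorted.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .bed_io import BedParseError, BedRecord, parse_bed, _is_comment
from .genomic_model import GenomicRegion

MAGIC = b"HZBIDX01"
DEFAULT_BIN_SIZE = 16_384
INDEX_SUFFIX = ".hzidx"

PathArg = Union[str, PathLike]


class UnsortedInputError(ValueError):
    """Input BED is not sorted by (chrom, start); reports the first bad line."""


class StaleIndexError(RuntimeError):
    """The BED file changed since its index was built."""


@dataclass(frozen=True)
class SourceQuery:
    """One region request against a named sample track."""

    sample: str
    region: GenomicRegion

    def __post_init__(self) -> None:
        if not self.sample:
            raise ValueError("sample identifier must be non-empty")


class BedFileSource:
    """In-memory source over one BED file (one sample).

    All records are loaded up front, grouped by chromosome and sorted by
    start; queries return exactly the records overlapping the region, in
    coordinate order.
    """

    def __init__(self, path: PathArg, sample: Optional[str] = None):
        self.path = Path(path)
        self.sample = sample if sample is not None else _sample_name(self.path)
        result = parse_bed(self.path)
        self.n_records = len(result)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[BedRecord]]] = {}
        grouped: dict[str, list[BedRecord]] = {}
        for rec in result:
            grouped.setdefault(rec.chrom, []).append(rec)
        for chrom, recs in grouped.items():
            recs.sort(key=lambda r: (r.start, r.end))
            starts = np.array([r.start for r in recs], dtype=np.int64)
            ends = np.array([r.end for r in recs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, recs)

    def samples(self) -> list[str]:
        return [self.sample]

    def query_region(self, region: GenomicRegion) -> list[BedRecord]:
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return []
        starts, ends, recs = entry
        mask = (starts < region.end) & (ends > region.start)
        return [recs[i] for i in np.flatnonzero(mask)]

    def query(self, q: SourceQuery) -> list[BedRecord]:
        if q.sample != self.sample:
            raise KeyError(f"unknown sample {q.sample!r}")
        return self.query_region(q.region)


def _sample_name(path: Path) -> str:
    name = path.name
    for suffix in (".gz", ".bed", ".bedgraph", ".bedGraph"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


class DirectorySource:
    """Multi-sample source: one BED file per sample in a directory."""

    def __init__(self, data_dir: PathArg):
        self.data_dir = Path(data_dir)
        paths = sorted(
            p
            for p in self.data_dir.iterdir()
            if p.is_file() and (
                p.suffix in (".bed", ".bedgraph", ".bedGraph")
                or p.name.endswith((".bed.gz", ".bedgraph.gz"))
            )
        )
        self._sources = {_sample_name(p): p for p in paths}
        self._loaded: dict[str, BedFileSource] = {}

    def samples(self) -> list[str]:
        return sorted(self._sources)

    def query(self, q: SourceQuery) -> list[BedRecord]:
        if q.sample not in self._sources:
            raise KeyError(f"unknown sample {q.sample!r}")
        if q.sample not in self._loaded:
            self._loaded[q.sample] = BedFileSource(
                self._sources[q.sample], sample=q.sample
            )
        return self._loaded[q.sample].query(q)


@dataclass
class LinearIndex:
    """Sparse bin -> smallest-overlapping-record-offset mapping."""

    bin_size_bp: int
    file_size: int
    crc32: int
    chroms: dict[str, dict[int, int]] = field(default_factory=dict)

    def first_offset(self, chrom: str, first_bin: int, last_bin: int) -> Optional[int]:
        """Smallest stored offset among bins [first_bin, last_bin] of chrom."""
        table = self.chroms.get(chrom)
        if not table:
            return None
        present = [table[b] for b in range(first_bin, last_bin + 1) if b in table]
        return min(present) if present else None


def _file_fingerprint(path: PathArg) -> tuple[int, int]:
    data = Path(path).read_bytes()
    return len(data), zlib.crc32(data)


def index_path_for(bed_path: PathArg) -> Path:
    return Path(str(bed_path) + INDEX_SUFFIX)


def build_index(
    bed_path: PathArg,
    bin_size_bp: int = DEFAULT_BIN_SIZE,
    out_path: Optional[PathArg] = None,
) -> LinearIndex:
    """Build and persist the sidecar index for a start-sorted BED file.

    The file must be sorted by (chrom, start) with each chromosome in one
    contiguous block; otherwise :class:`UnsortedInputError` names the
    first offending line and suggests sorting.  Building is deterministic
    given the input bytes.
    """
    if bin_size_bp < 1:
        raise ValueError("bin_size_bp must be >= 1")
    bed_path = Path(bed_path)
    data = bed_path.read_bytes()
    index = LinearIndex(
        bin_size_bp=bin_size_bp, file_size=len(data), crc32=zlib.crc32(data)
    )
    offset = 0
    seen_chroms: list[str] = []
    prev_start: Optional[int] = None
    lineno = 0
    for raw in data.splitlines(keepends=True):
        lineno += 1
        line_offset = offset
        offset += len(raw)
        text = raw.decode("utf-8").rstrip("\r\n")
        if not text.strip() or _is_comment(text):
            continue
        fields = text.split("\t") if "\t" in text else text.split()
        if len(fields) < 3:
            raise BedParseError(f"expected >= 3 columns, got {len(fields)}", lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedParseError("non-integer coordinates", lineno) from None
        if start >= end:
            raise BedParseError(f"start {start} >= end {end}", lineno)
        if not seen_chroms or chrom != seen_chroms[-1]:
            if chrom in seen_chroms:
                raise UnsortedInputError(
                    f"line {lineno}: chromosome {chrom} appears in multiple "
                    "blocks; sort the file by (chrom, start) first"
                )
            seen_chroms.append(chrom)
            prev_start = None
        if prev_start is not None and start < prev_start:
            raise UnsortedInputError(
                f"line {lineno}: start {start} < previous start {prev_start} "
                f"on {chrom}; sort the file by (chrom, start) first"
            )
        prev_start = start
        table = index.chroms.setdefault(chrom, {})
        for b in range(start // bin_size_bp, (end - 1) // bin_size_bp + 1):
            if b not in table:  # starts sorted => first seen offset is smallest
                table[b] = line_offset
    write_index(index, out_path or index_path_for(bed_path))
    return index


def write_index(index: LinearIndex, path: PathArg) -> None:
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<IQI", index.bin_size_bp, index.file_size, index.crc32))
        fh.write(struct.pack("<I", len(index.chroms)))
        for chrom in index.chroms:  # insertion (= file) order
            name = chrom.encode("utf-8")
            table = index.chroms[chrom]
            fh.write(struct.pack("<H", len(name)))
            fh.write(name)
            fh.write(struct.pack("<I", len(table)))
            for b in sorted(table):
                fh.write(struct.pack("<IQ", b, table[b]))


def read_index(path: PathArg) -> LinearIndex:
    data = Path(path).read_bytes()
    if data[:8] != MAGIC:
        raise ValueError(f"{path}: not a horizonbed index (bad magic)")
    off = 8
    bin_size, file_size, crc = struct.unpack_from("<IQI", data, off)
    off += 16
    (n_chroms,) = struct.unpack_from("<I", data, off)
    off += 4
    index = LinearIndex(bin_size_bp=bin_size, file_size=file_size, crc32=crc)
    for _ in range(n_chroms):
        (name_len,) = struct.unpack_from("<H", data, off)
        off += 2
        name = data[off : off + name_len].decode("utf-8")
        off += name_len
        (n_entries,) = struct.unpack_from("<I", data, off)
        off += 4
        table: dict[int, int] = {}
        for _ in range(n_entries):
            b, rec_off = struct.unpack_from("<IQ", data, off)
            off += 12
            table[b] = rec_off
        index.chroms[name] = table
    return index


def indexed_query(
    bed_path: PathArg,
    index: LinearIndex,
    q: SourceQuery,
    stats: Optional[dict] = None,
) -> list[BedRecord]:
    """Region query via the sidecar index: one seek, bounded forward scan.

    Seeks to the smallest indexed offset among the bins the region spans,
    then scans forward emitting overlapping records until a record starts
    at or past the region end (valid because the file is start-sorted).
    Raises :class:`StaleIndexError` if the file changed since indexing.
    ``stats``, when given, receives ``records_scanned``.
    """
    bed_path = Path(bed_path)
    size, crc = _file_fingerprint(bed_path)
    if (size, crc) != (index.file_size, index.crc32):
        raise StaleIndexError(
            f"{bed_path} changed since the index was built; rebuild it"
        )
    region = q.region
    first_bin = region.start // index.bin_size_bp
    last_bin = (region.end - 1) // index.bin_size_bp
    start_offset = index.first_offset(region.chrom, first_bin, last_bin)
    scanned = 0
    out: list[BedRecord] = []
    if start_offset is not None:
        with open(bed_path, "rb") as fh:
            fh.seek(start_offset)
            for raw in fh:
                text = raw.decode("utf-8").rstrip("\r\n")
                if not text.strip() or _is_comment(text):
                    continue
                fields = text.split("\t") if "\t" in text else text.split()
                chrom = fields[0]
                if chrom != region.chrom:
                    break  # chromosome block ended
                start, end = int(fields[1]), int(fields[2])
                scanned += 1
                if start >= region.end:
                    break
                if end > region.start:
                    value_col = 3 if len(fields) == 4 else 4
                    out.append(BedRecord(chrom, start, end, float(fields[value_col])))
    if stats is not None:
        stats["records_scanned"] = scanned
    return out


class IndexedFileSource:
    """Source facade over one BED file + sidecar index (builds if absent)."""

    def __init__(self, path: PathArg, sample: Optional[str] = None,
                 bin_size_bp: int = DEFAULT_BIN_SIZE):
        self.path = Path(path)
        self.sample = sample if sample is not None else _sample_name(self.path)
        idx_path = index_path_for(self.path)
        if idx_path.exists():
            self.index = read_index(idx_path)
            size, crc = _file_fingerprint(self.path)
            if (size, crc) != (self.index.file_size, self.index.crc32):
                self.index = build_index(self.path, bin_size_bp)
        else:
            self.index = build_index(self.path, bin_size_bp)

    def samples(self) -> list[str]:
        return [self.sample]

    def query(self, q: SourceQuery) -> list[BedRecord]:
        if q.sample != self.sample:
            raise KeyError(f"unknown sample {q.sample!r}")
        return indexed_query(self.path, self.index, q)
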