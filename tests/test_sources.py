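"""In-memory source, linear index build/query, oracle equivalence."""

import pytest

from conftest import random_records, sorted_bed_lines
from horizonbed.bed_io import BedParseError, BedRecord, write_bed_file
from horizonbed.genomic_model import GenomicRegion
from horizonbed.sources import (
    BedFileSource,
    DirectorySource,
    LinearIndex,
    SourceQuery,
    StaleIndexError,
    UnsortedInputError,
    build_index,
    index_path_for,
    indexed_query,
    read_index,
)


def linear_scan(records, region):
    """Brute-force overlap filter: the oracle all backends must match."""
    return [
        r
        for r in records
        if r.chrom == region.chrom and r.start < region.end and r.end > region.start
    ]


@pytest.fixture
def sorted_bed(tmp_path, rng):
    region = GenomicRegion("chrA", 0, 200_000)
    records = sorted(
        random_records(rng, region, 2_000, max_len=500),
        key=lambda r: (r.chrom, r.start, r.end),
    )
    path = tmp_path / "s1.bed"
    path.write_text("".join(sorted_bed_lines(records)))
    return path, records, region


class TestBedFileSource:
    def test_empty_region_query(self, tmp_path):
        p = tmp_path / "x.bed"
        write_bed_file([BedRecord("chrA", 100, 200, 1.0)], p)
        src = BedFileSource(p)
        assert src.query_region(GenomicRegion("chrA", 300, 400)) == []
        assert src.query_region(GenomicRegion("chrB", 100, 200)) == []

    def test_full_span_returns_all(self, tmp_path):
        records = [
            BedRecord("chrA", 0, 10, 1.0),
            BedRecord("chrA", 5, 20, 2.0),
            BedRecord("chrA", 30, 40, 3.0),
        ]
        p = tmp_path / "x.bed"
        write_bed_file(records, p)
        assert BedFileSource(p).query_region(GenomicRegion("chrA", 0, 40)) == records

    def test_sample_name_from_filename(self, tmp_path):
        p = tmp_path / "NA12878.bed"
        write_bed_file([BedRecord("chrA", 0, 1, 1.0)], p)
        src = BedFileSource(p)
        assert src.samples() == ["NA12878"]
        with pytest.raises(KeyError):
            src.query(SourceQuery("other", GenomicRegion("chrA", 0, 1)))

    def test_matches_linear_scan_on_random_queries(self, sorted_bed, rng):
        path, records, region = sorted_bed
        src = BedFileSource(path)
        for _ in range(100):
            s = int(rng.integers(0, region.end - 1))
            e = int(rng.integers(s + 1, region.end + 1000))
            q = GenomicRegion("chrA", s, e)
            assert src.query_region(q) == linear_scan(records, q)


class TestBuildIndex:
    def test_empty_bed_gives_valid_empty_index(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        idx = build_index(p)
        assert idx.chroms == {}
        assert read_index(index_path_for(p)).chroms == {}

    def test_single_record_maps_bin_zero_to_offset_zero(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chrA\t0\t100\t5\n")
        idx = build_index(p, bin_size_bp=16384)
        assert idx.chroms["chrA"] == {0: 0}

    def test_record_spanning_bins_marks_all(self, tmp_path):
        p = tmp_path / "span.bed"
        p.write_text("chrA\t100\t40000\t5\n")
        idx = build_index(p, bin_size_bp=16384)
        assert set(idx.chroms["chrA"]) == {0, 1, 2}

    def test_unsorted_starts_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chrA\t100\t200\t1\nchrA\t50\t80\t1\n")
        with pytest.raises(UnsortedInputError, match="line 2"):
            build_index(p)

    def test_split_chromosome_block_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chrA\t0\t10\t1\nchrB\t0\t10\t1\nchrA\t20\t30\t1\n")
        with pytest.raises(UnsortedInputError, match="chrA"):
            build_index(p)

    def test_deterministic_given_input_bytes(self, tmp_path, sorted_bed):
        path, _, _ = sorted_bed
        build_index(path)
        first = index_path_for(path).read_bytes()
        build_index(path)
        assert index_path_for(path).read_bytes() == first

    def test_roundtrips_through_sidecar_file(self, sorted_bed):
        path, _, _ = sorted_bed
        idx = build_index(path, bin_size_bp=4096)
        loaded = read_index(index_path_for(path))
        assert loaded == idx

    def test_invariant_offset_not_after_record(self, sorted_bed):
        """Every bin a record overlaps stores an offset <= the record's."""
        path, _, _ = sorted_bed
        idx = build_index(path, bin_size_bp=4096)
        offset = 0
        for raw in path.read_bytes().splitlines(keepends=True):
            fields = raw.decode().split("\t")
            start, end = int(fields[1]), int(fields[2])
            for b in range(start // 4096, (end - 1) // 4096 + 1):
                assert idx.chroms["chrA"][b] <= offset
            offset += len(raw)


class TestIndexedQuery:
    @pytest.mark.parametrize("bin_size", [1024, 16384])
    def test_equivalent_to_linear_scan(self, sorted_bed, rng, bin_size):
        path, records, region = sorted_bed
        idx = build_index(path, bin_size_bp=bin_size)
        for _ in range(100):
            s = int(rng.integers(0, region.end - 1))
            e = int(rng.integers(s + 1, region.end + 1000))
            q = SourceQuery("s1", GenomicRegion("chrA", s, e))
            assert indexed_query(path, idx, q) == linear_scan(records, q.region)

    def test_region_beyond_last_record_is_empty(self, sorted_bed):
        path, _, _ = sorted_bed
        idx = build_index(path)
        q = SourceQuery("s1", GenomicRegion("chrA", 10_000_000, 10_000_100))
        assert indexed_query(path, idx, q) == []

    def test_whole_chromosome_query_returns_everything(self, sorted_bed):
        path, records, _ = sorted_bed
        idx = build_index(path)
        q = SourceQuery("s1", GenomicRegion("chrA", 0, 10_000_000))
        assert indexed_query(path, idx, q) == records

    def test_stale_index_detected(self, sorted_bed):
        path, _, _ = sorted_bed
        idx = build_index(path)
        with open(path, "a") as fh:
            fh.write("chrA\t999999\t1000000\t1\n")
        with pytest.raises(StaleIndexError):
            indexed_query(path, idx, SourceQuery("s1", GenomicRegion("chrA", 0, 10)))

    def test_scan_is_bounded_by_index(self, tmp_path):
        """Query near the end of a large file must not scan earlier records."""
        lines = [f"chrA\t{i * 100}\t{i * 100 + 50}\t1\n" for i in range(10_000)]
        p = tmp_path / "adv.bed"
        p.write_text("".join(lines))
        idx = build_index(p, bin_size_bp=1024)
        stats = {}
        q = SourceQuery("adv", GenomicRegion("chrA", 990_000, 991_000))
        hits = indexed_query(p, idx, q, stats=stats)
        assert len(hits) == 10
        # records sharing the first overlapping bin + the stop record at most
        assert stats["records_scanned"] <= 1024 // 100 + len(hits) + 2


class TestDirectorySource:
    def test_lists_and_queries_samples(self, tmp_path):
        for name, v in (("a.bed", 1.0), ("b.bed", 2.0)):
            write_bed_file([BedRecord("chrA", 0, 10, v)], tmp_path / name)
        src = DirectorySource(tmp_path)
        assert src.samples() == ["a", "b"]
        got = src.query(SourceQuery("b", GenomicRegion("chrA", 0, 10)))
        assert got == [BedRecord("chrA", 0, 10, 2.0)]
        with pytest.raises(KeyError):
            src.query(SourceQuery("zz", GenomicRegion("chrA", 0, 10)))
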