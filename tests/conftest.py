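import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from horizonbed.bed_io import BedRecord
from horizonbed.genomic_model import GenomicRegion

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160127)


def random_records(rng, region: GenomicRegion, n: int, max_len: int = 50):
    """n random records inside (or slightly overlapping) a region."""
    out = []
    for _ in range(n):
        start = int(rng.integers(max(region.start - max_len, 0), region.end))
        length = int(rng.integers(1, max_len + 1))
        value = float(np.round(rng.normal(0, 30), 3))
        out.append(BedRecord(region.chrom, start, start + length, value))
    return out


def sorted_bed_lines(records):
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    from horizonbed.bed_io import format_value

    return [
        f"{r.chrom}\t{r.start}\t{r.end}\t{format_value(r.value)}\n" for r in recs
    ]
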