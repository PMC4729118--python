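"""Synthetic multi-sample read-depth generator.

Emulates the canonical sequencing-QC scenario: a cohort of whole-genome
samples at ~30x depth over a ~100 kb region, with a few sub-intervals
consistently underrepresented across *all* samples (shared dropouts, e.g.
mappability holes) and one sample whose depth is globally low (a failed or
shallow library).  A horizon chart of these tracks makes both defects
visible at a glance: dark vertical stripes shared across tracks, and one
uniformly pale track.

The noise model is a truncated Gaussian on per-window mean depth, not
per-read Poisson sampling — this package exercises visualization and data
plumbing, so smooth depth-like noise suffices and is cheap.  Output is
deterministic given the seed: sorted, non-overlapping windows exactly
tiling the region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .bed_io import BedRecord, write_bed_file
from .genomic_model import GenomicRegion

# The showcase scenario: 24 samples, 100 kb of chr17, 30x.
DEFAULT_REGION = GenomicRegion("chr17", 1_100_000, 1_200_000)
DEFAULT_DROPOUT_MULTIPLIER = 0.2
DEFAULT_LOW_SAMPLE_FACTOR = 0.3


@dataclass(frozen=True)
class DropoutInterval:
    """A sub-region whose depth is scaled by ``multiplier`` in all samples."""

    start: int
    end: int
    multiplier: float = DEFAULT_DROPOUT_MULTIPLIER

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid dropout interval")
        if not (0.0 <= self.multiplier < 1.0):
            raise ValueError("dropout multiplier must be in [0, 1)")


@dataclass(frozen=True)
class CoverageSimSpec:
    """Parameters of one simulated cohort.

    Defaults model 24 whole-genome samples at 30x over 100 kb of chr17,
    100 bp windows, noise SD 3 (a 10% coefficient of variation on
    window-mean depth, typical of desk-scale WGS summaries), one globally
    low sample at 30% depth and shared dropout holes at 20% depth.
    """

    n_samples: int = 24
    region: GenomicRegion = DEFAULT_REGION
    mean_depth: float = 30.0
    noise_sd: float = 3.0
    shared_dropout_intervals: tuple[DropoutInterval, ...] = ()
    low_sample_index: Optional[int] = None
    low_sample_factor: float = DEFAULT_LOW_SAMPLE_FACTOR
    window_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if not (0.0 < self.low_sample_factor < 1.0):
            raise ValueError("low_sample_factor must be in (0, 1)")
        if self.low_sample_index is not None and not (
            0 <= self.low_sample_index < self.n_samples
        ):
            raise ValueError("low_sample_index out of range")
        for d in self.shared_dropout_intervals:
            if d.start < self.region.start or d.end > self.region.end:
                raise ValueError(
                    f"dropout {d.start}-{d.end} outside region {self.region}"
                )

    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"sample_{i + 1:0{width}d}" for i in range(self.n_samples)]


def default_demo_spec(seed: int = 0) -> CoverageSimSpec:
    """The end-to-end demo cohort: two shared dropouts and one low sample."""
    r = DEFAULT_REGION
    return CoverageSimSpec(
        shared_dropout_intervals=(
            DropoutInterval(r.start + 20_000, r.start + 25_000),
            DropoutInterval(r.start + 60_000, r.start + 68_000),
        ),
        low_sample_index=9,
        seed=seed,
    )


def simulate_coverage(spec: CoverageSimSpec) -> dict[str, list[BedRecord]]:
    """Generate one BED record sequence per sample.

    Windows of ``window_bp`` tile the region exactly (the last window may
    be short).  Window value = mean_depth x shared dropout multiplier x
    per-sample factor + Gaussian noise, truncated at 0.
    """
    rng = np.random.default_rng(spec.seed)
    region = spec.region
    n = region.length()
    starts = np.arange(region.start, region.end, spec.window_bp, dtype=np.int64)
    ends = np.minimum(starts + spec.window_bp, region.end)
    centers_mult = np.ones(len(starts))
    for d in spec.shared_dropout_intervals:
        # a window takes the multiplier in proportion to its overlap
        ov = np.maximum(
            0, np.minimum(ends, d.end) - np.maximum(starts, d.start)
        ) / (ends - starts)
        centers_mult *= 1.0 - ov * (1.0 - d.multiplier)
    out: dict[str, list[BedRecord]] = {}
    for i, sid in enumerate(spec.sample_ids()):
        factor = (
            spec.low_sample_factor if i == spec.low_sample_index else 1.0
        )
        noise = rng.normal(0.0, spec.noise_sd, len(starts)) if spec.noise_sd > 0 else 0.0
        values = np.maximum(spec.mean_depth * factor * centers_mult + noise, 0.0)
        out[sid] = [
            BedRecord(region.chrom, int(s), int(e), float(v))
            for s, e, v in zip(starts, ends, values)
        ]
    return out


def write_cohort(
    spec: CoverageSimSpec, out_dir: Union[str, PathLike]
) -> dict:
    """Simulate and write one BED file per sample plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_coverage(spec)
    for sid, records in cohort.items():
        write_bed_file(records, out_dir / f"{sid}.bed")
    manifest = {
        "region": str(spec.region),
        "n_samples": spec.n_samples,
        "mean_depth": spec.mean_depth,
        "noise_sd": spec.noise_sd,
        "window_bp": spec.window_bp,
        "seed": spec.seed,
        "low_sample": (
            spec.sample_ids()[spec.low_sample_index]
            if spec.low_sample_index is not None
            else None
        ),
        "low_sample_factor": spec.low_sample_factor,
        "shared_dropouts": [
            [d.start, d.end, d.multiplier]
            for d in spec.shared_dropout_intervals
        ],
        "samples": spec.sample_ids(),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
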