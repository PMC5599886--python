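"""Quantifying cross-build coordinate incompatibility by binning.

The procedure: segment the source build's autosomes and sex chromosomes
into fixed-size bins (1 kb by default), lift every bin to the other build
through a chain file, and measure how far each bin moved — the distance
between the source bin's midpoint and its lifted image's midpoint.  Bins
that fail to lift, land on another chromosome, keep identical coordinates,
or move beyond a distance threshold (30 kb by default) are tallied.
The *erroneous fraction* — bins whose coordinates did not stay identical —
is what naive genome arithmetic across the two builds would get wrong.

For hg19 at 1-kb resolution the primary chromosomes yield exactly
3,095,689 bins.

Two denominators are defensible for the "moved beyond threshold" share
(all bins, or mapped bins only); the report carries both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

from .chain import ChainIndex, DEFAULT_MIN_MATCH, LiftResult, lift_interval
from .errors import ConfigurationError, TrackProvError
from .registry import GenomeBuild
from .tracks import GenomicInterval

__all__ = [
    "DEFAULT_BIN_SIZE",
    "DEFAULT_DISTANCE_THRESHOLD",
    "CROSS_CHROMOSOME",
    "FAILED",
    "BinStats",
    "make_bins",
    "bin_distance",
    "summarize",
    "run_liftcheck",
]

DEFAULT_BIN_SIZE = 1000
DEFAULT_DISTANCE_THRESHOLD = 30_000

#: classification values returned by :func:`bin_distance`
CROSS_CHROMOSOME = "cross_chromosome"
FAILED = "failed"

#: histogram bin edges for midpoint distances (bp); last bucket is open
DEFAULT_HISTOGRAM_EDGES = (0, 1, 10, 100, 1_000, 10_000, 30_000, 100_000, 1_000_000)


def make_bins(build: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE) -> list[GenomicInterval]:
    """Consecutive fixed-size bins over the build's primary chromosomes.

    Per chromosome of length L: bins [k*s, min((k+1)*s, L)) for
    k = 0 .. ceil(L/s)-1; the final bin may be short.
    """
    if bin_size <= 0:
        raise ConfigurationError(f"bin_size must be positive, got {bin_size}")
    bins: list[GenomicInterval] = []
    line = 1
    for chrom in build.primary_set:
        length = build.chrom_sizes[chrom]
        for k in range(ceil(length / bin_size)):
            start = k * bin_size
            bins.append(
                GenomicInterval(
                    chrom=chrom, start=start, end=min(start + bin_size, length),
                    source_line=line,
                )
            )
            line += 1
    return bins


def bin_distance(src: GenomicInterval, lifted: LiftResult) -> int | str:
    """Midpoint distance between a bin and its lifted image.

    Returns the absolute midpoint distance in bp for same-chromosome
    mappings, :data:`CROSS_CHROMOSOME` for mappings onto another
    chromosome, and :data:`FAILED` for any non-mapped result.
    Midpoints are floor((start+end)/2).
    """
    if not lifted.is_mapped:
        return FAILED
    image = lifted.mapped_interval
    if image.chrom != src.chrom:
        return CROSS_CHROMOSOME
    return abs(src.midpoint - image.midpoint)


@dataclass
class BinStats:
    """Tallies of bin fates after lift-over between two builds."""

    n_total: int
    n_failed: int
    n_cross_chromosome: int
    n_identical: int
    n_beyond_threshold: int
    distance_threshold: int
    bin_size: int
    distance_histogram: dict[str, int] = field(default_factory=dict)

    @property
    def n_mapped(self) -> int:
        return self.n_total - self.n_failed

    @property
    def pct_failed(self) -> float:
        return 100.0 * self.n_failed / self.n_total if self.n_total else 0.0

    @property
    def pct_identical(self) -> float:
        return 100.0 * self.n_identical / self.n_total if self.n_total else 0.0

    @property
    def pct_beyond_threshold(self) -> float:
        """Share of *all* bins that mapped further away than the threshold."""
        return 100.0 * self.n_beyond_threshold / self.n_total if self.n_total else 0.0

    @property
    def pct_beyond_threshold_of_mapped(self) -> float:
        return 100.0 * self.n_beyond_threshold / self.n_mapped if self.n_mapped else 0.0

    @property
    def pct_erroneous(self) -> float:
        """Share of bins a cross-build integration would get wrong."""
        return 100.0 * (self.n_total - self.n_identical) / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "bin_size": self.bin_size,
            "distance_threshold": self.distance_threshold,
            "n_total": self.n_total,
            "n_mapped": self.n_mapped,
            "n_failed": self.n_failed,
            "n_cross_chromosome": self.n_cross_chromosome,
            "n_identical": self.n_identical,
            "n_beyond_threshold": self.n_beyond_threshold,
            "pct_failed": round(self.pct_failed, 1),
            "pct_identical": round(self.pct_identical, 1),
            "pct_beyond_threshold": round(self.pct_beyond_threshold, 1),
            "pct_beyond_threshold_of_mapped": round(self.pct_beyond_threshold_of_mapped, 1),
            "pct_erroneous": round(self.pct_erroneous, 1),
            "distance_histogram": dict(self.distance_histogram),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        payload = self.to_dict()
        payload.pop("distance_histogram")
        keys = list(payload)
        return (
            "\t".join(keys) + "\n" + "\t".join(str(payload[k]) for k in keys) + "\n"
        )


def _histogram_label(edges: Sequence[int], i: int) -> str:
    if i + 1 < len(edges):
        return f"[{edges[i]},{edges[i + 1]})"
    return f">={edges[-1]}"


def summarize(
    bins: Sequence[GenomicInterval],
    results: Sequence[LiftResult],
    distance_threshold: int = DEFAULT_DISTANCE_THRESHOLD,
    bin_size: int = DEFAULT_BIN_SIZE,
    histogram_edges: Sequence[int] = DEFAULT_HISTOGRAM_EDGES,
) -> BinStats:
    """Aggregate lift results for a bin set into :class:`BinStats`.

    "Identical" means same chromosome, same start and same end.  Bins
    moved beyond the threshold are counted among same-chromosome mappings;
    cross-chromosome and failed bins contribute to the erroneous fraction
    but not to the distance tally.
    """
    if len(bins) != len(results):
        raise TrackProvError(
            f"{len(bins)} bins but {len(results)} lift results"
        )
    n_failed = n_cross = n_identical = n_beyond = 0
    histogram = {_histogram_label(histogram_edges, i): 0 for i in range(len(histogram_edges))}
    histogram[CROSS_CHROMOSOME] = 0
    histogram[FAILED] = 0
    for src, res in zip(bins, results):
        dist = bin_distance(src, res)
        if dist == FAILED:
            n_failed += 1
            histogram[FAILED] += 1
            continue
        if dist == CROSS_CHROMOSOME:
            n_cross += 1
            histogram[CROSS_CHROMOSOME] += 1
            continue
        image = res.mapped_interval
        if dist == 0 and image.start == src.start and image.end == src.end:
            n_identical += 1
        if dist > distance_threshold:
            n_beyond += 1
        bucket = len(histogram_edges) - 1
        for i in range(len(histogram_edges) - 1):
            if histogram_edges[i] <= dist < histogram_edges[i + 1]:
                bucket = i
                break
        histogram[_histogram_label(histogram_edges, bucket)] += 1
    return BinStats(
        n_total=len(bins),
        n_failed=n_failed,
        n_cross_chromosome=n_cross,
        n_identical=n_identical,
        n_beyond_threshold=n_beyond,
        distance_threshold=distance_threshold,
        bin_size=bin_size,
        distance_histogram=histogram,
    )


def run_liftcheck(
    build: GenomeBuild,
    chains: ChainIndex,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_match: float = DEFAULT_MIN_MATCH,
    distance_threshold: int = DEFAULT_DISTANCE_THRESHOLD,
) -> BinStats:
    """Bin the source build, lift every bin, and summarize the outcome."""
    bins = make_bins(build, bin_size)
    results = [lift_interval(b, chains, min_match=min_match) for b in bins]
    return summarize(
        bins, results,
        distance_threshold=distance_threshold,
        bin_size=bin_size,
    )
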