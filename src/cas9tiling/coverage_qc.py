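"""Coverage and read-length QC over a target region.

Computes the run statistics used to judge an enrichment experiment: exact
per-base depth from read intervals (clipped to the region), min/mean/max
depth, the cumulative coverage curve (percentage of bases at or above each
depth threshold), on-target read count and read N50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .seqio import GenomicRegion, PathLike


@dataclass(frozen=True)
class DepthProfile:
    region: GenomicRegion
    depth: np.ndarray  # int per base, length == region.length()

    def __post_init__(self) -> None:
        if len(self.depth) != self.region.length():
            raise ValueError("depth array length must equal region length")


@dataclass(frozen=True)
class QcSummary:
    n_reads: int
    n50: int
    min_depth: int
    mean_depth: float
    max_depth: int
    pct_at_or_above: Mapping[int, float]


def depth_profile(
    intervals: Iterable[GenomicRegion], region: GenomicRegion
) -> DepthProfile:
    """Exact per-base depth of ``intervals`` over ``region`` (clipping overhangs)."""
    length = region.length()
    diff = np.zeros(length + 1, dtype=np.int64)
    for iv in intervals:
        if iv.seq_name != region.seq_name:
            raise ValueError(
                f"interval on {iv.seq_name!r} does not match region {region.seq_name!r}"
            )
        s = max(iv.start, region.start) - region.start
        e = min(iv.end, region.end) - region.start
        if s < e:
            diff[s] += 1
            diff[e] -= 1
    return DepthProfile(region, np.cumsum(diff[:-1]))


def depth_stats(profile: DepthProfile) -> tuple[int, float, int]:
    """(min, mean, max) depth; mean rounded half-up to 2 decimals."""
    d = profile.depth
    if d.size == 0:
        raise ValueError("empty depth profile")
    return int(d.min()), round_half_up(float(d.mean()), 2), int(d.max())


def cumulative_coverage(
    profile: DepthProfile, thresholds: Sequence[int]
) -> dict[int, float]:
    """Percentage of region bases with depth >= t, for each threshold t."""
    if any(t < 0 for t in thresholds):
        raise ValueError("thresholds must be >= 0")
    d = profile.depth
    n = d.size
    return {
        int(t): round_half_up(100.0 * int((d >= t).sum()) / n, 2) for t in thresholds
    }


def read_n50(lengths: Sequence[int]) -> int:
    """N50: largest length L such that reads >= L hold half of all bases.

    Computed as the first length, in descending order, at which the
    cumulative sum reaches half the total.
    """
    if not len(lengths):
        raise ValueError("read_n50 needs at least one length")
    if min(lengths) <= 0:
        raise ValueError("read lengths must be positive")
    srt = sorted(lengths, reverse=True)
    half = sum(srt) / 2.0
    acc = 0
    for length in srt:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def qc_summary(
    intervals: Sequence[GenomicRegion],
    region: GenomicRegion,
    thresholds: Sequence[int] = (1, 20, 60),
) -> QcSummary:
    """Full QC block for read intervals against a target region.

    A read is on-target when its interval intersects the region by >= 1 bp;
    N50 uses the full (unclipped) lengths of on-target reads.
    """
    on_target = [iv for iv in intervals if iv.intersects(region)]
    profile = depth_profile(on_target, region)
    mn, mean, mx = depth_stats(profile)
    lengths = [iv.length() for iv in on_target]
    return QcSummary(
        n_reads=len(on_target),
        n50=read_n50(lengths) if lengths else 0,
        min_depth=mn,
        mean_depth=mean,
        max_depth=mx,
        pct_at_or_above=cumulative_coverage(profile, thresholds),
    )


def qc_table(summary: QcSummary) -> pd.DataFrame:
    """QC summary as a two-column statistic/value table."""
    rows = [
        ("Reads", summary.n_reads),
        ("PASS read N50 (bp)", summary.n50),
        ("Min depth", summary.min_depth),
        ("Mean depth", summary.mean_depth),
        ("Max depth", summary.max_depth),
    ]
    rows += [
        (f"% bases >= x{t}", pct) for t, pct in sorted(summary.pct_at_or_above.items())
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def write_qc_table(summary: QcSummary, path: PathLike) -> None:
    qc_table(summary).to_csv(path, sep="\t", index=False)
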