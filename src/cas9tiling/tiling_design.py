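"""Tiling selection of opposite-strand guide pairs and pool arrangement.

A locus larger than ~20 kb is enriched with the tiling approach: the target
(plus optional flanks) is partitioned into near-equal blocks of at most
10 kb, and each block receives one guide pair cutting on opposite strands —
a minus-strand guide near the block's left edge (its read runs rightwards
into the block) and a plus-strand guide near the right edge (read runs
leftwards). Adjacent cuts end up < 10 kb apart so reads jointly span the
locus.

Two pool arrangements for library preparation are supported:

* ``bricklayer`` — alternate pairs go to pools A and B, so no pool contains
  two adjacent pairs;
* ``highway`` — pools C and D are exactly the strand classes (all minus-cut
  guides together, all plus-cut guides together).
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import pandas as pd

from ._util import round_half_up_int
from .guide_scan import (
    DEFAULT_BACKBONE,
    CriteriaConfig,
    GuideCandidate,
    GuideMetrics,
    compute_metrics,
    enumerate_candidates,
    passes_criteria,
)
from .seqio import GenomicRegion, SequenceRecord


class DesignError(RuntimeError):
    """Raised when no criteria-passing pair exists for a tile."""


@dataclass(frozen=True)
class TileBlock:
    index: int  # 1-based
    span: GenomicRegion


@dataclass(frozen=True)
class SelectedGuide:
    name: str
    candidate: GuideCandidate
    metrics: GuideMetrics


@dataclass(frozen=True)
class GuidePair:
    tile: TileBlock
    minus_guide: SelectedGuide
    plus_guide: SelectedGuide

    def __post_init__(self) -> None:
        if self.minus_guide.candidate.strand != "-" or self.plus_guide.candidate.strand != "+":
            raise ValueError("pair must hold one - guide and one + guide")

    @property
    def cut_distance(self) -> int:
        return abs(self.plus_guide.candidate.cut_pos - self.minus_guide.candidate.cut_pos)


@dataclass(frozen=True)
class DesignConfig:
    """Geometry and selection parameters of the tiling design."""

    flank: int = 5000
    block_size: int = 10000
    window: int = 1500
    window_step: int = 500
    window_max: int = 5000
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    backbone: str = DEFAULT_BACKBONE
    max_adjacent_distance: int = 10000


@dataclass(frozen=True)
class TilingDesign:
    region: GenomicRegion
    pairs: tuple[GuidePair, ...]
    criteria: CriteriaConfig

    def guides(self) -> list[SelectedGuide]:
        out: list[SelectedGuide] = []
        for p in self.pairs:
            out.extend((p.minus_guide, p.plus_guide))
        return out

    def cut_positions(self) -> list[int]:
        return sorted(g.candidate.cut_pos for g in self.guides())

    def adjacent_cut_distances(self) -> list[int]:
        cuts = self.cut_positions()
        return [b - a for a, b in zip(cuts, cuts[1:])]


@dataclass(frozen=True)
class PoolLayout:
    scheme: str
    pools: dict[str, tuple[str, ...]]


def expand_with_flanks(locus: GenomicRegion, flank: int = 5000) -> GenomicRegion:
    """Symmetrically widen the locus by ``flank`` bp on each side."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if locus.start < flank:
        raise ValueError("flank would extend past the sequence origin")
    if flank == 0:
        return locus
    return GenomicRegion(locus.seq_name, locus.start - flank, locus.end + flank, locus.label)


def build_tiles(region: GenomicRegion, block_size: int = 10000) -> list[TileBlock]:
    """Contiguous, exhaustive partition into ceil(length/block_size) blocks.

    Boundary k sits at ``start + round_half_up(k * length / n)`` so the blocks
    differ in length by at most 1 bp and none exceeds ``block_size``.
    """
    if block_size < 1000:
        raise ValueError("block_size must be >= 1000")
    length = region.length()
    n = math.ceil(length / block_size)
    bounds = [region.start + round_half_up_int(k * length / n) for k in range(n + 1)]
    return [
        TileBlock(k + 1, GenomicRegion(region.seq_name, bounds[k], bounds[k + 1]))
        for k in range(n)
    ]


def _pick(
    candidates: list[GuideCandidate],
    cuts: list[int],
    edge: int,
    metrics_of: Callable[[GuideCandidate], GuideMetrics],
    criteria: CriteriaConfig,
    window: int,
    window_step: int,
    window_max: int,
) -> Optional[tuple[GuideCandidate, GuideMetrics]]:
    """Best criteria-passing candidate with cut within a growing window of ``edge``.

    "Best" = highest efficiency, ties broken by |cut - edge| then by
    protospacer string. Efficiency and the tie-breaks need no off-target
    scan, so candidates are tried in that order and the first one passing
    the full criteria wins (equivalent to filtering first, cheaper).
    """
    w = window
    while w <= window_max:
        lo, hi = bisect_left(cuts, edge - w), bisect_right(cuts, edge + w)
        pool = candidates[lo:hi]
        if pool:
            ranked = sorted(
                pool,
                key=lambda c: (
                    -metrics_of(c).efficiency,
                    abs(c.cut_pos - edge),
                    c.protospacer,
                ),
            )
            for cand in ranked:
                if passes_criteria(metrics_of(cand), criteria):
                    return cand, metrics_of(cand)
        w += window_step
    return None


def select_pair_for_tile(
    tile: TileBlock,
    candidates: Iterable[GuideCandidate],
    metrics_of: Callable[[GuideCandidate], GuideMetrics],
    criteria: CriteriaConfig = CriteriaConfig(),
    window: int = 1500,
    window_step: int = 500,
    window_max: int = 5000,
) -> GuidePair:
    """One opposite-strand pair for a tile: - guide at the left edge, + at the right."""
    minus = sorted(
        (c for c in candidates if c.strand == "-"), key=lambda c: c.cut_pos
    )
    plus = sorted((c for c in candidates if c.strand == "+"), key=lambda c: c.cut_pos)
    minus_cuts = [c.cut_pos for c in minus]
    plus_cuts = [c.cut_pos for c in plus]

    m = _pick(minus, minus_cuts, tile.span.start, metrics_of, criteria, window, window_step, window_max)
    if m is None:
        raise DesignError(
            f"tile {tile.index}: no criteria-passing - guide within "
            f"{window_max} bp of position {tile.span.start}"
        )
    p = _pick(plus, plus_cuts, tile.span.end, metrics_of, criteria, window, window_step, window_max)
    if p is None:
        raise DesignError(
            f"tile {tile.index}: no criteria-passing + guide within "
            f"{window_max} bp of position {tile.span.end}"
        )
    return GuidePair(
        tile=tile,
        minus_guide=SelectedGuide(f"pair{tile.index}_minus", m[0], m[1]),
        plus_guide=SelectedGuide(f"pair{tile.index}_plus", p[0], p[1]),
    )


def design_tiling(
    ref: SequenceRecord,
    locus: GenomicRegion,
    config: DesignConfig = DesignConfig(),
) -> TilingDesign:
    """Full design: flank expansion -> tiling -> per-tile pair selection.

    Deterministic for a fixed reference. Raises :class:`DesignError` when a
    tile has no passing pair or a geometric invariant (pair distance <=
    block size, adjacent cuts < 10 kb) cannot be met.
    """
    region = expand_with_flanks(locus, config.flank)
    candidates = enumerate_candidates(ref, region)
    tiles = build_tiles(region, config.block_size)

    cache: dict[GuideCandidate, GuideMetrics] = {}

    def metrics_of(c: GuideCandidate) -> GuideMetrics:
        if c not in cache:
            cache[c] = compute_metrics(c, [ref], backbone=config.backbone)
        return cache[c]

    pairs = tuple(
        select_pair_for_tile(
            tile,
            candidates,
            metrics_of,
            config.criteria,
            config.window,
            config.window_step,
            config.window_max,
        )
        for tile in tiles
    )

    design = TilingDesign(region=region, pairs=pairs, criteria=config.criteria)
    for pair in pairs:
        if pair.cut_distance > config.block_size:
            raise DesignError(
                f"tile {pair.tile.index}: pair cut distance {pair.cut_distance} "
                f"exceeds block size {config.block_size}"
            )
    gaps = design.adjacent_cut_distances()
    if gaps and max(gaps) >= config.max_adjacent_distance:
        raise DesignError(
            f"adjacent cut distance {max(gaps)} >= {config.max_adjacent_distance}"
        )
    return design


def assign_pools(design: TilingDesign, scheme: str) -> PoolLayout:
    """Arrange the designed guides into two pools.

    ``bricklayer``: odd-indexed pairs -> pool A, even-indexed -> pool B, so
    adjacent (overlapping) pairs never share a pool. ``highway``: pool C is
    every minus-cut guide, pool D every plus-cut guide.
    """
    if not design.pairs:
        raise ValueError("design has no pairs")
    if scheme == "bricklayer":
        a = tuple(
            g.name
            for p in design.pairs
            if p.tile.index % 2 == 1
            for g in (p.minus_guide, p.plus_guide)
        )
        b = tuple(
            g.name
            for p in design.pairs
            if p.tile.index % 2 == 0
            for g in (p.minus_guide, p.plus_guide)
        )
        return PoolLayout("bricklayer", {"A": a, "B": b})
    if scheme == "highway":
        c = tuple(p.minus_guide.name for p in design.pairs)
        d = tuple(p.plus_guide.name for p in design.pairs)
        return PoolLayout("highway", {"C": c, "D": d})
    raise ValueError(f"unknown pool scheme {scheme!r}")


def design_report(
    design: TilingDesign, layouts: Iterable[PoolLayout] = ()
) -> pd.DataFrame:
    """One row per selected guide with metrics, geometry and pool membership.

    Summary geometry (mean pair distance, mean/max adjacent-cut distance)
    is attached in ``DataFrame.attrs``.
    """
    pool_of: dict[str, dict[str, str]] = {}
    for layout in layouts:
        col = f"pool_{layout.scheme}"
        pool_of[col] = {
            name: pool for pool, names in layout.pools.items() for name in names
        }

    rows = []
    for pair in design.pairs:
        for g in (pair.minus_guide, pair.plus_guide):
            row = {
                "name": g.name,
                "tile": pair.tile.index,
                "strand": g.candidate.strand,
                "sequence": g.candidate.sequence,
                "cut_pos": g.candidate.cut_pos,
                "gc_percent": g.metrics.gc_percent,
                "self_complementarity": g.metrics.self_complementarity,
                "MM0": g.metrics.mm_counts[0],
                "MM1": g.metrics.mm_counts[1],
                "MM2": g.metrics.mm_counts[2],
                "MM3": g.metrics.mm_counts[3],
                "efficiency": g.metrics.efficiency,
                "pair_distance": pair.cut_distance,
            }
            for col, mapping in pool_of.items():
                row[col] = mapping.get(g.name, "")
            rows.append(row)
    df = pd.DataFrame(rows)
    gaps = design.adjacent_cut_distances()
    df.attrs["mean_pair_distance"] = (
        sum(p.cut_distance for p in design.pairs) / len(design.pairs)
    )
    df.attrs["mean_adjacent_cut_distance"] = sum(gaps) / len(gaps) if gaps else 0.0
    df.attrs["max_adjacent_cut_distance"] = max(gaps) if gaps else 0
    return df
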