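"""Callset comparison and variant-category bookkeeping for a target locus.

Two site-level callsets (e.g. nanopore enrichment vs short-read WGS) are
restricted to the locus, matched on the exact (name, pos, ref, alt) key and
summarised as shared / unique-to-either with a concordance percentage
against the reference callset. In-region variants are classified against a
single transcript model into coding / 5'UTR / 3'UTR / intronic / flanking,
with the distance to the nearest exon carried so any "deep intronic" cutoff
can be applied downstream. A rarity filter keeps variants with population
allele frequency < 0.001 (missing frequency counts as rare: absent from the
population databases).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .seqio import GenomicRegion, PathLike, TranscriptModel, VariantRecord

CATEGORIES = ("coding", "utr5", "utr3", "intronic", "flanking")


@dataclass(frozen=True)
class CallsetComparison:
    shared: tuple[tuple[VariantRecord, VariantRecord], ...]
    only_a: tuple[VariantRecord, ...]
    only_b: tuple[VariantRecord, ...]
    concordance_pct: float


@dataclass(frozen=True)
class VariantClass:
    category: str
    distance_to_exon: int  # 0 for exonic

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class SummaryTable:
    counts: Mapping[str, int]
    pct: Mapping[str, float]
    n_rare: int
    n_low_qual: int
    total: int


def restrict_to_region(
    variants: Iterable[VariantRecord], region: GenomicRegion
) -> list[VariantRecord]:
    """Variants whose 1-based position falls inside the region (inclusive bounds)."""
    lo, hi = region.start + 1, region.end
    return [v for v in variants if v.seq_name == region.seq_name and lo <= v.pos <= hi]


def match_variants(
    a: Sequence[VariantRecord], b: Sequence[VariantRecord]
) -> CallsetComparison:
    """Exact-key comparison of callset ``a`` against reference callset ``b``.

    Concordance is the percentage of ``b`` also found in ``a``, rounded
    half-up to 2 decimals. No indel normalisation is attempted: records must
    agree on (seq_name, pos, ref, alt) literally.
    """
    if not b:
        raise ValueError("reference callset b is empty; concordance undefined")
    index_a = {v.key: v for v in a}
    index_b = {v.key: v for v in b}
    shared = tuple(
        (index_a[v.key], v) for v in b if v.key in index_a
    )
    only_a = tuple(v for v in a if v.key not in index_b)
    only_b = tuple(v for v in b if v.key not in index_a)
    pct = round_half_up(100.0 * len(shared) / len(b), 2)
    return CallsetComparison(shared, only_a, only_b, pct)


def _distance_to_nearest_exon(pos0: int, model: TranscriptModel) -> int:
    best = None
    for e in model.exons:
        if e.contains(pos0):
            return 0
        d = e.start - pos0 if pos0 < e.start else pos0 - e.end + 1
        best = d if best is None else min(best, d)
    return best  # type: ignore[return-value]


def classify_variant(v: VariantRecord, model: TranscriptModel) -> VariantClass:
    """Place a variant in exactly one genic category.

    coding: inside CDS-overlapping exon sequence; utr5/utr3: exonic outside
    the CDS, side resolved by transcript strand; intronic: inside the
    transcript span but not exonic; flanking: outside the transcript span.
    The variant's REF start base determines its position.
    """
    pos0 = v.pos - 1
    if not model.region.contains(pos0):
        raise ValueError(
            f"variant at {v.seq_name}:{v.pos} lies outside the transcript region"
        )
    if model.is_exonic(pos0):
        if model.cds.contains(pos0):
            return VariantClass("coding", 0)
        genomically_upstream = pos0 < model.cds.start
        if model.strand == "+":
            return VariantClass("utr5" if genomically_upstream else "utr3", 0)
        return VariantClass("utr3" if genomically_upstream else "utr5", 0)
    dist = _distance_to_nearest_exon(pos0, model)
    if model.span.contains(pos0):
        return VariantClass("intronic", dist)
    return VariantClass("flanking", dist)


def summarize(
    classes: Sequence[VariantClass],
    variants: Sequence[VariantRecord],
    max_af: float = 0.001,
    qual_min: float = 10.0,
) -> SummaryTable:
    """Category counts/percentages plus rarity and low-quality tallies.

    Percentages are half-up to 2 decimals (59/71 -> 83.10). ``n_rare``
    counts allele frequency < max_af or missing; ``n_low_qual`` counts
    records with a reported QUAL < qual_min.
    """
    total = len(classes)
    counts = {cat: 0 for cat in CATEGORIES}
    for c in classes:
        counts[c.category] += 1
    pct = {
        cat: (round_half_up(100.0 * n / total, 2) if total else 0.0)
        for cat, n in counts.items()
    }
    n_rare = sum(
        1
        for v in variants
        if v.allele_frequency is None or v.allele_frequency < max_af
    )
    n_low_qual = sum(1 for v in variants if v.qual is not None and v.qual < qual_min)
    return SummaryTable(counts, pct, n_rare, n_low_qual, total)


def frequency_filter(
    variants: Iterable[VariantRecord], max_af: float = 0.001
) -> list[VariantRecord]:
    """Keep rare variants: AF strictly below ``max_af``, or AF missing."""
    return [
        v
        for v in variants
        if v.allele_frequency is None or v.allele_frequency < max_af
    ]


def summary_table(
    summary: SummaryTable, comparison: Optional[CallsetComparison] = None
) -> pd.DataFrame:
    """Summary (and optional comparison) as a statistic/value table."""
    rows: list[tuple[str, object]] = [("total variants", summary.total)]
    for cat in CATEGORIES:
        if summary.counts[cat]:
            rows.append((f"{cat} count", summary.counts[cat]))
            rows.append((f"{cat} pct", summary.pct[cat]))
    rows.append((f"rare (AF<0.001 or missing)", summary.n_rare))
    rows.append(("low quality (QUAL<10)", summary.n_low_qual))
    if comparison is not None:
        rows += [
            ("shared", len(comparison.shared)),
            ("only in A", len(comparison.only_a)),
            ("only in B", len(comparison.only_b)),
            ("concordance pct (of B)", comparison.concordance_pct),
        ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def write_summary_table(
    summary: SummaryTable,
    path: PathLike,
    comparison: Optional[CallsetComparison] = None,
) -> None:
    summary_table(summary, comparison).to_csv(path, sep="\t", index=False)
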