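"""SpCas9 guide candidate enumeration and per-guide metrics.

A guide candidate is a 20-nt protospacer followed by an NGG PAM on the
targeted strand. SpCas9 cuts bluntly 3 bp 5' of the PAM, between protospacer
positions 17 and 18; ``cut_pos`` records that boundary as a 0-based
plus-strand coordinate.

Metrics mirror a guide-design report: GC content, a 4-mer hairpin/backbone
self-complementarity count, off-target site counts at 0-3 mismatches
(PAM-constrained, on-target excluded) and a deterministic heuristic cut
efficiency in [0,1]. Guides are retained when they satisfy the design
criteria: GC in [30,80]%, self-complementarity 0, fewer than 10 off-target
sites over MM0-MM3, efficiency >= 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._util import revcomp, round_half_up
from .seqio import GenomicRegion, SequenceRecord

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN

#: Invariant part of the crRNA that can seed guide:backbone duplexes.
DEFAULT_BACKBONE = "AGGCTAGTCCGT"

_G = ord("G")
_C = ord("C")


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM site; coordinates are 0-based on the + strand."""

    protospacer: str
    pam: str
    strand: str
    protospacer_start: int
    cut_pos: int
    seq_name: str = ""

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or not self.pam.endswith("GG"):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        lo, hi = self.footprint
        if not (lo <= self.cut_pos < hi):
            raise ValueError("cut position outside protospacer footprint")

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic span of the protospacer on the + strand (half-open)."""
        return self.protospacer_start, self.protospacer_start + PROTOSPACER_LEN

    @property
    def sequence(self) -> str:
        """Protospacer + PAM, 5'->3' on the targeted strand (report style)."""
        return self.protospacer + self.pam


@dataclass(frozen=True)
class GuideMetrics:
    gc_percent: float
    self_complementarity: int
    mm_counts: tuple[int, ...]
    efficiency: float

    @property
    def total_offtargets(self) -> int:
        return int(sum(self.mm_counts))


@dataclass(frozen=True)
class CriteriaConfig:
    """Selection thresholds; defaults are the published design criteria."""

    gc_min: float = 30.0
    gc_max: float = 80.0
    max_self_complementarity: int = 0
    max_offtargets: int = 10  # strict: total MM0..MM3 must be < this
    min_efficiency: float = 0.2


def enumerate_candidates(
    ref: SequenceRecord, region: GenomicRegion
) -> list[GuideCandidate]:
    """All NGG-adjacent 20-mers on both strands of ``region``.

    Windows containing N are skipped. Candidates come back sorted by cut
    position, + strand before - on ties.
    """
    if region.seq_name != ref.name:
        raise ValueError(f"region on {region.seq_name!r} but reference is {ref.name!r}")
    if region.start < 0 or region.end > len(ref.sequence):
        raise ValueError("region lies outside the reference sequence")
    if region.length() < SITE_LEN:
        raise ValueError(f"region shorter than {SITE_LEN} bp")

    seq = ref.sequence[region.start : region.end]
    out: list[GuideCandidate] = []
    for i in range(len(seq) - SITE_LEN + 1):
        window = seq[i : i + SITE_LEN]
        if "N" in window:
            continue
        if window[21] == "G" and window[22] == "G":
            out.append(
                GuideCandidate(
                    protospacer=window[:PROTOSPACER_LEN],
                    pam=window[PROTOSPACER_LEN:],
                    strand="+",
                    protospacer_start=region.start + i,
                    cut_pos=region.start + i + 17,
                    seq_name=ref.name,
                )
            )
        if window[0] == "C" and window[1] == "C":
            rc = revcomp(window)
            out.append(
                GuideCandidate(
                    protospacer=rc[:PROTOSPACER_LEN],
                    pam=rc[PROTOSPACER_LEN:],
                    strand="-",
                    protospacer_start=region.start + i + PAM_LEN,
                    cut_pos=region.start + i + 6,
                    seq_name=ref.name,
                )
            )
    out.sort(key=lambda c: (c.cut_pos, c.strand))
    return out


def gc_percent(protospacer: str) -> float:
    """GC content of the 20-nt protospacer as a percentage."""
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 20 nt")
    if set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must be over ACGT")
    gc = sum(protospacer.count(b) for b in "GC")
    return round_half_up(100.0 * gc / PROTOSPACER_LEN, 1)


def self_complementarity(protospacer: str, backbone: str = DEFAULT_BACKBONE) -> int:
    """4-mer self-complementarity count (hairpin seeds + backbone duplexes).

    Counts (a) ordered position pairs (i, j), j >= i+7, where the 4-mer at j
    is the reverse complement of the 4-mer at i — an intramolecular hairpin
    seed with a >= 3 nt loop — and (b) protospacer 4-mers whose reverse
    complement occurs in ``backbone``. Pass ``backbone=""`` to count only the
    intramolecular part.
    """
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 20 nt")
    count = 0
    last = PROTOSPACER_LEN - 4
    for i in range(last + 1):
        rc = revcomp(protospacer[i : i + 4])
        for j in range(i + 7, last + 1):
            if protospacer[j : j + 4] == rc:
                count += 1
        if backbone and rc in backbone:
            count += 1
    return count


def _longest_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def efficiency_score(protospacer: str, self_comp: int = 0) -> float:
    """Deterministic heuristic cut-efficiency score in [0, 1].

    Rewards a PAM-proximal G and mid-range GC; penalises a PAM-proximal T,
    extreme GC, homopolymer runs >= 5 and any self-complementarity:

        0.5 + 0.2*[base20 == G] - 0.1*[base20 == T]
            + 0.1*[40 <= GC <= 70] - 0.2*[GC < 30 or GC > 80]
            - 0.15*[homopolymer >= 5] - 0.1*[self_comp > 0]

    clamped to [0, 1].
    """
    gc = gc_percent(protospacer)
    eff = 0.5
    if protospacer[-1] == "G":
        eff += 0.2
    elif protospacer[-1] == "T":
        eff -= 0.1
    if 40.0 <= gc <= 70.0:
        eff += 0.1
    if gc < 30.0 or gc > 80.0:
        eff -= 0.2
    if _longest_homopolymer(protospacer) >= 5:
        eff -= 0.15
    if self_comp > 0:
        eff -= 0.1
    # terms are multiples of 0.05; quantize away float accumulation noise
    return min(1.0, max(0.0, round_half_up(eff, 2)))


def count_offtargets(
    candidate: GuideCandidate,
    genome: Sequence[SequenceRecord],
    max_mm: int = 3,
) -> tuple[int, ...]:
    """PAM-constrained off-target site counts at 0..max_mm mismatches.

    Scans every 23-mer window on both strands of every record; a window
    counts at level m when its NGG PAM is intact and its 20-mer differs from
    the protospacer at exactly m positions. The on-target site (same record,
    same footprint, same strand) is excluded.
    """
    if max_mm > PROTOSPACER_LEN or max_mm < 0:
        raise ValueError("max_mm must be in [0, 20]")
    if not genome:
        raise ValueError("genome must contain at least one record")

    counts = np.zeros(max_mm + 1, dtype=np.int64)
    proto = np.frombuffer(candidate.protospacer.encode("ascii"), dtype=np.uint8)
    proto_rc = np.frombuffer(
        revcomp(candidate.protospacer).encode("ascii"), dtype=np.uint8
    )

    for rec in genome:
        arr = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        if arr.size < SITE_LEN:
            continue
        w = sliding_window_view(arr, SITE_LEN)

        # + strand sites: ...20-mer NGG
        idx = np.nonzero((w[:, 21] == _G) & (w[:, 22] == _G))[0]
        if idx.size:
            mm = (w[idx, :PROTOSPACER_LEN] != proto).sum(axis=1)
            keep = mm <= max_mm
            counts += np.bincount(mm[keep], minlength=max_mm + 1)[: max_mm + 1]
            if (
                rec.name == candidate.seq_name
                and candidate.strand == "+"
                and candidate.protospacer_start in idx
            ):
                m = int(
                    (w[candidate.protospacer_start, :PROTOSPACER_LEN] != proto).sum()
                )
                if m <= max_mm:
                    counts[m] -= 1

        # - strand sites read CCN... on the + strand
        idx = np.nonzero((w[:, 0] == _C) & (w[:, 1] == _C))[0]
        if idx.size:
            mm = (w[idx, PAM_LEN:] != proto_rc).sum(axis=1)
            keep = mm <= max_mm
            counts += np.bincount(mm[keep], minlength=max_mm + 1)[: max_mm + 1]
            win_start = candidate.protospacer_start - PAM_LEN
            if (
                rec.name == candidate.seq_name
                and candidate.strand == "-"
                and win_start in idx
            ):
                m = int((w[win_start, PAM_LEN:] != proto_rc).sum())
                if m <= max_mm:
                    counts[m] -= 1

    return tuple(int(c) for c in counts)


def compute_metrics(
    candidate: GuideCandidate,
    genome: Sequence[SequenceRecord],
    backbone: str = DEFAULT_BACKBONE,
    max_mm: int = 3,
) -> GuideMetrics:
    """All per-guide metrics for one candidate (off-targets over ``genome``)."""
    gc = gc_percent(candidate.protospacer)
    sc = self_complementarity(candidate.protospacer, backbone)
    mm = count_offtargets(candidate, genome, max_mm)
    eff = efficiency_score(candidate.protospacer, sc)
    return GuideMetrics(gc, sc, mm, eff)


def passes_criteria(
    metrics: GuideMetrics, thresholds: CriteriaConfig = CriteriaConfig()
) -> bool:
    """Apply the four design criteria (off-target bound is strict '<')."""
    return (
        thresholds.gc_min <= metrics.gc_percent <= thresholds.gc_max
        and metrics.self_complementarity <= thresholds.max_self_complementarity
        and metrics.total_offtargets < thresholds.max_offtargets
        and metrics.efficiency >= thresholds.min_efficiency
    )


def guide_table(
    candidates: Iterable[GuideCandidate],
    metrics: Iterable[GuideMetrics],
    names: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Report-style table: one row per guide, design-report columns."""
    rows = []
    names = list(names) if names is not None else None
    for k, (cand, met) in enumerate(zip(candidates, metrics)):
        rows.append(
            {
                "name": names[k] if names else f"guide{k + 1}",
                "strand": cand.strand,
                "sequence": cand.sequence,
                "cut_pos": cand.cut_pos,
                "gc_percent": met.gc_percent,
                "self_complementarity": met.self_complementarity,
                "MM0": met.mm_counts[0],
                "MM1": met.mm_counts[1],
                "MM2": met.mm_counts[2],
                "MM3": met.mm_counts[3],
                "efficiency": met.efficiency,
            }
        )
    return pd.DataFrame(rows)
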