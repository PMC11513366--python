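"""Seeded generators for all desk-scale test inputs.

Everything the toolkit consumes from the wet lab or from public references
can be emulated here: random references with controllable GC (hence PAM
density) and planted protospacer sites at a chosen mismatch level, a 14-exon
transcript model laid out like a compact retinal-gene locus, and paired
variant callsets with a configured shared/unique structure and category mix.
All generators are pure functions of their spec (seeds included), so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._util import revcomp
from .seqio import (
    GenomicRegion,
    SequenceRecord,
    TranscriptModel,
    VariantRecord,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedSite:
    """A 23-mer (protospacer+NGG) written into the reference.

    ``n_mismatches`` protospacer positions are mutated before planting, so
    the site is recovered at exactly that mismatch level; the PAM is always
    intact. ``position`` is the 0-based start of the 23-mer window on the
    + strand (for strand '-', the window holds the reverse complement).
    """

    protospacer: str
    strand: str
    position: int
    n_mismatches: int = 0


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 42
    length: int = 31133
    gc_fraction: float = 0.4
    name: str = "chrS"
    planted_sites: tuple[PlantedSite, ...] = ()


def make_reference(spec: FixtureSpec) -> SequenceRecord:
    """I.i.d. random reference at the requested GC, with planted sites."""
    if spec.length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 < spec.gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc_fraction) / 2.0
    gc = spec.gc_fraction / 2.0
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=spec.length,
                     p=[at, gc, gc, at])

    occupied: list[tuple[int, int]] = []
    for site in spec.planted_sites:
        if len(site.protospacer) != 20 or site.strand not in {"+", "-"}:
            raise ValueError(f"bad planted site {site!r}")
        lo, hi = site.position, site.position + 23
        if lo < 0 or hi > spec.length:
            raise ValueError(f"planted site at {site.position} outside the sequence")
        if any(lo < e and s < hi for s, e in occupied):
            raise ValueError(f"planted sites overlap at {site.position}")
        occupied.append((lo, hi))
        proto = list(site.protospacer)
        if site.n_mismatches:
            pos = rng.choice(20, size=site.n_mismatches, replace=False)
            for p in pos:
                others = [b for b in _BASES if b != proto[p]]
                proto[p] = others[int(rng.integers(0, 3))]
        site23 = "".join(proto) + _BASES[int(rng.integers(0, 4))] + "GG"
        if site.strand == "-":
            site23 = revcomp(site23)
        arr[lo:hi] = np.frombuffer(site23.encode("ascii"), dtype=np.uint8)

    return SequenceRecord(spec.name, arr.tobytes().decode("ascii"))


# 14 exons + 13 introns spanning 21,133 bp, echoing a compact retinal locus:
# ~3.5 kb mRNA, a short 5'UTR in exon 1 and a long 3'UTR in the last exon.
DEFAULT_EXON_LENGTHS = (278, 183, 143, 117, 218, 95, 151, 87, 104, 126, 92, 139, 167, 1583)
DEFAULT_INTRON_LENGTHS = (1720, 902, 2111, 640, 1410, 988, 2205, 745, 1630, 1105, 860, 1912, 1422)


@dataclass(frozen=True)
class TranscriptLayout:
    exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS
    intron_lengths: tuple[int, ...] = DEFAULT_INTRON_LENGTHS
    offset: int = 5000  # transcript start relative to region start
    strand: str = "+"
    utr5_len: int = 100  # inside the first exon
    utr3_len: int = 800  # inside the last exon
    name: str = "synthetic_tx"


def make_transcript(
    layout: TranscriptLayout, region: GenomicRegion
) -> TranscriptModel:
    """Lay exons/introns into ``region`` and derive the CDS span."""
    if len(layout.intron_lengths) != len(layout.exon_lengths) - 1:
        raise ValueError("need exactly one intron fewer than exons")
    exons: list[GenomicRegion] = []
    cursor = region.start + layout.offset
    for i, elen in enumerate(layout.exon_lengths):
        exons.append(GenomicRegion(region.seq_name, cursor, cursor + elen, f"exon{i + 1}"))
        cursor += elen
        if i < len(layout.intron_lengths):
            cursor += layout.intron_lengths[i]
    if cursor > region.end:
        raise ValueError("transcript layout exceeds the region")
    if layout.utr5_len >= layout.exon_lengths[0] or layout.utr3_len >= layout.exon_lengths[-1]:
        raise ValueError("UTRs must fit inside the terminal exons")
    if layout.strand == "+":
        cds = GenomicRegion(
            region.seq_name, exons[0].start + layout.utr5_len, exons[-1].end - layout.utr3_len, "cds"
        )
    else:
        cds = GenomicRegion(
            region.seq_name, exons[0].start + layout.utr3_len, exons[-1].end - layout.utr5_len, "cds"
        )
    return TranscriptModel(
        region=region, strand=layout.strand, exons=tuple(exons), cds=cds, name=layout.name
    )


@dataclass(frozen=True)
class CallsetSpec:
    """Structure of a paired-callset fixture.

    Callset A plays the enrichment (query) role and has
    ``n_shared + n_only_a`` variants; callset B plays the orthogonal
    reference role with ``n_total_b`` variants of which ``n_shared`` also
    appear in A. ``category_mix`` (category -> count, summing to |A|) pins
    how many A variants fall into each genic category; ``rare_fraction`` of
    A variants receive an allele frequency below 0.001. Variants found only
    in A get a low QUAL (4-10), mimicking marginal false-positive calls.
    """

    n_total_b: int = 69
    n_shared: int = 68
    n_only_a: int = 3
    category_mix: Optional[dict[str, int]] = None
    rare_fraction: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 <= self.n_shared <= self.n_total_b:
            raise ValueError("need 0 <= n_shared <= n_total_b")
        if self.n_only_a < 0:
            raise ValueError("n_only_a must be >= 0")


def _category_positions(
    model: TranscriptModel, region: GenomicRegion
) -> dict[str, np.ndarray]:
    """0-based positions of each genic category inside the region."""
    length = region.length()
    labels = np.full(length, 4, dtype=np.int8)  # flanking
    span = model.span
    labels[span.start - region.start : span.end - region.start] = 3  # intronic
    for e in model.exons:
        lo, hi = e.start - region.start, e.end - region.start
        for p in range(lo, hi):
            gpos = p + region.start
            if model.cds.contains(gpos):
                labels[p] = 0
            else:
                upstream = gpos < model.cds.start
                if model.strand == "+":
                    labels[p] = 1 if upstream else 2
                else:
                    labels[p] = 2 if upstream else 1
    names = ("coding", "utr5", "utr3", "intronic", "flanking")
    return {
        name: np.nonzero(labels == i)[0] + region.start for i, name in enumerate(names)
    }


def make_callsets(
    spec: CallsetSpec, region: GenomicRegion, model: TranscriptModel
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Paired callsets (A, B) with the configured overlap and category mix.

    Positions are sampled without replacement; REF is a random base and ALT
    a random different base (site-level matching only). Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_a = spec.n_shared + spec.n_only_a
    n_only_b = spec.n_total_b - spec.n_shared
    n_union = n_a + n_only_b

    pools = _category_positions(model, region)
    if spec.category_mix is not None:
        if sum(spec.category_mix.values()) != n_a:
            raise ValueError("category_mix must sum to |A| = n_shared + n_only_a")
        positions: list[int] = []
        for cat, count in spec.category_mix.items():
            pool = pools[cat]
            if count > pool.size:
                raise ValueError(f"region too small: {count} {cat} variants requested")
            positions.extend(int(p) for p in rng.choice(pool, count, replace=False))
        # extra union positions (only-B) drawn intronic by default
        extra_pool = np.setdiff1d(pools["intronic"], np.array(positions, dtype=np.int64))
        positions.extend(int(p) for p in rng.choice(extra_pool, n_only_b, replace=False))
    else:
        all_pos = np.arange(region.start, region.end)
        if n_union > all_pos.size:
            raise ValueError("region too small for the requested variant count")
        positions = [int(p) for p in rng.choice(all_pos, n_union, replace=False)]

    def _record(pos0: int, low_qual: bool) -> VariantRecord:
        ref = _BASES[int(rng.integers(0, 4))]
        alt = [b for b in _BASES if b != ref][int(rng.integers(0, 3))]
        rare = rng.random() < spec.rare_fraction
        af = float(rng.uniform(1e-5, 9e-4)) if rare else float(rng.uniform(2e-3, 0.5))
        qual = float(rng.uniform(4, 9.9)) if low_qual else float(rng.uniform(20, 60))
        return VariantRecord(region.seq_name, pos0 + 1, ref, alt, round(qual, 1), af)

    # first n_shared+n_only_a positions belong to A; A's first n_shared are shared
    a_records = [
        _record(positions[i], low_qual=(i >= spec.n_shared)) for i in range(n_a)
    ]
    shared_b = [
        VariantRecord(v.seq_name, v.pos, v.ref, v.alt,
                      round(float(rng.uniform(20, 60)), 1), v.allele_frequency)
        for v in a_records[: spec.n_shared]
    ]
    only_b = [_record(positions[n_a + i], low_qual=False) for i in range(n_only_b)]
    b_records = shared_b + only_b
    a_records.sort(key=lambda v: v.pos)
    b_records.sort(key=lambda v: v.pos)
    return a_records, b_records
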