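"""Generative model of Cas9 cut-site capture and nanopore read production.

Each simulated molecule is a copy of the reference. Every designed guide
cuts its molecule independently with probability equal to its efficiency
score; each realised cut releases one sequenceable end, so it yields one
read starting exactly at the cut. Reads from minus-strand guides run toward
increasing coordinates and reads from plus-strand guides toward decreasing
coordinates — with guides placed at block edges cutting inward, coverage
piles up directionally from the cuts and decays into each block (the
sawtooth profile characteristic of Cas9 enrichment).

Read length is the minimum of a lognormal draw (median 8 kb by default),
the distance to the next realised cut on the same molecule (multiple RNPs
fragment the molecule), and the distance to the sequence end. A small
background rate models non-specific ends. Per-read quality is Gaussian;
reads below the pass threshold (Qscore 9 by default) are dropped by
:func:`apply_qscore_filter`. Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

import gzip
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from ._util import revcomp
from .seqio import GenomicRegion, PathLike, SequenceRecord
from .tiling_design import TilingDesign

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    n_molecules: int = 1000
    read_length_log_mean: float = math.log(8000.0)
    read_length_log_sd: float = 0.6
    background_rate: float = 0.01
    qscore_mean: float = 12.0
    qscore_sd: float = 2.5
    qscore_min_pass: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if min(self.read_length_log_sd, self.background_rate, self.qscore_sd) < 0:
            raise ValueError("rates and standard deviations must be non-negative")


@dataclass(frozen=True)
class SimGuide:
    """The slice of a design the simulator needs for one guide."""

    name: str
    cut_pos: int
    strand: str
    efficiency: float


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    start: int
    end: int
    direction: str  # 'fwd' | 'rev'
    mean_q: float
    sequence: str  # + strand (reference orientation) substring
    origin: str  # 'cut' | 'background'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read must have start < end")

    def length(self) -> int:
        return self.end - self.start


DesignLike = Union[TilingDesign, Sequence[SimGuide]]


def design_guides(design: DesignLike) -> list[SimGuide]:
    """Flatten a tiling design (or pass through a SimGuide list)."""
    if isinstance(design, TilingDesign):
        return [
            SimGuide(g.name, g.candidate.cut_pos, g.candidate.strand, g.metrics.efficiency)
            for g in design.guides()
        ]
    return list(design)


def simulate_reads(
    ref: SequenceRecord, design: DesignLike, config: SimConfig = SimConfig()
) -> list[SimulatedRead]:
    """Draw cut-initiated (and rare background) reads for every molecule."""
    guides = design_guides(design)
    if not guides:
        raise ValueError("design contains no guides")
    length = len(ref.sequence)
    for g in guides:
        if not 0 <= g.cut_pos < length:
            raise ValueError(f"cut position of {g.name} outside the reference")

    rng = np.random.default_rng(config.seed)
    n_g = len(guides)
    occurred = rng.random((config.n_molecules, n_g)) < np.array(
        [g.efficiency for g in guides]
    )
    has_bg = rng.random(config.n_molecules) < config.background_rate
    reads: list[SimulatedRead] = []

    for m in range(config.n_molecules):
        cuts = sorted(guides[j].cut_pos for j in range(n_g) if occurred[m, j])
        for j in range(n_g):
            if not occurred[m, j]:
                continue
            g = guides[j]
            draw = int(round(rng.lognormal(config.read_length_log_mean, config.read_length_log_sd)))
            q = max(0.0, rng.normal(config.qscore_mean, config.qscore_sd))
            c = g.cut_pos
            if g.strand == "-":  # read runs rightwards from the cut
                i = bisect_right(cuts, c)
                next_cut = cuts[i] if i < len(cuts) else length
                start, end = c, min(c + max(draw, 1), next_cut, length)
                direction = "fwd"
            else:  # plus-strand guide: read runs leftwards
                i = bisect_left(cuts, c)
                prev_cut = cuts[i - 1] if i > 0 else 0
                start, end = max(c - max(draw, 1), prev_cut, 0), c
                direction = "rev"
            if start >= end:
                continue
            reads.append(
                SimulatedRead(
                    read_id=f"mol{m:05d}_{g.name}",
                    start=start,
                    end=end,
                    direction=direction,
                    mean_q=q,
                    sequence=ref.sequence[start:end],
                    origin="cut",
                )
            )
        if has_bg[m]:
            pos = int(rng.integers(0, length))
            direction = "fwd" if rng.random() < 0.5 else "rev"
            draw = int(round(rng.lognormal(config.read_length_log_mean, config.read_length_log_sd)))
            q = max(0.0, rng.normal(config.qscore_mean, config.qscore_sd))
            if direction == "fwd":
                i = bisect_right(cuts, pos)
                next_cut = cuts[i] if i < len(cuts) else length
                start, end = pos, min(pos + max(draw, 1), next_cut, length)
            else:
                i = bisect_left(cuts, pos)
                prev_cut = cuts[i - 1] if i > 0 else 0
                start, end = max(pos - max(draw, 1), prev_cut, 0), pos
            if start < end:
                reads.append(
                    SimulatedRead(
                        read_id=f"mol{m:05d}_bg",
                        start=start,
                        end=end,
                        direction=direction,
                        mean_q=q,
                        sequence=ref.sequence[start:end],
                        origin="background",
                    )
                )
    return reads


def apply_qscore_filter(
    reads: Iterable[SimulatedRead], qmin: float = 9.0
) -> list[SimulatedRead]:
    """Keep reads with mean Qscore >= qmin (boundary inclusive), order preserved."""
    return [r for r in reads if r.mean_q >= qmin]


def emit_fastq(
    reads: Iterable[SimulatedRead],
    ref: SequenceRecord,
    path: PathLike,
    seed: int = 0,
) -> None:
    """Write reads as FASTQ (Sanger encoding, flat per-read quality).

    Substitution errors are injected at the Phred rate 10^(-mean_q/10);
    reverse-direction reads are emitted as the reverse complement of the
    (error-injected) reference substring.
    """
    rng = np.random.default_rng(seed)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for r in reads:
            seq = r.sequence or ref.sequence[r.start : r.end]
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            err = rng.random(arr.size) < 10.0 ** (-r.mean_q / 10.0)
            n_err = int(err.sum())
            if n_err:
                # shift by 1..3 in base space: always a different base
                idx = np.nonzero(err)[0]
                cur = np.searchsorted(_BASES, arr[idx])
                arr[idx] = _BASES[(cur + rng.integers(1, 4, n_err)) % 4]
            seq = arr.tobytes().decode("ascii")
            if r.direction == "rev":
                seq = revcomp(seq)
            qchar = chr(33 + max(0, min(93, round(r.mean_q))))
            out.write(f"@{r.read_id}\n{seq}\n+\n{qchar * len(seq)}\n")


def emit_truth_alignments(reads: Iterable[SimulatedRead], path: PathLike) -> None:
    """BED-like truth table: read_id, start, end, direction, mean_q, origin."""
    with open(path, "w") as out:
        for r in reads:
            out.write(
                f"{r.read_id}\t{r.start}\t{r.end}\t{r.direction}"
                f"\t{r.mean_q:.3f}\t{r.origin}\n"
            )


def read_truth_alignments(path: PathLike) -> list[SimulatedRead]:
    """Parse the truth table back into (sequence-less) SimulatedRead records."""
    out: list[SimulatedRead] = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            rid, start, end, direction, q, origin = line.rstrip("\n").split("\t")
            out.append(
                SimulatedRead(rid, int(start), int(end), direction, float(q), "N", origin)
            )
    return out


def truth_intervals(
    reads: Iterable[SimulatedRead], seq_name: str
) -> list[GenomicRegion]:
    """Read footprints as regions on ``seq_name`` (for depth/QC)."""
    return [GenomicRegion(seq_name, r.start, r.end, r.read_id) for r in reads]
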