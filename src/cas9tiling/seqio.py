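"""Coordinate model and readers/writers for the plain-text formats the toolkit touches.

Conventions
-----------
All in-memory coordinates are 0-based, half-open (the BED convention).
Region strings ("chr1:68,423,822-68,454,954") and VCF positions are 1-based
as printed and are converted at this boundary, so the rest of the package
never reasons about off-by-one.

FASTA and FASTQ go through Biopython; the BED-like tables and the minimal
8-column VCF dialect used here are parsed directly because they are
deliberately headerless desk-scale files.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

from ._util import DNA_ALPHABET

PathLike = Union[str, Path]

_REGION_RE = re.compile(r"^(?P<name>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


class FormatError(ValueError):
    """Raised when an input file or coordinate string is malformed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open, 0-based interval on a named sequence."""

    seq_name: str
    start: int
    end: int
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise FormatError("region coordinates must be integers")
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid region {self.seq_name}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if the 0-based position lies inside the interval."""
        return self.start <= pos < self.end

    def intersects(self, other: "GenomicRegion") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"sequence record {self.name!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.name!r} contains non-DNA characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS layout of a single transcript, for variant classification.

    ``cds`` is the genomic span of the coding sequence; exonic bases outside
    it are UTR (which UTR depends on ``strand``).
    """

    region: GenomicRegion
    strand: str
    exons: tuple[GenomicRegion, ...]
    cds: GenomicRegion
    name: str = "tx"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"bad transcript strand {self.strand!r}")
        if not self.exons:
            raise FormatError("transcript needs at least one exon")
        prev_end = None
        for e in self.exons:
            if prev_end is not None and e.start < prev_end:
                raise FormatError("exons must be sorted and non-overlapping")
            prev_end = e.end
        span_start, span_end = self.exons[0].start, self.exons[-1].end
        if self.cds.start < span_start or self.cds.end > span_end:
            raise FormatError("CDS must lie within the exon span")

    @property
    def span(self) -> GenomicRegion:
        return GenomicRegion(
            self.region.seq_name, self.exons[0].start, self.exons[-1].end, self.name
        )

    def is_exonic(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)


@dataclass(frozen=True)
class VariantRecord:
    """Minimal site-level variant (VCF-style 1-based position)."""

    seq_name: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float] = None
    allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position {self.pos} must be >= 1")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise FormatError("REF and ALT must be non-empty and distinct")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.seq_name, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# region strings
# ---------------------------------------------------------------------------


def parse_region_string(text: str) -> GenomicRegion:
    """Parse a 1-based inclusive region string into a 0-based half-open region.

    Thousands separators are permitted: "chr1:68,423,822-68,454,954" spans
    31,133 bp.
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise FormatError(f"malformed region string {text!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1:
        raise FormatError(f"region coordinates must be positive in {text!r}")
    if start1 > end1:
        raise FormatError(f"region start exceeds end in {text!r}")
    return GenomicRegion(m.group("name"), start1 - 1, end1)


def format_region_string(region: GenomicRegion) -> str:
    """Inverse of :func:`parse_region_string` (no thousands separators)."""
    return f"{region.seq_name}:{region.start + 1}-{region.end}"


# ---------------------------------------------------------------------------
# file helpers
# ---------------------------------------------------------------------------


def _open_text(path: PathLike, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a (optionally gzipped) multi-record FASTA; sequences uppercased."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA record name {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: PathLike) -> list[GenomicRegion]:
    """Read BED3+ intervals (0-based half-open), label from column 4 if present."""
    regions: list[GenomicRegion] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = fields[3] if len(fields) > 3 else None
            try:
                regions.append(GenomicRegion(fields[0], start, end, label))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: PathLike) -> None:
    with _open_text(path, "wt") as out:
        for r in regions:
            cols = [r.seq_name, str(r.start), str(r.end)]
            if r.label is not None:
                cols.append(r.label)
            out.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# transcript table (BED6-like: exon/cds rows, strand in column 6)
# ---------------------------------------------------------------------------


def read_transcript_bed(path: PathLike, name: str = "tx") -> TranscriptModel:
    """Read an exon/CDS table: BED6 rows labelled ``exon`` or ``cds``.

    Column 4 carries the row kind, column 6 the transcript strand. Exactly one
    ``cds`` row is expected; exon rows must be sorted.
    """
    exons: list[GenomicRegion] = []
    cds: Optional[GenomicRegion] = None
    strand = "+"
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: transcript rows need >= 4 columns")
            region = GenomicRegion(fields[0], int(fields[1]), int(fields[2]), fields[3])
            if len(fields) >= 6 and fields[5] in {"+", "-"}:
                strand = fields[5]
            kind = fields[3].lower()
            if kind.startswith("exon"):
                exons.append(region)
            elif kind == "cds":
                if cds is not None:
                    raise FormatError(f"{path}:{lineno}: multiple cds rows")
                cds = region
            else:
                raise FormatError(f"{path}:{lineno}: unknown row kind {fields[3]!r}")
    if not exons or cds is None:
        raise FormatError(f"{path}: transcript table needs exon rows and one cds row")
    span = GenomicRegion(exons[0].seq_name, exons[0].start, exons[-1].end, name)
    return TranscriptModel(region=span, strand=strand, exons=tuple(exons), cds=cds, name=name)


def write_transcript_bed(model: TranscriptModel, path: PathLike) -> None:
    with _open_text(path, "wt") as out:
        for i, e in enumerate(model.exons, 1):
            out.write(
                "\t".join(
                    [e.seq_name, str(e.start), str(e.end), f"exon{i}", "0", model.strand]
                )
                + "\n"
            )
        c = model.cds
        out.write(
            "\t".join([c.seq_name, str(c.start), str(c.end), "cds", "0", model.strand])
            + "\n"
        )


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

_AF_RE = re.compile(r"(?:^|;)AF=([^;]+)")


def read_variant_table(path: PathLike) -> list[VariantRecord]:
    """Read a minimal VCF: '#' header lines skipped, 8 fixed columns required.

    QUAL '.' maps to None; AF is taken from the INFO ``AF=`` key when present.
    Genotype columns beyond INFO are ignored.
    """
    records: list[VariantRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"{path}:{lineno}: VCF data line needs 8 columns, got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt, qual_s, _filter, info = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric POS {pos_s!r}") from exc
            qual = None if qual_s == "." else float(qual_s)
            af = None
            m = _AF_RE.search(info)
            if m:
                af = float(m.group(1))
            try:
                records.append(
                    VariantRecord(chrom, pos, ref.upper(), alt.upper(), qual, af)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_variant_table(variants: Iterable[VariantRecord], path: PathLike) -> None:
    """Write records as a minimal VCF v4.2 (8 fixed columns, AF in INFO)."""
    with _open_text(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            qual = "." if v.qual is None else f"{v.qual:g}"
            info = "." if v.allele_frequency is None else f"AF={v.allele_frequency:g}"
            out.write(
                "\t".join(
                    [v.seq_name, str(v.pos), ".", v.ref, v.alt, qual, "PASS", info]
                )
                + "\n"
            )
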