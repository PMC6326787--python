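"""Read preprocessing: barcode demultiplexing, UMI extraction and
position+UMI de-duplication of aligned reads.

rNMP sequencing libraries carry a fixed molecular barcode (identifying
reads that genuinely derive from the ribonucleotide capture chemistry) and
a random unique molecular identifier (UMI, distinguishing biological
duplicates from PCR copies) at the 5' end of read 1, in UMI-then-barcode
order. Both are removed before alignment; the UMI travels in the read name
(suffix after the final ``_``) so it survives alignment, and aligned reads
sharing a 5' genomic position *and* a UMI are collapsed to one
representative. Reads at the same position with different UMIs are distinct
molecules and are all retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import GenomeIndex, InputError

__all__ = [
    "RawRead",
    "ReadStructure",
    "AlignedInterval",
    "DemuxReport",
    "DedupReport",
    "read_fastq",
    "write_fastq",
    "demultiplex",
    "extract_umi",
    "deduplicate",
    "load_sam_alignments",
    "load_bed_alignments",
    "write_bed_alignments",
]

logger = logging.getLogger(__name__)

UMI_SEPARATOR = "_"  # survives common aligners' read-name handling


@dataclass(frozen=True)
class RawRead:
    """One FASTQ record."""

    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise InputError(
                f"read {self.name!r}: sequence and quality lengths differ"
            )


@dataclass(frozen=True)
class ReadStructure:
    """5' layout of read 1: ``UMI (umi_length) + barcode + genomic insert``."""

    umi_length: int = 0
    barcode: str = ""

    def __post_init__(self) -> None:
        if self.umi_length < 0:
            raise InputError("umi_length must be non-negative")
        if set(self.barcode) - set("ACGT"):
            raise InputError(f"barcode {self.barcode!r} must be A/C/G/T")

    @property
    def prefix_length(self) -> int:
        return self.umi_length + len(self.barcode)


@dataclass(frozen=True)
class AlignedInterval:
    """One aligned read 1 as a zero-based half-open genomic interval.

    The 5' base of a ``+`` read sits at ``start``; the 5' base of a ``-``
    read sits at ``end - 1`` (the coordinate system counts from the 5' end
    of the forward strand, so a reverse read's 5' end is its highest
    coordinate).
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    umi: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise InputError(
                f"invalid interval [{self.start}, {self.end}) for {self.name!r}"
            )
        if self.strand not in "+-":
            raise InputError(f"strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Zero-based offset of the 5' (tagged) base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class DemuxReport:
    retained: int = 0
    discarded: int = 0
    too_short: int = 0

    @property
    def total(self) -> int:
        return self.retained + self.discarded + self.too_short


@dataclass
class DedupReport:
    reads_in: int = 0
    reads_out: int = 0
    groups: int = 0
    umi_missing: int = 0


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield RawRead(name=title.split()[0], sequence=seq, quality=qual)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.name}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Barcode retention / UMI extraction


def extract_umi(read: RawRead, structure: ReadStructure) -> RawRead:
    """Move the 5' UMI from the sequence into the read name.

    The name becomes ``<original>_<UMI>``; UMI characters (including any
    ``N``) are kept verbatim. With ``umi_length == 0`` the read is returned
    unchanged.
    """
    k = structure.umi_length
    if k == 0:
        return read
    if len(read.sequence) <= k:
        raise InputError(f"read {read.name!r} shorter than UMI length {k}")
    umi = read.sequence[:k]
    return RawRead(
        name=f"{read.name}{UMI_SEPARATOR}{umi}",
        sequence=read.sequence[k:],
        quality=read.quality[k:],
    )


def demultiplex(
    reads: Iterable[RawRead], structure: ReadStructure
) -> tuple[list[RawRead], DemuxReport]:
    """Retain reads carrying the barcode; strip UMI+barcode from retained reads.

    A read is retained iff the bases at offsets
    ``[umi_length, umi_length + len(barcode))`` equal the barcode exactly
    (zero mismatches). Retained reads come back with the barcode removed and
    the UMI moved into the read name. Reads shorter than the UMI+barcode
    prefix are discarded and counted separately.
    """
    kept: list[RawRead] = []
    report = DemuxReport()
    k = structure.umi_length
    barcode = structure.barcode
    for read in reads:
        if len(read.sequence) <= structure.prefix_length:
            report.too_short += 1
            continue
        if read.sequence[k : k + len(barcode)] != barcode:
            report.discarded += 1
            continue
        if barcode:
            read = RawRead(
                name=read.name,
                sequence=read.sequence[:k] + read.sequence[k + len(barcode) :],
                quality=read.quality[:k] + read.quality[k + len(barcode) :],
            )
        kept.append(extract_umi(read, structure))
        report.retained += 1
    return kept, report


# ---------------------------------------------------------------------------
# De-duplication


def umi_from_name(name: str) -> str:
    """Recover the UMI appended by :func:`extract_umi` (empty if none)."""
    if UMI_SEPARATOR not in name:
        return ""
    return name.rsplit(UMI_SEPARATOR, 1)[1]


def deduplicate(
    alignments: Iterable[AlignedInterval],
) -> tuple[list[AlignedInterval], DedupReport]:
    """Collapse PCR duplicates: one read per (chrom, strand, 5' position, UMI).

    Reads mapping to the same 5' position with the *same* UMI are copies of
    one molecule and collapse to a single representative — the
    lexicographically smallest read name, a deterministic tie-break. Reads
    at the same position with *different* UMIs are distinct molecules and
    all survive. UMI matching is exact (no edit-distance clustering). With
    empty UMIs the grouping is positional only, which over-collapses
    libraries that used PCR; a warning is logged.
    """
    groups: dict[tuple[str, str, int, str], AlignedInterval] = {}
    report = DedupReport()
    for aln in alignments:
        report.reads_in += 1
        if aln.umi == "":
            report.umi_missing += 1
        key = (aln.chrom, aln.strand, aln.five_prime, aln.umi)
        best = groups.get(key)
        if best is None or aln.name < best.name:
            groups[key] = aln
    if report.umi_missing:
        logger.warning(
            "%d/%d alignments carry no UMI; de-duplication is positional only",
            report.umi_missing,
            report.reads_in,
        )
    kept = list(groups.values())
    report.reads_out = len(kept)
    report.groups = len(groups)
    return kept, report


# ---------------------------------------------------------------------------
# Alignment ingestion (SAM/BAM and BED)


def load_sam_alignments(
    path: str | Path,
    genome: GenomeIndex | None = None,
    min_mapq: int = 0,
) -> list[AlignedInterval]:
    """Read aligned read-1 intervals from SAM/BAM.

    Unmapped, secondary and supplementary records and read 2 of a pair are
    skipped (only read 1 carries the tagged nucleotide); records below
    ``min_mapq`` are skipped. The UMI is recovered from the query-name
    suffix after the final ``_``.
    """
    intervals: list[AlignedInterval] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_paired and rec.is_read2:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if genome is not None and chrom not in genome:
                raise InputError(
                    f"alignment references unknown chromosome {chrom!r}"
                )
            name = rec.query_name
            intervals.append(
                AlignedInterval(
                    chrom=chrom,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    name=name,
                    umi=umi_from_name(name),
                )
            )
    return intervals


def load_bed_alignments(
    path: str | Path, genome: GenomeIndex | None = None
) -> list[AlignedInterval]:
    """Read aligned intervals from a BED6 file (zero-based half-open)."""
    intervals: list[AlignedInterval] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InputError(
                    f"{path}:{line_no}: BED6 requires 6 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if genome is not None and chrom not in genome:
                raise InputError(
                    f"alignment references unknown chromosome {chrom!r}"
                )
            intervals.append(
                AlignedInterval(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    name=name,
                    umi=umi_from_name(name),
                )
            )
    return intervals


def write_bed_alignments(
    alignments: Iterable[AlignedInterval], path: str | Path
) -> int:
    """Write alignments as BED6 (score column 0).

    A non-empty UMI is carried in the name column as the ``_<UMI>`` suffix
    (unless already present), so :func:`load_bed_alignments` recovers it.
    """
    n = 0
    with open(path, "w") as handle:
        for aln in alignments:
            name = aln.name
            if aln.umi and not name.endswith(f"{UMI_SEPARATOR}{aln.umi}"):
                name = f"{name}{UMI_SEPARATOR}{aln.umi}"
            handle.write(
                f"{aln.chrom}\t{aln.start}\t{aln.end}\t{name}\t0\t{aln.strand}\n"
            )
            n += 1
    return n
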