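"""Single-nucleotide rNMP coordinates from aligned read-1 intervals.

Each rNMP sequencing technique tags the embedded ribonucleotide at a fixed
offset and strand relative to the 5'-most base of read 1 (the *tagged
nucleotide*):

========================  =======================  =======================
technique                 rNMP on forward strand   rNMP on reverse strand
                          (from a ``-`` read)      (from a ``+`` read)
========================  =======================  =======================
ribose-seq                [end-1, end)             [start, start+1)
HydEn-seq / Pu-seq        [start-1, start)*        [end, end+1)*
emRiboSeq                 [end, end+1)             [start-1, start)
========================  =======================  =======================

(*) HydEn-seq/Pu-seq place forward-strand rNMPs one base upstream of a
``+`` read's start and reverse-strand rNMPs one base past a ``-`` read's
end; they share one code path because their chemistry (alkaline hydrolysis
3' of the rNMP) is positionally identical. All intervals are zero-based
half-open (BED convention); SAM's 1-based positions are converted once at
ingestion and never again.

For HydEn-seq, Pu-seq and emRiboSeq the arithmetic can step off the
chromosome when a read aligns at a 5'-most end, producing a biologically
meaningless coordinate such as start ``-1``. Those sites must be screened
out before export; ribose-seq sites always fall inside the read's own
footprint and can never be rejected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import ConfigurationError, GenomeIndex, InputError
from .preprocess import (
    AlignedInterval,
    load_bed_alignments,
    load_sam_alignments,
)

__all__ = [
    "Technique",
    "RnmpSite",
    "SiteTable",
    "alignments_to_intervals",
    "calc_site",
    "screen_site",
    "screen_sites",
    "count_sites",
    "write_site_bed",
    "write_counts_tsv",
    "write_rejection_log",
    "load_site_table",
]


class Technique(enum.Enum):
    """The four supported rNMP sequencing techniques."""

    RIBOSE_SEQ = "ribose-seq"
    HYDEN_SEQ = "HydEn-seq"
    PU_SEQ = "Pu-seq"
    EMRIBOSE_SEQ = "emRiboSeq"

    @classmethod
    def parse(cls, value: "str | Technique") -> "Technique":
        """Case-insensitive parse, tolerant of hyphen/underscore variants."""
        if isinstance(value, cls):
            return value
        key = str(value).lower().replace("-", "").replace("_", "")
        table = {
            "riboseseq": cls.RIBOSE_SEQ,
            "hydenseq": cls.HYDEN_SEQ,
            "puseq": cls.PU_SEQ,
            "emriboseq": cls.EMRIBOSE_SEQ,
        }
        if key not in table:
            valid = ", ".join(t.value for t in cls)
            raise ConfigurationError(
                f"unknown technique {value!r}; valid names: {valid}"
            )
        return table[key]


@dataclass(frozen=True)
class RnmpSite:
    """A single-nucleotide rNMP site (zero-based half-open, end==start+1).

    ``strand`` is the strand of the DNA molecule carrying the embedded
    ribonucleotide, which for three of the four techniques is the opposite
    of the read strand. ``start`` may be negative, and ``end`` may exceed
    the chromosome length, until the site passes screening.
    """

    chrom: str
    start: int
    strand: str
    read_name: str = "."

    @property
    def end(self) -> int:
        return self.start + 1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


def alignments_to_intervals(
    alignment_path: str | Path,
    genome: GenomeIndex | None = None,
    min_mapq: int = 0,
) -> list[AlignedInterval]:
    """Load read-1 alignments from SAM/BAM or BED6 into zero-based intervals.

    SAM records are converted from 1-based inclusive to zero-based
    half-open here, once; BED input passes through unchanged.
    """
    suffix = Path(alignment_path).suffix.lower()
    if suffix in {".sam", ".bam"}:
        return load_sam_alignments(alignment_path, genome, min_mapq)
    return load_bed_alignments(alignment_path, genome)


def calc_site(read: AlignedInterval, technique: Technique | str) -> RnmpSite:
    """Apply the technique's genomic arithmetic to one aligned read.

    The output is *unscreened*: it may lie outside the chromosome and must
    pass :func:`screen_site` before being written anywhere.
    """
    technique = Technique.parse(technique)
    if technique is Technique.RIBOSE_SEQ:
        # rNMP is the reverse complement of the tagged nucleotide.
        if read.strand == "+":
            return RnmpSite(read.chrom, read.start, "-", read.name)
        return RnmpSite(read.chrom, read.end - 1, "+", read.name)
    if technique in (Technique.HYDEN_SEQ, Technique.PU_SEQ):
        # rNMP is one nucleotide upstream of the tagged nucleotide.
        if read.strand == "+":
            return RnmpSite(read.chrom, read.start - 1, "+", read.name)
        return RnmpSite(read.chrom, read.end, "-", read.name)
    # emRiboSeq: one nucleotide downstream of the tagged base's reverse
    # complement.
    if read.strand == "+":
        return RnmpSite(read.chrom, read.start - 1, "-", read.name)
    return RnmpSite(read.chrom, read.end, "+", read.name)


def screen_site(site: RnmpSite, genome: GenomeIndex) -> bool:
    """Biological-relevance screen: the site must lie on the chromosome.

    Accept iff ``0 <= start`` and ``end <= chromosome length``. Off-end
    coordinates arise only from reads aligned at a chromosome's 5'-most
    positions under the HydEn-seq/Pu-seq/emRiboSeq arithmetic and would
    break any downstream per-position analysis.
    """
    return site.start >= 0 and site.end <= genome.length(site.chrom)


def screen_sites(
    sites: Iterable[RnmpSite], genome: GenomeIndex
) -> tuple[list[RnmpSite], list[RnmpSite]]:
    """Partition sites into (accepted, rejected); rejects keep read names."""
    accepted: list[RnmpSite] = []
    rejected: list[RnmpSite] = []
    for site in sites:
        (accepted if screen_site(site, genome) else rejected).append(site)
    return accepted, rejected


@dataclass
class SiteTable:
    """Unique rNMP sites with raw and per-hundred-normalized counts.

    ``frame`` columns: chrom, start, end, strand, raw, normalized. Rows are
    sorted by (reference chromosome order, start, strand); ``normalized``
    is ``raw / library_total * 100`` so it sums to 100 over a non-empty
    table and is comparable across libraries of different depth.
    """

    frame: pd.DataFrame

    COLUMNS = ("chrom", "start", "end", "strand", "raw", "normalized")

    @property
    def total(self) -> int:
        return int(self.frame["raw"].sum())

    def __len__(self) -> int:
        return len(self.frame)

    def restrict(self, chroms: Sequence[str]) -> "SiteTable":
        """Rows on the given chromosomes; normalization is left untouched."""
        sub = self.frame[self.frame["chrom"].isin(set(chroms))]
        return SiteTable(frame=sub.reset_index(drop=True))


def count_sites(
    sites: Sequence[RnmpSite], genome: GenomeIndex | None = None
) -> SiteTable:
    """Tabulate screened sites into per-site raw and normalized counts.

    ``raw`` is the site's multiplicity among the de-duplicated, screened
    reads; ``normalized`` divides by the library total and scales to 100.
    Chromosomes sort in reference order when a genome is given, else
    lexicographically.
    """
    if not sites:
        return SiteTable(
            frame=pd.DataFrame(columns=list(SiteTable.COLUMNS)).astype(
                {"start": int, "end": int, "raw": int, "normalized": float}
            )
        )
    counts: dict[tuple[str, int, str], int] = {}
    for site in sites:
        counts[site.key] = counts.get(site.key, 0) + 1
    rank = genome.chrom_rank() if genome is not None else None
    keys = sorted(
        counts,
        key=lambda k: ((rank[k[0]] if rank else k[0]), k[1], k[2]),
    )
    total = sum(counts.values())
    frame = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "start": [k[1] for k in keys],
            "end": [k[1] + 1 for k in keys],
            "strand": [k[2] for k in keys],
            "raw": [counts[k] for k in keys],
            "normalized": [counts[k] / total * 100.0 for k in keys],
        }
    )
    return SiteTable(frame=frame)


# ---------------------------------------------------------------------------
# Export


def write_site_bed(table: SiteTable, path: str | Path) -> int:
    """BED6 per unique site; the score column carries the raw count."""
    with open(path, "w") as handle:
        for row in table.frame.itertuples(index=False):
            handle.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t.\t{row.raw}\t{row.strand}\n"
            )
    return len(table)


def write_counts_tsv(table: SiteTable, path: str | Path) -> None:
    """TSV with header chrom/start/end/strand/raw/normalized."""
    out = table.frame.copy()
    out["normalized"] = out["normalized"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def write_rejection_log(rejected: Sequence[RnmpSite], path: str | Path) -> None:
    """TSV of screened-out sites with their originating read names."""
    with open(path, "w") as handle:
        handle.write("chrom\tstart\tend\tstrand\tread_name\n")
        for site in rejected:
            handle.write(
                f"{site.chrom}\t{site.start}\t{site.end}\t{site.strand}"
                f"\t{site.read_name}\n"
            )


def load_site_table(path: str | Path) -> SiteTable:
    """Read back a counts TSV written by :func:`write_counts_tsv`."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(SiteTable.COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return SiteTable(frame=frame)
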