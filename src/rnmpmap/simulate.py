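"""Synthetic data: reference genomes, planted rNMP truth sets and
technique-faithful reads.

The simulator is the exact inverse of the coordinate arithmetic: given a
planted ribonucleotide at zero-based position ``p`` on the ``+`` strand and
read length ``L``, it places read 1 where the technique's chemistry would
put it —

* ribose-seq: ``-`` strand read over ``[p+1-L, p+1)`` (the rNMP is the
  reverse complement of the 5' tagged base),
* HydEn-seq / Pu-seq: ``+`` strand read over ``[p+1, p+1+L)`` (the rNMP is
  one base upstream of the tagged base),
* emRiboSeq: ``-`` strand read over ``[p-L, p)`` (the rNMP is one base
  downstream of the tagged base's reverse complement),

with ``-`` strand sites handled as the strand mirror. Running the
coordinate calculation on simulated alignments therefore recovers the
planted (chrom, pos, strand) set exactly, which makes every downstream
stage testable without sequencing data or an aligner.

Reads are error-free: the mapping logic under test is positional, so base
call errors would only exercise the (external) aligner. Reads carry the
UMI-then-barcode 5' structure and can be PCR-duplicated verbatim to
exercise de-duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coordinate import Technique
from .genome import COMPLEMENT, GenomeIndex, InputError
from .preprocess import AlignedInterval, RawRead, umi_from_name

__all__ = [
    "TruthSite",
    "SimSpec",
    "generate_reference",
    "write_fasta",
    "plant_rnmps",
    "simulate_alignments",
    "end_aligned_alignments",
    "apply_pcr_duplicates",
    "emit_fastq",
    "write_truth_bed",
    "perfect_align",
]

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])

RNA_OF_DNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


@dataclass(frozen=True)
class TruthSite:
    """A planted rNMP: position, strand, and ribonucleotide identity.

    ``base`` is in the RNA alphabet {A, C, G, U}, read 5'→3' on the site's
    own strand, so a ``+`` strand site over reference T (or a ``-`` strand
    site over reference A) is rU.
    """

    chrom: str
    pos: int
    strand: str
    base: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class SimSpec:
    """Simulation parameters for one synthetic library."""

    technique: Technique | str
    read_length: int = 50
    barcode: str = ""
    umi_length: int = 0
    duplication_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise InputError("read_length must be >= 1")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise InputError("duplication_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# Reference generation


def generate_reference(
    chrom_specs: Sequence[tuple[str, int, str, float]],
    seed: int,
    fasta_path: str | Path | None = None,
) -> GenomeIndex:
    """Generate a random reference genome.

    ``chrom_specs`` is a list of ``(name, length, organelle, gc_fraction)``.
    Bases are drawn i.i.d.: G/C each with probability ``gc/2``, A/T each
    with ``(1-gc)/2``, so the realized GC content concentrates around the
    request (binomial, within a few tenths of a percent at 100 kb). Output
    is reproducible for a fixed seed; a FASTA copy is written when
    ``fasta_path`` is given.
    """
    names = [spec[0] for spec in chrom_specs]
    if len(set(names)) != len(names):
        raise InputError("duplicate chromosome names in chrom_specs")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    organelle_of: dict[str, str] = {}
    for name, length, organelle, gc in chrom_specs:
        if length < 1:
            raise InputError(f"chromosome {name!r}: length must be >= 1")
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        sequences[name] = "".join(rng.choice(BASES, size=length, p=p))
        organelle_of[name] = organelle
    genome = GenomeIndex(
        names=names, sequences=sequences, organelle_of=organelle_of
    )
    if fasta_path is not None:
        write_fasta(genome, fasta_path)
    return genome


def write_fasta(
    genome: GenomeIndex, path: str | Path, line_width: int = 70
) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.iter_records():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Truth sets


def plant_rnmps(
    genome: GenomeIndex,
    n: int,
    seed: int,
    base_bias: Mapping[str, float] | None = None,
) -> list[TruthSite]:
    """Plant ``n`` rNMP sites sampled without replacement over
    (chromosome, position, strand).

    Each site's base is the reference base read on the site's strand, with
    T reported as U (the rNMP is a ribonucleotide). ``base_bias`` maps RNA
    bases {A, C, G, U} to relative weights; candidate sites are then
    rejection-filtered — a uniformly drawn site with base ``b`` is accepted
    with probability ``w[b]/max(w)`` — which reproduces incorporation
    signatures such as an rCMP excess.
    """
    if n < 0:
        raise InputError("n must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = [genome.length(c) for c in genome.names]
    total = 2 * sum(lengths)  # both strands
    if n > total:
        raise InputError(f"cannot plant {n} sites in {total} positions")
    offsets = np.cumsum([0] + lengths)

    def decode(flat: int) -> TruthSite:
        strand = "+" if flat < total // 2 else "-"
        flat = flat % (total // 2)
        ci = int(np.searchsorted(offsets, flat, side="right")) - 1
        chrom = genome.names[ci]
        pos = int(flat - offsets[ci])
        ref = genome.sequence(chrom)[pos]
        base = ref if strand == "+" else COMPLEMENT[ref]
        return TruthSite(chrom, pos, strand, RNA_OF_DNA.get(base, "N"))

    order = rng.permutation(total)
    if base_bias is None:
        chosen = [decode(int(i)) for i in order[:n]]
    else:
        weights = {b: float(base_bias.get(b, 0.0)) for b in "ACGU"}
        wmax = max(weights.values())
        if wmax <= 0:
            raise InputError("base_bias weights must include a positive value")
        chosen = []
        for flat in order:
            site = decode(int(flat))
            w = weights.get(site.base, 0.0)
            if w > 0 and rng.random() < w / wmax:
                chosen.append(site)
                if len(chosen) == n:
                    break
        if len(chosen) < n:
            raise InputError(
                f"only {len(chosen)} positions matched base_bias; requested {n}"
            )
    return chosen


# ---------------------------------------------------------------------------
# Read placement (inverse of the coordinate arithmetic)


def _read_placement(
    site: TruthSite, technique: Technique, read_length: int
) -> tuple[int, int, str]:
    """(start, end, read strand) for the read tagging ``site``; unclipped."""
    p, L = site.pos, read_length
    if technique is Technique.RIBOSE_SEQ:
        if site.strand == "+":
            return p + 1 - L, p + 1, "-"
        return p, p + L, "+"
    if technique in (Technique.HYDEN_SEQ, Technique.PU_SEQ):
        if site.strand == "+":
            return p + 1, p + 1 + L, "+"
        return p - L, p, "-"
    # emRiboSeq
    if site.strand == "+":
        return p - L, p, "-"
    return p + 1, p + 1 + L, "+"


def simulate_alignments(
    truth: Sequence[TruthSite],
    spec: SimSpec,
    genome: GenomeIndex,
) -> tuple[list[AlignedInterval], list[TruthSite], list[TruthSite]]:
    """Place one error-free read-1 alignment per planted site.

    Returns ``(alignments, kept_truth, skipped_truth)``: sites whose read
    would overhang a chromosome end cannot be simulated at this read length
    and are skipped (and logged); the round-trip guarantee applies to
    ``kept_truth``. Each alignment receives a deterministic name and, when
    ``spec.umi_length > 0``, a random UMI drawn from ``spec.seed``.
    """
    technique = Technique.parse(spec.technique)
    rng = np.random.default_rng(spec.seed)
    alignments: list[AlignedInterval] = []
    kept: list[TruthSite] = []
    skipped: list[TruthSite] = []
    for i, site in enumerate(truth):
        start, end, strand = _read_placement(site, technique, spec.read_length)
        if start < 0 or end > genome.length(site.chrom):
            skipped.append(site)
            continue
        umi = (
            "".join(rng.choice(BASES, size=spec.umi_length))
            if spec.umi_length
            else ""
        )
        alignments.append(
            AlignedInterval(
                chrom=site.chrom,
                start=start,
                end=end,
                strand=strand,
                name=f"sim{i:06d}",
                umi=umi,
            )
        )
        kept.append(site)
    if skipped:
        logger.info(
            "skipped %d/%d truth sites whose read would overhang a "
            "chromosome end",
            len(skipped),
            len(truth),
        )
    return alignments, kept, skipped


def end_aligned_alignments(
    genome: GenomeIndex,
    read_length: int,
    forward_chrom: str,
    reverse_chrom: str,
) -> list[AlignedInterval]:
    """Two reads aligned to chromosome 5'-most ends.

    One ``+`` read occupies ``[0, L)`` of ``forward_chrom`` (5'-most end of
    the forward strand) and one ``-`` read occupies ``[len-L, len)`` of
    ``reverse_chrom`` (5'-most end of the reverse strand). Under the
    HydEn-seq/Pu-seq/emRiboSeq arithmetic both imply rNMP coordinates off
    the chromosome, so both must be rejected by the biological-relevance
    screen; no planted truth site corresponds to them.
    """
    L = read_length
    rev_len = genome.length(reverse_chrom)
    if L > genome.length(forward_chrom) or L > rev_len:
        raise InputError("read_length exceeds a chromosome length")
    return [
        AlignedInterval(forward_chrom, 0, L, "+", name="end_fwd"),
        AlignedInterval(reverse_chrom, rev_len - L, rev_len, "-", name="end_rev"),
    ]


# ---------------------------------------------------------------------------
# PCR duplication and FASTQ emission


def apply_pcr_duplicates(
    alignments: Sequence[AlignedInterval], rate: float, seed: int
) -> list[AlignedInterval]:
    """Duplicate each alignment verbatim with probability ``rate``.

    PCR copies keep the read's UMI and position (they are copies of the
    same molecule), which is exactly the signal de-duplication keys on.
    """
    rng = np.random.default_rng(seed)
    out: list[AlignedInterval] = []
    for aln in alignments:
        out.append(aln)
        if rate > 0 and rng.random() < rate:
            out.append(aln)
    return out


def read_sequence(aln: AlignedInterval, genome: GenomeIndex) -> str:
    """Genomic sequence of the interval read 5'→3' on the alignment strand."""
    seq = genome.sequence(aln.chrom)[aln.start : aln.end]
    if aln.strand == "-":
        seq = "".join(COMPLEMENT[b] for b in reversed(seq))
    return seq


def emit_fastq(
    alignments: Sequence[AlignedInterval],
    spec: SimSpec,
    genome: GenomeIndex,
    seed: int,
    fastq_path: str | Path,
) -> int:
    """Write simulated reads as Phred+33 FASTQ (constant quality ``I``).

    Each record is ``UMI + barcode + genomic insert``; with probability
    ``spec.duplication_rate`` a record is emitted again verbatim (same name,
    same UMI, same insert) to emulate a PCR copy. Byte-identical for a
    fixed seed. Returns the number of records written.
    """
    rng = np.random.default_rng(seed)
    n = 0
    with open(fastq_path, "w") as handle:
        for aln in alignments:
            insert = read_sequence(aln, genome)
            full = aln.umi + spec.barcode + insert
            record = f"@{aln.name}\n{full}\n+\n{'I' * len(full)}\n"
            handle.write(record)
            n += 1
            if spec.duplication_rate > 0 and rng.random() < spec.duplication_rate:
                handle.write(record)
                n += 1
    return n


def write_truth_bed(truth: Sequence[TruthSite], path: str | Path) -> int:
    """BED6 of planted sites (name ``.``, score 1), one line per site."""
    with open(path, "w") as handle:
        for site in truth:
            handle.write(
                f"{site.chrom}\t{site.pos}\t{site.pos + 1}\t.\t1\t{site.strand}\n"
            )
    return len(truth)


def perfect_align(
    reads: Iterable[RawRead],
    alignments: Sequence[AlignedInterval],
) -> list[AlignedInterval]:
    """Map preprocessed simulated reads back to their known placements.

    A perfect-placement aligner for simulator output: each read is looked
    up by its original simulated name (the part of the FASTQ name before
    the UMI suffix) in the simulated alignment list, and the UMI extracted
    during preprocessing is attached. External alignment software is never
    involved, so the test surface stays self-contained.
    """
    by_name = {aln.name: aln for aln in alignments}
    placed: list[AlignedInterval] = []
    for read in reads:
        umi = umi_from_name(read.name)
        base = read.name.rsplit("_", 1)[0] if umi else read.name
        if base not in by_name:
            raise InputError(f"read {read.name!r} has no simulated placement")
        placed.append(replace(by_name[base], name=read.name, umi=umi))
    return placed
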