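"""Reference genome access: loading, indexing, organelle grouping and
background base composition.

Every chromosome of the reference carries an organelle label (``nuclear`` or
``mitochondrial``) because downstream sequence-context analysis is split by
compartment: the base composition, and the sequence context of embedded
ribonucleotides, differ between the nuclear and mitochondrial genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "ORGANELLE_LABELS",
    "COMPLEMENT",
    "GenomeIndex",
    "BaseFrequencies",
    "load_reference",
    "base_at",
    "background_frequencies",
]

ORGANELLE_LABELS = ("nuclear", "mitochondrial")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

BASES = ("A", "C", "G", "T")


class ConfigurationError(ValueError):
    """Raised when run configuration is inconsistent with the inputs."""


class InputError(ValueError):
    """Raised when an input file or value violates a precondition."""


@dataclass(frozen=True)
class BaseFrequencies:
    """Mononucleotide proportions of a genome compartment.

    Proportions are pooled over both strands, so they are complement
    symmetric by construction (``freq['A'] == freq['T']`` and
    ``freq['C'] == freq['G']``). ``N`` bases are excluded from both the
    numerator and the denominator.
    """

    freq: Mapping[str, float]

    def __getitem__(self, base: str) -> float:
        return self.freq[base]


@dataclass
class GenomeIndex:
    """An in-memory reference genome with per-chromosome organelle labels.

    Chromosome order is the FASTA record order and is preserved in every
    downstream table and track. Sequences are upper-case A/C/G/T/N.
    """

    names: list[str]
    sequences: dict[str, str]
    organelle_of: dict[str, str]
    _bg_cache: dict[str, BaseFrequencies] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise InputError("duplicate chromosome names in reference")
        for name in self.names:
            if name not in self.organelle_of:
                raise ConfigurationError(
                    f"chromosome {name!r} has no organelle label"
                )
            label = self.organelle_of[name]
            if label not in ORGANELLE_LABELS:
                raise ConfigurationError(
                    f"organelle label for {name!r} must be one of "
                    f"{ORGANELLE_LABELS}, got {label!r}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        self._require(chrom)
        return len(self.sequences[chrom])

    def sequence(self, chrom: str) -> str:
        self._require(chrom)
        return self.sequences[chrom]

    def chromosomes(self, organelle: str | None = None) -> list[str]:
        """Chromosome names in reference order, optionally one organelle."""
        if organelle is None:
            return list(self.names)
        return [n for n in self.names if self.organelle_of[n] == organelle]

    def chrom_rank(self) -> dict[str, int]:
        """Reference order of chromosomes, for deterministic sorting."""
        return {name: i for i, name in enumerate(self.names)}

    def _require(self, chrom: str) -> None:
        if chrom not in self.sequences:
            raise InputError(f"unknown chromosome {chrom!r}")

    def iter_records(self) -> Iterator[tuple[str, str]]:
        for name in self.names:
            yield name, self.sequences[name]


def load_reference(
    fasta_path: str | Path, organelles: Mapping[str, str] | str | Path
) -> GenomeIndex:
    """Load a FASTA reference and attach organelle labels.

    Parameters
    ----------
    fasta_path:
        Multi-record FASTA; wrapped or unwrapped lines.
    organelles:
        Mapping of chromosome name to ``nuclear``/``mitochondrial``, or a
        path to a YAML/``name: label`` text file with one pair per line.

    Every chromosome in the FASTA must be labelled; sequences are
    upper-cased on load.
    """
    if not isinstance(organelles, Mapping):
        organelles = _read_organelle_file(organelles)
    names: list[str] = []
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        names.append(record.id)
        sequences[record.id] = str(record.seq).upper()
    if not names:
        raise InputError(f"no FASTA records found in {fasta_path}")
    missing = [n for n in names if n not in organelles]
    if missing:
        raise ConfigurationError(
            "missing organelle label for chromosome(s): " + ", ".join(missing)
        )
    return GenomeIndex(
        names=names,
        sequences=sequences,
        organelle_of={n: organelles[n] for n in names},
    )


def _read_organelle_file(path: str | Path) -> dict[str, str]:
    import yaml

    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ConfigurationError(
            f"organelle file {path} must contain 'chromosome: label' pairs"
        )
    return {str(k): str(v) for k, v in data.items()}


def base_at(genome: GenomeIndex, chrom: str, pos: int, strand: str) -> str | None:
    """Base at a zero-based offset, read on the requested strand.

    On ``+`` this is the reference base itself; on ``-`` its complement.
    Positions outside ``[0, length)`` return ``None`` rather than raising,
    so window extraction near chromosome ends can mark positions absent.
    """
    seq = genome.sequence(chrom)
    if pos < 0 or pos >= len(seq):
        return None
    base = seq[pos]
    return base if strand == "+" else COMPLEMENT[base]


def background_frequencies(genome: GenomeIndex, organelle: str) -> BaseFrequencies:
    """Base composition of one organelle compartment, pooled over strands.

    Embedded ribonucleotides occur on either strand and are always reported
    5'→3' on their own strand, so the matching background is the two-strand
    pool: freq(A) = (#A + #T) / 2N and likewise for C/G, where N counts the
    non-``N`` bases of the forward sequence.
    """
    if organelle in genome._bg_cache:
        return genome._bg_cache[organelle]
    chroms = genome.chromosomes(organelle)
    if not chroms:
        raise InputError(f"no chromosome labelled {organelle!r}")
    counts = {b: 0 for b in BASES}
    for chrom in chroms:
        seq = genome.sequence(chrom)
        for b in BASES:
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        raise InputError(f"organelle {organelle!r} contains no A/C/G/T bases")
    freq = {
        "A": (counts["A"] + counts["T"]) / (2 * total),
        "T": (counts["A"] + counts["T"]) / (2 * total),
        "C": (counts["C"] + counts["G"]) / (2 * total),
        "G": (counts["C"] + counts["G"]) / (2 * total),
    }
    result = BaseFrequencies(freq=freq)
    genome._bg_cache[organelle] = result
    return result
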