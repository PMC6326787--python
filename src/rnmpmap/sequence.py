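"""Nucleotide sequence context of rNMP sites.

For every unique site the surrounding window is read 5'→3' on the
rNMP-bearing strand (reverse complement orientation for ``-`` strand
sites), so relative position 0 is the ribonucleotide itself, negative
positions are upstream and positive positions downstream on that strand.
Per-position base frequencies are normalized to the background composition
of the matching organelle compartment: a normalized frequency of 1 means
"no different from the genome", an excess above 1 flags an incorporation
or context bias (e.g. an rCMP preference shows as C > 1 at position 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coordinate import SiteTable
from .genome import GenomeIndex, InputError, base_at, background_frequencies

__all__ = [
    "FrequencyMatrix",
    "oriented_window",
    "profile",
    "write_profile_tsv",
    "plot_profile",
]

DNA_BASES = ("A", "C", "G", "T")
RNA_BASES = ("A", "C", "G", "U")

#: default window half-widths: a wide view and a zoomed-in view
DEFAULT_WINDOWS = (100, 15)


@dataclass
class FrequencyMatrix:
    """Per-relative-position base frequencies around rNMP sites.

    ``counts`` holds the (possibly count-weighted) base tallies per
    relative position; ``raw`` the per-position frequencies (rows sum to 1
    over counted bases; positions with zero coverage are all-NaN, i.e.
    absent rather than zero); ``normalized`` divides each raw frequency by
    the organelle background frequency of that base, with T and U
    identified. ``totals`` is the effective (weighted) number of sites
    contributing at each position — sites whose window is truncated at a
    chromosome end do not contribute to the truncated positions.
    """

    counts: pd.DataFrame  # index: relative position; columns: A/C/G/T
    totals: pd.Series
    raw: pd.DataFrame
    normalized: pd.DataFrame
    organelle: str
    half_width: int
    rnmp_filter: str | None = None
    n_sites: int = 0

    @property
    def positions(self) -> np.ndarray:
        return self.counts.index.to_numpy()


def oriented_window(
    site_chrom: str,
    site_pos: int,
    site_strand: str,
    genome: GenomeIndex,
    w: int,
) -> list[str | None]:
    """Bases at relative positions ``-w..+w`` around a site, 5'→3' on the
    site's strand.

    For a ``+`` site at ``p`` relative position ``i`` is the reference base
    at ``p+i``; for a ``-`` site it is the complement of the base at
    ``p-i``. Out-of-range positions are ``None`` (absent).
    """
    if site_strand == "+":
        return [base_at(genome, site_chrom, site_pos + i, "+") for i in range(-w, w + 1)]
    return [base_at(genome, site_chrom, site_pos - i, "-") for i in range(-w, w + 1)]


def _site_rna_base(
    chrom: str, pos: int, strand: str, genome: GenomeIndex
) -> str | None:
    base = base_at(genome, chrom, pos, strand)
    if base is None or base == "N":
        return None
    return "U" if base == "T" else base


def profile(
    sites: SiteTable,
    genome: GenomeIndex,
    organelle: str,
    w: int,
    rnmp_filter: str | None = None,
    weight_by_count: bool = True,
) -> FrequencyMatrix:
    """Background-normalized base frequencies at and around rNMP sites.

    Only sites on chromosomes of the requested organelle contribute. Each
    site contributes its raw count at every in-range window position
    (``weight_by_count=False`` switches to unique-site weighting). With
    ``rnmp_filter`` in {A, C, G, U} only sites whose position-0
    ribonucleotide matches are kept, giving per-rNMP-type profiles whose
    count-weighted average recombines to the unfiltered profile. An empty
    selection yields an all-absent matrix (warning-level situation, not an
    error).
    """
    if rnmp_filter is not None and rnmp_filter not in RNA_BASES:
        raise InputError(f"rnmp_filter must be one of {RNA_BASES}")
    chroms = genome.chromosomes(organelle)
    table = sites.restrict(chroms)
    positions = np.arange(-w, w + 1)
    base_index = {b: j for j, b in enumerate(DNA_BASES)}
    counts = np.zeros((len(positions), 4), dtype=float)
    totals = np.zeros(len(positions), dtype=float)
    n_sites = 0
    for row in table.frame.itertuples(index=False):
        rna = _site_rna_base(row.chrom, row.start, row.strand, genome)
        if rnmp_filter is not None and rna != rnmp_filter:
            continue
        weight = float(row.raw) if weight_by_count else 1.0
        n_sites += 1
        window = oriented_window(row.chrom, row.start, row.strand, genome, w)
        for i, base in enumerate(window):
            if base is None or base == "N":
                continue
            counts[i, base_index[base]] += weight
            totals[i] += weight
    counts_df = pd.DataFrame(counts, index=positions, columns=list(DNA_BASES))
    totals_s = pd.Series(totals, index=positions)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = counts_df.div(totals_s.replace(0.0, np.nan), axis=0)
    background = background_frequencies(genome, organelle)
    normalized = raw.copy()
    for b in DNA_BASES:
        normalized[b] = raw[b] / background[b]
    return FrequencyMatrix(
        counts=counts_df,
        totals=totals_s,
        raw=raw,
        normalized=normalized,
        organelle=organelle,
        half_width=w,
        rnmp_filter=rnmp_filter,
        n_sites=n_sites,
    )


def write_profile_tsv(matrix: FrequencyMatrix, path: str | Path) -> None:
    """TSV with per-position raw and normalized frequencies.

    The thymine column is labelled ``T/U``: at relative position 0 it is
    the rU frequency (the site is a ribonucleotide), elsewhere the
    flanking DNA thymine frequency. Absent positions are written as ``NA``.
    """
    out = pd.DataFrame({"position": matrix.positions})
    for b in DNA_BASES:
        out[f"{'T/U' if b == 'T' else b}_raw"] = matrix.raw[b].to_numpy()
    for b in DNA_BASES:
        out[f"{'T/U' if b == 'T' else b}_normalized"] = matrix.normalized[
            b
        ].to_numpy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def plot_profile(matrix: FrequencyMatrix, path: str | Path) -> None:
    """Line plot of normalized frequencies, one series per base."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for b in DNA_BASES:
        label = "T/U" if b == "T" else b
        ax.plot(matrix.positions, matrix.normalized[b], label=label, lw=1.2)
    ax.axhline(1.0, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("position relative to rNMP site (nt)")
    ax.set_ylabel("normalized frequency")
    title = f"{matrix.organelle}, ±{matrix.half_width} nt"
    if matrix.rnmp_filter:
        title += f", r{matrix.rnmp_filter}MP only"
    ax.set_title(title)
    ax.legend(frameon=False, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
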