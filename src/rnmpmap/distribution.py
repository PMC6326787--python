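"""Genome-wide distribution of rNMP sites: per-nucleotide coverage tracks,
reads-per-hundred normalization, BedGraph export and per-chromosome plots.

Coverage is normalized to *reads per hundred* — each position's count
divided by the whole-library total, times 100 — so libraries of different
sequencing depth plot on one comparable scale. Tracks are sparse
(zero-coverage runs omitted) and zero-based half-open, ready for direct
upload to a genome browser as BedGraph custom tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .coordinate import SiteTable
from .genome import GenomeIndex, InputError

__all__ = [
    "CoverageTrack",
    "coverage",
    "normalize_track",
    "write_bedgraph",
    "plot_coverage",
]

STRAND_SCOPES = ("+", "-", "both")


@dataclass(frozen=True)
class CoverageTrack:
    """Sparse per-nucleotide coverage on one chromosome.

    ``entries`` are non-overlapping sorted ``(start, end, value)`` runs with
    value > 0; adjacent runs of equal value are merged. Values are raw site
    counts or percent of the library total depending on ``percent``.
    """

    chrom: str
    scope: str  # '+', '-' or 'both'
    entries: tuple[tuple[int, int, float], ...]
    percent: bool = False

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, value in self.entries:
            if end <= start or value <= 0:
                raise InputError(
                    f"invalid track entry ({start}, {end}, {value})"
                )
            if prev_end is not None and start < prev_end:
                raise InputError("track entries overlap or are unsorted")
            prev_end = end

    @property
    def mass(self) -> float:
        """Sum of value × run length over the track."""
        return sum(v * (e - s) for s, e, v in self.entries)


def _merge_runs(
    positions: Sequence[int], values: Sequence[float]
) -> tuple[tuple[int, int, float], ...]:
    """Merge sorted single-nucleotide (pos, value) pairs into equal-value runs."""
    runs: list[tuple[int, int, float]] = []
    for pos, value in zip(positions, values):
        if runs and runs[-1][1] == pos and runs[-1][2] == value:
            start, _, _ = runs[-1]
            runs[-1] = (start, pos + 1, value)
        else:
            runs.append((pos, pos + 1, value))
    return tuple(runs)


def coverage(
    sites: SiteTable, genome: GenomeIndex, scope: str = "both"
) -> list[CoverageTrack]:
    """Raw per-nucleotide coverage tracks, one per chromosome in
    reference order.

    The value at a position is the summed raw count of the sites there
    matching the strand scope (``both`` pools strands). Chromosomes with no
    matching sites yield no track (sparse convention).
    """
    if scope not in STRAND_SCOPES:
        raise InputError(f"scope must be one of {STRAND_SCOPES}")
    frame = sites.frame
    if scope != "both":
        frame = frame[frame["strand"] == scope]
    tracks: list[CoverageTrack] = []
    for chrom in genome.names:
        sub = frame[frame["chrom"] == chrom]
        if sub.empty:
            continue
        per_pos = sub.groupby("start")["raw"].sum().sort_index()
        tracks.append(
            CoverageTrack(
                chrom=chrom,
                scope=scope,
                entries=_merge_runs(
                    per_pos.index.to_list(),
                    [float(v) for v in per_pos.to_numpy()],
                ),
            )
        )
    return tracks


def normalize_track(
    tracks: Sequence[CoverageTrack], library_total: int
) -> list[CoverageTrack]:
    """Convert raw tracks to reads per hundred (percent of library total).

    ``library_total`` is the summed raw count of the whole library (all
    chromosomes, both strands), so percent values over every chromosome
    and strand sum to 100; per-chromosome totals would break cross-library
    comparability and are not used here.
    """
    if library_total <= 0:
        raise InputError("library_total must be positive")
    out: list[CoverageTrack] = []
    for track in tracks:
        entries = tuple(
            (s, e, v / library_total * 100.0) for s, e, v in track.entries
        )
        out.append(replace(track, entries=entries, percent=True))
    return out


def _format_value(value: float) -> str:
    """Trim to at most 6 decimals with no trailing zeros (10.0 → '10')."""
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def write_bedgraph(
    tracks: "CoverageTrack | Iterable[CoverageTrack]", path: str | Path
) -> int:
    """Standard 4-column BedGraph (chrom, start, end, value), LF endings.

    Adjacent equal-valued entries are merged into one line. Returns the
    number of lines written; an empty track yields an empty file with no
    header (browser-compatible).
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    n = 0
    with open(path, "w") as handle:
        for track in tracks:
            merged: list[tuple[int, int, float]] = []
            for start, end, value in track.entries:
                if merged and merged[-1][1] == start and merged[-1][2] == value:
                    merged[-1] = (merged[-1][0], end, value)
                else:
                    merged.append((start, end, value))
            for start, end, value in merged:
                handle.write(
                    f"{track.chrom}\t{start}\t{end}\t{_format_value(value)}\n"
                )
                n += 1
    return n


def plot_coverage(
    tracks_by_scope: dict[str, Sequence[CoverageTrack]],
    genome: GenomeIndex,
    path: str | Path,
) -> None:
    """One panel per chromosome; x = position, y = percent coverage.

    ``tracks_by_scope`` maps a strand scope label to its (normalized)
    tracks; scopes are overlaid as separate series in each panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = genome.names
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(9, 2.2 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        for scope, tracks in tracks_by_scope.items():
            for track in tracks:
                if track.chrom != chrom:
                    continue
                xs, ys = [], []
                for start, end, value in track.entries:
                    for pos in range(start, end):
                        xs.append(pos)
                        ys.append(value)
                ax.vlines(xs, 0, ys, label=scope, lw=0.8)
        ax.set_xlim(0, genome.length(chrom))
        ax.set_ylabel("reads per hundred (%)")
        ax.set_title(chrom, fontsize=9)
        handles, labels = ax.get_legend_handles_labels()
        if handles:
            seen: dict[str, object] = {}
            for h, l in zip(handles, labels):
                seen.setdefault(l, h)
            ax.legend(seen.values(), seen.keys(), frameon=False, fontsize=7)
    axes.ravel()[-1].set_xlabel("chromosome position (nt)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
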