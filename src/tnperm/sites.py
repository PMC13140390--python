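"""Unique-site collapsing, per-library summary statistics, coverage windows.

A "unique insertion site" is a distinct (contig, position, strand) junction;
forward- and reverse-strand junctions at the same base are distinct
molecular events. Library summaries count only insertions falling in the
central 80% of each gene (the 10-90% interval), the same window the scoring
module uses, so that short terminal truncations without phenotype do not
inflate gene-level counts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import median_abs_deviation

from .iohub import GeneAnnotation, GenomeModel, InsertionSite
from .scoring import central_window

logger = logging.getLogger("tnperm")


@dataclass
class LibraryStats:
    """Per-library Tn-seq summary over central-80% gene windows."""

    library_id: str
    final_reads: float
    insertions_80: float
    unique_80: float
    unique_ratio: float  # percent
    normalized_per_M: float  # unique_80 per 10^6 final reads

    @classmethod
    def from_counts(
        cls, library_id: str, final_reads: float, insertions_80: float, unique_80: float
    ) -> "LibraryStats":
        """Derive the ratio and depth-normalized columns from raw counts."""
        if final_reads <= 0:
            raise ValueError(f"library {library_id!r}: final_reads must be > 0")
        if not (unique_80 <= insertions_80 <= final_reads):
            logger.warning(
                "library %s: expected unique_80 <= insertions_80 <= final_reads "
                "(got %s, %s, %s)", library_id, unique_80, insertions_80, final_reads,
            )
        ratio = 100.0 * unique_80 / insertions_80 if insertions_80 else 0.0
        return cls(
            library_id=library_id,
            final_reads=final_reads,
            insertions_80=insertions_80,
            unique_80=unique_80,
            unique_ratio=ratio,
            normalized_per_M=unique_80 / final_reads * 1e6,
        )


@dataclass
class CoverageWindow:
    contig: str
    window_start: int
    width: int
    mean_coverage: float  # reads per bp
    log10_mean: float  # log10(mean + 1)
    hotspot_flag: bool = False


def collapse_sites(raw_sites: Sequence[InsertionSite]) -> list[InsertionSite]:
    """Merge records sharing (contig, position, strand), summing read counts.

    All input records must come from one library. Output is sorted by
    contig, position, strand and is idempotent under re-collapsing.
    """
    libs = {s.library_id for s in raw_sites}
    if len(libs) > 1:
        raise ValueError(f"mixed library_ids in one collapse: {sorted(libs)}")
    lib = libs.pop() if libs else ""
    acc: dict[tuple[str, int, str], int] = {}
    for s in raw_sites:
        acc[s.key] = acc.get(s.key, 0) + s.read_count
    return [
        InsertionSite(contig, pos, strand, count, lib)
        for (contig, pos, strand), count in sorted(acc.items())
    ]


def _window_counts(
    sites: Sequence[InsertionSite], genes: Sequence[GeneAnnotation]
) -> tuple[int, int]:
    """(read-level events, unique sites) inside central-80% windows.

    Summed per gene, so a site inside two overlapping gene windows counts
    toward both (this keeps the per-gene and library-level totals consistent).
    """
    by_contig: dict[str, list[InsertionSite]] = {}
    for s in sites:
        by_contig.setdefault(s.contig, []).append(s)
    pos_arrays: dict[str, np.ndarray] = {}
    count_arrays: dict[str, np.ndarray] = {}
    for c, lst in by_contig.items():
        lst_sorted = sorted(lst, key=lambda s: (s.position, s.strand))
        pos_arrays[c] = np.array([s.position for s in lst_sorted], dtype=np.int64)
        count_arrays[c] = np.array([s.read_count for s in lst_sorted], dtype=np.int64)
    total_reads = 0
    total_unique = 0
    for gene in genes:
        if gene.contig not in pos_arrays:
            continue
        ws, we = central_window(gene)
        pos = pos_arrays[gene.contig]
        lo = np.searchsorted(pos, ws, side="left")
        hi = np.searchsorted(pos, we, side="left")
        total_reads += int(count_arrays[gene.contig][lo:hi].sum())
        total_unique += int(hi - lo)
    return total_reads, total_unique


def library_stats(
    sites: Sequence[InsertionSite],
    genes: Sequence[GeneAnnotation],
    final_reads: float,
    library_id: str | None = None,
) -> LibraryStats:
    """Summary statistics for one collapsed library."""
    if final_reads <= 0:
        raise ValueError("final_reads must be > 0")
    if library_id is None:
        library_id = next((s.library_id for s in sites if s.library_id), "")
    insertions_80, unique_80 = _window_counts(sites, genes)
    return LibraryStats.from_counts(library_id, final_reads, insertions_80, unique_80)


def mean_stats(stats: Sequence[LibraryStats]) -> LibraryStats:
    """Arithmetic mean of each numeric column across libraries; the ratio and
    normalized columns are averaged as values, not recomputed from means."""
    if not stats:
        raise ValueError("mean_stats needs at least one library")
    n = len(stats)
    return LibraryStats(
        library_id="Mean",
        final_reads=sum(s.final_reads for s in stats) / n,
        insertions_80=sum(s.insertions_80 for s in stats) / n,
        unique_80=sum(s.unique_80 for s in stats) / n,
        unique_ratio=sum(s.unique_ratio for s in stats) / n,
        normalized_per_M=sum(s.normalized_per_M for s in stats) / n,
    )


def unique_site_spacing(genome: GenomeModel, mean_unique: float) -> int:
    """Mean distance (bp) between unique insertion sites, to the nearest bp."""
    if mean_unique <= 0:
        raise ValueError("mean_unique must be > 0")
    return round(genome.total_length / mean_unique)


def coverage_windows(
    sites: Sequence[InsertionSite], genome: GenomeModel, width: int = 1000
) -> list[CoverageWindow]:
    """Mean read coverage per fixed-width window tiling each contig.

    mean_coverage = summed read counts in the window / true window width;
    log10_mean uses a pseudocount of 1 on the mean. The last window of a
    contig may be partial and is normalized by its true width.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    by_contig: dict[str, list[InsertionSite]] = {c: [] for c in genome.contig_ids}
    for s in sites:
        if s.contig not in by_contig:
            raise KeyError(f"site contig {s.contig!r} not in genome model")
        by_contig[s.contig].append(s)
    windows: list[CoverageWindow] = []
    for contig, length in zip(genome.contig_ids, genome.contig_lengths):
        n_win = math.ceil(length / width)
        sums = np.zeros(n_win)
        for s in by_contig[contig]:
            if s.position >= length:
                raise ValueError(
                    f"site at {s.position} beyond contig {contig!r} length {length}"
                )
            sums[s.position // width] += s.read_count
        for i in range(n_win):
            true_width = min(width, length - i * width)
            mean = sums[i] / true_width
            windows.append(
                CoverageWindow(
                    contig=contig,
                    window_start=i * width,
                    width=true_width,
                    mean_coverage=float(mean),
                    log10_mean=float(np.log10(mean + 1)),
                )
            )
    return windows


def flag_hotspots(windows: Sequence[CoverageWindow], k: float = 5.0) -> list[CoverageWindow]:
    """Flag windows whose mean coverage exceeds median + k * MAD.

    The threshold is computed over all supplied windows jointly. With fewer
    than 3 windows no flags are set and a warning is emitted.
    """
    out = [
        CoverageWindow(w.contig, w.window_start, w.width, w.mean_coverage, w.log10_mean, False)
        for w in windows
    ]
    if len(windows) < 3:
        warnings.warn("fewer than 3 windows: hotspot flagging skipped")
        return out
    cov = np.array([w.mean_coverage for w in windows])
    threshold = np.median(cov) + k * median_abs_deviation(cov, scale=1.0)
    for w in out:
        w.hotspot_flag = w.mean_coverage > threshold
    return out
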