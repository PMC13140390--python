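"""Per-gene insertion scores, Z-scores, library PCA and modality diagnostics.

For each gene the read-level insertion events inside its central 80% window
are counted and normalized against the expectation under a uniform insertion
rate:

    Score = log2( count / (mapped_reads * gene_length / genome_length) + 1 )

where mapped_reads is the library's total read-level events within all
central gene windows. A gene inserted exactly at the uniform expectation
scores 1 (log2 of 2); a gene with no insertions scores 0. Scores are then
standardized per library across genes (sample SD) to Z-scores, which carry
all downstream comparisons: libraries can be overlaid, averaged and
clustered regardless of their sequencing depth.

The modality diagnostic is the bimodality coefficient

    BC = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))

with sample skewness g1 and sample excess kurtosis g2; BC above 5/9 (the
value for a uniform density) is called bimodal. A classic Tn-seq score
distribution (zero-insertion essential mode + permissive mode) is bimodal;
a polyploid organism tolerating heterozygous disruptions collapses to one
mode and the coefficient falls below the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iohub import GeneAnnotation, InsertionSite

BIMODALITY_THRESHOLD = 5.0 / 9.0


def central_window(gene: GeneAnnotation) -> tuple[int, int]:
    """The central 80% of the gene's genomic interval (strand-independent).

    [start + floor(0.1 L), start + ceil(0.9 L)) in 0-based half-open
    coordinates; trimming 10% from each end discards insertions producing
    short terminal truncations that may lack a phenotype.
    """
    L = gene.length
    return gene.start + math.floor(0.1 * L), gene.start + math.ceil(0.9 * L)


def count_in_window(
    sites: Sequence[InsertionSite], gene: GeneAnnotation
) -> tuple[int, int]:
    """(read-level events, unique sites) within the gene's central window.

    Strands are pooled for counting; unique sites keep strand in the key.
    ``sites`` should be collapsed so unique counting is well defined.
    """
    ws, we = central_window(gene)
    count = 0
    unique = 0
    for s in sites:
        if s.contig == gene.contig and ws <= s.position < we:
            count += s.read_count
            unique += 1
    return count, unique


def score(count: float, mapped_reads: float, gene_length: int, genome_length: int) -> float:
    """Length- and depth-normalized insertion score (log2 observed/expected + 1)."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    if gene_length <= 0 or genome_length <= 0:
        raise ValueError("gene_length and genome_length must be > 0")
    expected = mapped_reads * gene_length / genome_length
    return math.log2(count / expected + 1.0)


def zscore(scores: Sequence[float]) -> np.ndarray:
    """Standardize one library's scores across genes (sample SD, ddof=1)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("zscore needs at least 2 genes")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate library: all scores identical (SD = 0)")
    return (x - x.mean()) / sd


def score_table(
    genes: Sequence[GeneAnnotation],
    libraries: Mapping[str, Sequence[InsertionSite]],
    genome_length: int,
    use_unique: bool = False,
) -> pd.DataFrame:
    """Per-gene score table across libraries.

    Columns per library: ``count_<lib>``, ``unique_<lib>``, ``score_<lib>``,
    ``z_<lib>``; plus ``mean_Z`` (unweighted mean of per-library Z). The
    score uses read-level counts by default; ``use_unique`` switches it to
    unique-site counts. ``mapped_reads`` per library is the summed
    read-level count over all central windows.
    """
    if not genes:
        raise ValueError("no genes")
    index = [g.gene_id for g in genes]
    df = pd.DataFrame(index=pd.Index(index, name="gene_id"))
    z_cols = []
    for lib_id, sites in libraries.items():
        by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per_contig: dict[str, list[InsertionSite]] = {}
        for s in sites:
            per_contig.setdefault(s.contig, []).append(s)
        for c, lst in per_contig.items():
            lst = sorted(lst, key=lambda s: (s.position, s.strand))
            by_contig[c] = (
                np.array([s.position for s in lst], dtype=np.int64),
                np.array([s.read_count for s in lst], dtype=np.int64),
            )
        counts = np.zeros(len(genes), dtype=np.int64)
        uniques = np.zeros(len(genes), dtype=np.int64)
        for i, gene in enumerate(genes):
            if gene.contig not in by_contig:
                continue
            pos, cnt = by_contig[gene.contig]
            ws, we = central_window(gene)
            lo = np.searchsorted(pos, ws, side="left")
            hi = np.searchsorted(pos, we, side="left")
            counts[i] = cnt[lo:hi].sum()
            uniques[i] = hi - lo
        mapped = int(counts.sum())
        if mapped <= 0:
            raise ValueError(f"library {lib_id!r}: no mapped reads in gene windows")
        basis = uniques if use_unique else counts
        lengths = np.array([g.length for g in genes])
        scores = np.log2(basis / (mapped * lengths / genome_length) + 1.0)
        df[f"count_{lib_id}"] = counts
        df[f"unique_{lib_id}"] = uniques
        df[f"score_{lib_id}"] = scores
        df[f"z_{lib_id}"] = zscore(scores)
        z_cols.append(f"z_{lib_id}")
    if not z_cols:
        raise ValueError("no libraries supplied")
    df["mean_Z"] = df[z_cols].mean(axis=1)
    return df


def z_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """The genes x libraries Z-score block of a score table."""
    cols = [c for c in table.columns if c.startswith("z_")]
    return table[cols]


def pca_libraries(z: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with libraries as the points and genes as the features.

    Returns (coordinates, variance fractions); fractions sum to 1.
    """
    from sklearn.decomposition import PCA

    if isinstance(z, pd.DataFrame):
        names = [c.removeprefix("z_") for c in z.columns]
        mat = z.to_numpy(dtype=float)
    else:
        mat = np.asarray(z, dtype=float)
        names = [f"lib_{i + 1}" for i in range(mat.shape[1])]
    if mat.shape[1] < 2:
        raise ValueError("PCA needs at least 2 libraries")
    pca = PCA()  # all components, so the variance fractions sum to 1
    coords = pca.fit_transform(mat.T)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=pd.Index(names, name="library"), columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class DistributionDiagnostics:
    """Modality diagnostic for one library's Z-score distribution."""

    library_id: str
    n: int
    bimodality_coefficient: float
    modality_call: str  # "unimodal" | "bimodal"
    histogram_counts: np.ndarray = field(repr=False, default=None)
    histogram_edges: np.ndarray = field(repr=False, default=None)


def bimodality(z: Sequence[float], library_id: str = "", bins: int = 30) -> DistributionDiagnostics:
    """Bimodality coefficient of a Z-score vector; bimodal iff BC > 5/9."""
    x = np.asarray(z, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"bimodality needs n >= 10, got {n}")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    bc = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    counts, edges = np.histogram(x, bins=bins)
    return DistributionDiagnostics(
        library_id=library_id,
        n=n,
        bimodality_coefficient=float(bc),
        modality_call="bimodal" if bc > BIMODALITY_THRESHOLD else "unimodal",
        histogram_counts=counts,
        histogram_edges=edges,
    )
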