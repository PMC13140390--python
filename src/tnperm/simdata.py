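"""Synthetic polyploid Tn-seq libraries with known ground truth.

The generator emulates a compact, high-coding-density bacterial genome
(~2.1 Mb, ~2000 genes averaging 955 bp) and transposon-insertion libraries
of 10^5 clones yielding 10^5-10^6 reads, including insertion hotspots.

The mechanism of interest is ploidy-dependent survival: in a polyploid cell
(c genome copies) a transposon can disrupt one copy of an essential gene
while intact copies keep the clone alive. Each insertion landing in an
essential gene body survives with probability ``w`` (the heterozygous
survival probability, default 1 - 1/c, forced to 0 in a monoploid), and a
surviving heterozygous disruption carries an allele fraction of (c-1)/c,
scaling its expected read yield. Insertions in non-essential genes or
intergenic DNA always survive. At c=1 this produces the classic bimodal
per-gene score distribution (an empty essential mode); at c=7-8 essential
genes keep most of their insertions and the distribution collapses to a
single mode, which is exactly why essential genes become hard to call.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .iohub import (
    GeneAnnotation,
    GenomeModel,
    InsertionSite,
    write_fai,
    write_gff,
    write_sites_bed,
    write_table,
)


@dataclass
class SimulationParams:
    """Knobs of the synthetic genome and library generator.

    Defaults mirror the study organism: a 2.12 Mb genome densely packed with
    ~955 bp genes, ploidy 7-8 (8 here), and libraries of 10^5 independent
    insertion clones sequenced to a few 10^5 reads.
    """

    seed: int = 0
    genome_length: int = 2_120_000
    n_genes: int = 2000
    gene_length_mean: int = 955
    coding_fraction: float = 0.93
    essential_fraction: float = 0.10
    ploidy: int = 8
    het_survival: float | None = None  # default 1 - 1/ploidy; 0 forced at ploidy 1
    clones: int = 100_000
    reads_per_clone_mean: float = 5.0
    reads_per_clone_dispersion: float = 2.0  # negative-binomial size parameter
    hotspots: tuple[tuple[int, float], ...] = ()  # (window start bp, fold)
    hotspot_width: int = 1000
    n_libraries: int = 4
    contig_id: str = "chromosome"

    def __post_init__(self):
        for name in ("coding_fraction", "essential_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.clones <= 0:
            raise ValueError("clones must be > 0")
        if self.het_survival is None:
            self.het_survival = 0.0 if self.ploidy == 1 else 1.0 - 1.0 / self.ploidy
        if self.ploidy == 1:
            self.het_survival = 0.0  # a monoploid cannot carry a heterozygous knockout
        if not 0 <= self.het_survival <= 1:
            raise ValueError("het_survival must be in [0, 1]")
        if self.reads_per_clone_mean <= 0 or self.reads_per_clone_dispersion <= 0:
            raise ValueError("read-count parameters must be positive")
        for pos, fold in self.hotspots:
            if fold <= 0 or pos < 0 or pos >= self.genome_length:
                raise ValueError(f"bad hotspot ({pos}, {fold})")


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests: per-gene essentiality and
    the survival probability of an insertion landing in the gene body."""

    essential: dict[str, bool]
    survival_rate: dict[str, float]

    def essential_ids(self) -> set[str]:
        return {g for g, e in self.essential.items() if e}


@dataclass
class SimBundle:
    params: SimulationParams
    genome: GenomeModel
    genes: list[GeneAnnotation]
    truth: TruthTable
    libraries: dict[str, list[InsertionSite]]


def _genome_rng(params: SimulationParams) -> np.random.Generator:
    return np.random.default_rng([params.seed, 0])


def _library_rng(params: SimulationParams, index: int) -> np.random.Generator:
    # fixed per-library stream offsets so each fixture is independently reproducible
    return np.random.default_rng([params.seed, 1 + index])


def simulate_genome(
    params: SimulationParams,
) -> tuple[GenomeModel, list[GeneAnnotation], TruthTable]:
    """Place non-overlapping genes uniformly on a single-contig genome.

    Gene lengths are gamma-distributed (shape 3) around ``gene_length_mean``,
    floored at 90 bp; essential flags are i.i.d. Bernoulli draws. Raises if
    the requested coding content cannot fit.
    """
    genome = GenomeModel((params.contig_id,), (params.genome_length,))
    if params.n_genes == 0:
        return genome, [], TruthTable({}, {})
    budget = params.coding_fraction * params.genome_length
    if params.n_genes * params.gene_length_mean > budget:
        raise ValueError(
            f"infeasible packing: {params.n_genes} genes x {params.gene_length_mean} bp mean "
            f"= {params.n_genes * params.gene_length_mean} bp exceeds the coding capacity "
            f"{budget:.0f} bp (coding_fraction {params.coding_fraction} of "
            f"{params.genome_length} bp)"
        )
    rng = _genome_rng(params)
    shape = 3.0
    lengths = rng.gamma(shape, params.gene_length_mean / shape, size=params.n_genes)
    lengths = np.maximum(90, np.round(lengths)).astype(int)
    if lengths.sum() > budget:  # rare upward fluctuation of the drawn total
        lengths = np.maximum(90, np.floor(lengths * budget / lengths.sum())).astype(int)
    free = params.genome_length - int(lengths.sum())
    gaps = rng.multinomial(free, np.full(params.n_genes + 1, 1.0 / (params.n_genes + 1)))
    strands = rng.choice(["+", "-"], size=params.n_genes)
    essential = rng.random(params.n_genes) < params.essential_fraction

    genes: list[GeneAnnotation] = []
    truth_e: dict[str, bool] = {}
    truth_s: dict[str, float] = {}
    pos = 0
    width = len(str(params.n_genes))
    for i in range(params.n_genes):
        pos += int(gaps[i])
        gid = f"gene_{i:0{width}d}"
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                contig=params.contig_id,
                start=pos,
                end=pos + int(lengths[i]),
                strand=str(strands[i]),
                product="simulated protein",
            )
        )
        truth_e[gid] = bool(essential[i])
        truth_s[gid] = params.het_survival if essential[i] else 1.0
        pos += int(lengths[i])
    return genome, genes, TruthTable(truth_e, truth_s)


def _hotspot_segments(params: SimulationParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genome partition into segments with multiplicative sampling weight."""
    L = params.genome_length
    bounds = {0, L}
    folds: list[tuple[int, int, float]] = []
    for pos, fold in params.hotspots:
        end = min(L, pos + params.hotspot_width)
        bounds.update((pos, end))
        folds.append((pos, end, fold))
    edges = np.array(sorted(bounds))
    starts, ends = edges[:-1], edges[1:]
    weight = (ends - starts).astype(float)
    for pos, end, fold in folds:
        inside = (starts >= pos) & (ends <= end)
        weight[inside] *= fold
    return starts, ends, weight


def simulate_library(
    genome: GenomeModel,
    genes: Sequence[GeneAnnotation],
    truth: TruthTable,
    params: SimulationParams,
    library_id: str = "lib_1",
    rng: np.random.Generator | None = None,
) -> list[InsertionSite]:
    """One library: ``clones`` insertion attempts under the survival model.

    Returns one raw record per surviving clone (duplicate coordinates are
    possible and intentional; collapsing is downstream work).
    """
    if rng is None:
        rng = _library_rng(params, 0)
    n = params.clones
    starts, ends, weight = _hotspot_segments(params)
    seg = rng.choice(len(weight), size=n, p=weight / weight.sum())
    positions = starts[seg] + np.floor(
        rng.random(n) * (ends[seg] - starts[seg])
    ).astype(np.int64)
    strands = rng.choice(["+", "-"], size=n)

    gene_starts = np.array([g.start for g in genes], dtype=np.int64)
    gene_ends = np.array([g.end for g in genes], dtype=np.int64)
    if len(genes):
        idx = np.searchsorted(gene_starts, positions, side="right") - 1
        in_gene = (idx >= 0) & (positions < gene_ends[np.clip(idx, 0, None)])
    else:
        idx = np.full(n, -1)
        in_gene = np.zeros(n, dtype=bool)
    essential_flags = np.array(
        [truth.essential.get(g.gene_id, False) for g in genes], dtype=bool
    )
    hit_essential = np.zeros(n, dtype=bool)
    if len(genes):
        hit_essential[in_gene] = essential_flags[idx[in_gene]]

    survive = np.ones(n, dtype=bool)
    survive[hit_essential] = rng.random(hit_essential.sum()) < params.het_survival

    # read yield: NB around the per-clone mean, scaled by the allele fraction
    # (c-1)/c when the surviving clone is a heterozygous essential disruption
    c = params.ploidy
    mean = np.full(n, params.reads_per_clone_mean)
    if c > 1:
        mean[hit_essential] *= (c - 1) / c
    r = params.reads_per_clone_dispersion
    counts = 1 + rng.negative_binomial(r, r / (r + mean))

    sites = [
        InsertionSite(
            contig=params.contig_id,
            position=int(p),
            strand=str(s),
            read_count=int(k),
            library_id=library_id,
        )
        for p, s, k, ok in zip(positions, strands, counts, survive)
        if ok
    ]
    return sites


def simulate_libraries(params: SimulationParams) -> SimBundle:
    """The full bundle: genome, annotation, truth and n_libraries libraries."""
    genome, genes, truth = simulate_genome(params)
    libraries = {}
    for i in range(params.n_libraries):
        lib_id = f"lib_{i + 1}"
        libraries[lib_id] = simulate_library(
            genome, genes, truth, params, lib_id, _library_rng(params, i)
        )
    return SimBundle(params, genome, genes, truth, libraries)


def emit_fixture(bundle: SimBundle, out_dir: str) -> dict[str, str]:
    """Write the bundle as plain-text files: GFF3, .fai, one BED per library
    and a truth TSV. Returns the paths keyed by role."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "gff": write_gff(bundle.genes, os.path.join(out_dir, "genes.gff3")),
        "fai": write_fai(bundle.genome, os.path.join(out_dir, "genome.fa.fai")),
    }
    for lib_id, sites in bundle.libraries.items():
        paths[lib_id] = write_sites_bed(sites, os.path.join(out_dir, f"{lib_id}.bed"))
    truth_rows = [
        {
            "gene_id": gid,
            "essential": int(flag),
            "survival_rate": bundle.truth.survival_rate[gid],
        }
        for gid, flag in bundle.truth.essential.items()
    ]
    import pandas as pd

    truth_path = os.path.join(out_dir, "truth.tsv")
    pd.DataFrame(truth_rows, columns=["gene_id", "essential", "survival_rate"]).to_csv(
        truth_path, sep="\t", index=False
    )
    paths["truth"] = truth_path
    return paths
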