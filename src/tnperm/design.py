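"""Library-design arithmetic: how many insertion clones saturate a genome.

With f the per-clone probability of hitting an average gene
(gene_length / genome_length), the clone count needed to hit every gene
with probability at least P is N = ln(1-P) / ln(1-f), rounded up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class LibraryDesignParams:
    P: float
    gene_length: int
    genome_length: int

    @property
    def f(self) -> float:
        return self.gene_length / self.genome_length

    @property
    def N(self) -> int:
        return saturation_size(self.P, self.gene_length, self.genome_length)


def saturation_size(P: float, gene_length: int, genome_length: int) -> int:
    """Clones needed to hit an average gene with probability >= P (ceiling)."""
    if not 0 < P < 1:
        raise ValueError(f"P must be in (0, 1), got {P}")
    f = gene_length / genome_length
    if not 0 < f < 1:
        raise ValueError(f"gene/genome length ratio must be in (0, 1), got {f}")
    return max(1, math.ceil(math.log(1.0 - P) / math.log(1.0 - f)))


def coverage_probability(N: int, f: float) -> float:
    """Probability that at least one of N clones hits a gene of share f."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if not 0 < f < 1:
        raise ValueError(f"f must be in (0, 1), got {f}")
    return 1.0 - (1.0 - f) ** N
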