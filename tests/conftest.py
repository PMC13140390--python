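import pytest

from tnperm import (
    SimulationParams,
    collapse_sites,
    score_table,
    simulate_libraries,
)

#: study-scale simulation conditions used by the cross-module tests:
#: 1000 genes averaging 955 bp on a ~1 Mb genome, 10% essential genes,
#: 10^5 insertion clones per library, four libraries.
STUDY_CONDITIONS = dict(
    genome_length=1_060_000,
    n_genes=1000,
    essential_fraction=0.10,
    clones=100_000,
    n_libraries=4,
)


def _bundle_and_table(ploidy: int, seed: int = 0):
    params = SimulationParams(seed=seed, ploidy=ploidy, **STUDY_CONDITIONS)
    bundle = simulate_libraries(params)
    collapsed = {k: collapse_sites(v) for k, v in bundle.libraries.items()}
    table = score_table(bundle.genes, collapsed, bundle.genome.total_length)
    return bundle, collapsed, table


@pytest.fixture(scope="session")
def monoploid_run():
    """Simulated study at ploidy 1: essential genes cannot retain insertions."""
    return _bundle_and_table(ploidy=1)


@pytest.fixture(scope="session")
def polyploid_run():
    """Simulated study at ploidy 8 (heterozygous survival 7/8)."""
    return _bundle_and_table(ploidy=8)


@pytest.fixture(scope="session")
def small_monoploid_run():
    """A lighter monoploid run for distribution-level property tests."""
    params = SimulationParams(
        seed=0, ploidy=1, genome_length=560_000, n_genes=500,
        essential_fraction=0.10, clones=50_000, n_libraries=2,
    )
    bundle = simulate_libraries(params)
    collapsed = {k: collapse_sites(v) for k, v in bundle.libraries.items()}
    table = score_table(bundle.genes, collapsed, bundle.genome.total_length)
    return bundle, collapsed, table
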