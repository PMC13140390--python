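import random

import pytest

from tnperm import (
    GeneAnnotation,
    GenomeModel,
    InsertionSite,
    LibraryStats,
    collapse_sites,
    coverage_windows,
    flag_hotspots,
    library_stats,
    mean_stats,
    sig3,
    unique_site_spacing,
)

# the study's four printed library summaries (final reads, read-level
# insertions and unique sites inside central-80% gene windows)
PRINTED_LIBRARIES = [
    ("Ppol_1", 9.00e5, 1.05e5, 3.69e4),
    ("Ppol_2", 1.70e6, 1.64e5, 4.39e4),
    ("HB27_2", 1.30e6, 2.88e5, 7.14e4),
    ("HB27_1", 2.70e6, 1.56e5, 3.77e4),
]


class TestCollapseSites:
    def test_same_key_counts_summed(self):
        raw = [InsertionSite("c", 150, "+", 2), InsertionSite("c", 150, "+", 3)]
        (merged,) = collapse_sites(raw)
        assert merged.read_count == 5

    def test_strand_is_part_of_the_key(self):
        raw = [InsertionSite("c", 150, "+", 1), InsertionSite("c", 150, "-", 1)]
        assert len(collapse_sites(raw)) == 2

    def test_order_independent(self):
        raw = [
            InsertionSite("c", p, s, k)
            for p, s, k in [(10, "+", 1), (5, "-", 2), (10, "+", 4), (7, "+", 1), (5, "-", 1)]
        ]
        expected = collapse_sites(raw)
        for seed in range(5):
            shuffled = raw[:]
            random.Random(seed).shuffle(shuffled)
            assert collapse_sites(shuffled) == expected

    def test_idempotent_and_read_sum_preserved(self):
        raw = [InsertionSite("c", i % 7, "+", 1 + i % 3) for i in range(50)]
        once = collapse_sites(raw)
        assert collapse_sites(once) == once
        assert sum(s.read_count for s in once) == sum(s.read_count for s in raw)

    def test_mixed_libraries_rejected(self):
        raw = [InsertionSite("c", 1, "+", 1, "a"), InsertionSite("c", 2, "+", 1, "b")]
        with pytest.raises(ValueError, match="mixed"):
            collapse_sites(raw)


class TestLibraryStats:
    def test_printed_normalized_column_recovered(self):
        st = LibraryStats.from_counts("HB27_1", 2.70e6, 1.56e5, 3.77e4)
        assert sig3(st.normalized_per_M) == "1.40e4"

    def test_printed_unique_ratio_recovered(self):
        st = LibraryStats.from_counts("HB27_2", 1.30e6, 2.88e5, 7.14e4)
        assert sig3(st.unique_ratio) == "24.8"

    def test_no_sites_all_zero_except_final_reads(self):
        genes = [GeneAnnotation("g", "c", 0, 1000, "+")]
        st = library_stats([], genes, final_reads=100.0, library_id="x")
        assert (st.insertions_80, st.unique_80, st.unique_ratio) == (0, 0, 0.0)
        assert st.final_reads == 100.0

    def test_zero_final_reads_rejected(self):
        with pytest.raises(ValueError):
            library_stats([], [], final_reads=0)

    def test_counts_only_inside_central_window(self):
        genes = [GeneAnnotation("g", "c", 100, 1100, "+")]  # window [200, 1000)
        sites = [
            InsertionSite("c", 150, "+", 5),   # trimmed 5' tail
            InsertionSite("c", 500, "+", 3),   # inside
            InsertionSite("c", 1000, "-", 2),  # window end, excluded
        ]
        st = library_stats(sites, genes, final_reads=100)
        assert (st.insertions_80, st.unique_80) == (3, 1)

    def test_unique_ratio_independent_of_sequencing_depth(self):
        """The unique/insertions ratio is a property of the site table; only
        the per-million normalization responds to final_reads."""
        genes = [GeneAnnotation("g", "c", 0, 1000, "+")]
        sites = [InsertionSite("c", p, "+", k) for p, k in [(200, 2), (300, 5), (400, 1)]]
        a = library_stats(sites, genes, final_reads=1000)
        b = library_stats(sites, genes, final_reads=10_000)
        assert a.unique_ratio == pytest.approx(b.unique_ratio)
        assert a.normalized_per_M == pytest.approx(10 * b.normalized_per_M)


class TestMeanStats:
    def test_mean_row_reproduced_from_printed_libraries(self):
        stats = [LibraryStats.from_counts(*row) for row in PRINTED_LIBRARIES]
        mean = mean_stats(stats)
        assert sig3(mean.unique_ratio) == "27.7"
        assert sig3(mean.normalized_per_M) == "3.39e4"
        assert sig3(mean.unique_80) == "4.75e4"

    def test_single_library_is_identity(self):
        st = LibraryStats.from_counts(*PRINTED_LIBRARIES[0])
        mean = mean_stats([st])
        assert mean.unique_ratio == st.unique_ratio
        assert mean.normalized_per_M == st.normalized_per_M

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_stats([])


class TestSpacing:
    def test_study_scale_spacing_is_45_bp(self):
        genome = GenomeModel(("chr",), (2_120_000,))
        assert unique_site_spacing(genome, 4.75e4) == 45

    @pytest.mark.parametrize("length,unique,expected", [(100, 100, 1), (1000, 3, 333)])
    def test_small_cases(self, length, unique, expected):
        assert unique_site_spacing(GenomeModel(("c",), (length,)), unique) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            unique_site_spacing(GenomeModel(("c",), (10,)), 0)


class TestCoverageWindows:
    def test_uniform_single_reads(self):
        import math

        genome = GenomeModel(("c",), (2000,))
        sites = [InsertionSite("c", i, "+", 1) for i in range(2000)]
        windows = coverage_windows(sites, genome, width=1000)
        assert all(w.mean_coverage == 1.0 for w in windows)
        assert all(w.log10_mean == pytest.approx(math.log10(2)) for w in windows)

    def test_empty_library_zero_everywhere(self):
        windows = coverage_windows([], GenomeModel(("c",), (3000,)), width=1000)
        assert all(w.mean_coverage == 0 and w.log10_mean == 0 for w in windows)

    def test_all_reads_in_one_window(self):
        genome = GenomeModel(("c",), (5000,))
        sites = [InsertionSite("c", 2100 + i, "+", 2) for i in range(10)]
        windows = coverage_windows(sites, genome, width=1000)
        nonzero = [w for w in windows if w.mean_coverage > 0]
        assert [w.window_start for w in nonzero] == [2000]
        assert nonzero[0].mean_coverage == pytest.approx(20 / 1000)

    def test_partial_last_window_uses_true_width(self):
        genome = GenomeModel(("c",), (1500,))
        sites = [InsertionSite("c", 1400, "+", 50)]
        windows = coverage_windows(sites, genome, width=1000)
        assert windows[-1].width == 500
        assert windows[-1].mean_coverage == pytest.approx(50 / 500)

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            coverage_windows([], GenomeModel(("c",), (10,)), width=0)


class TestHotspots:
    def test_single_spike_flagged(self):
        genome = GenomeModel(("c",), (10_000,))
        sites = [InsertionSite("c", i * 1000 + 5, "+", 1) for i in range(10)]
        sites.append(InsertionSite("c", 3500, "+", 100))
        windows = flag_hotspots(coverage_windows(collapse_sites(sites), genome))
        assert [w.window_start for w in windows if w.hotspot_flag] == [3000]

    def test_flat_coverage_unflagged(self):
        genome = GenomeModel(("c",), (10_000,))
        sites = [InsertionSite("c", i * 1000 + 5, "+", 7) for i in range(10)]
        windows = flag_hotspots(coverage_windows(sites, genome))
        assert not any(w.hotspot_flag for w in windows)

    def test_too_few_windows_warns_without_flags(self):
        genome = GenomeModel(("c",), (2000,))
        sites = [InsertionSite("c", 10, "+", 100)]
        windows = coverage_windows(sites, genome, width=1000)
        with pytest.warns(UserWarning, match="fewer than 3"):
            flagged = flag_hotspots(windows)
        assert not any(w.hotspot_flag for w in flagged)

    def test_simulated_hotspot_recovered(self):
        """A fold-50 hotspot injected by the simulator is the flagged window."""
        from tnperm import SimulationParams, simulate_genome, simulate_library

        params = SimulationParams(
            seed=2, genome_length=100_000, n_genes=0, clones=20_000,
            hotspots=((40_000, 50.0),), n_libraries=1,
        )
        genome, genes, truth = simulate_genome(params)
        sites = collapse_sites(simulate_library(genome, genes, truth, params))
        windows = flag_hotspots(coverage_windows(sites, genome))
        assert [w.window_start for w in windows if w.hotspot_flag] == [40_000]
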