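import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tnperm import (
    GROUPS,
    crosstab,
    enrich_categories,
    join_tables,
    load_table2,
    spearman_matrix,
)

PARTITION_LEVELS = [
    "partition_species",
    "partition_genus",
    "partition_family",
    "partition_phylum",
]


@pytest.fixture()
def toy_records():
    scores = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "mean_Z": [0.5, -1.0, 1.2]})
    groups = pd.DataFrame(
        {"gene_id": ["g1", "g2", "g3"],
         "group": ["Intermediate", "Less permissive", "Highly permissive"]}
    )
    return scores, groups


class TestJoinTables:
    def test_fully_populated_record(self, toy_records):
        scores, groups = toy_records
        expr = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "expression": [5.0, 2.0, 9.0]})
        records, report = join_tables(scores, groups, {"expression": expr})
        assert records.loc["g1", "expression"] == 5.0
        assert report["tables"]["expression"] == {"matched": 3, "missing": 0}

    def test_missing_side_values_retained_as_na(self, toy_records):
        scores, groups = toy_records
        expr = pd.DataFrame({"gene_id": ["g1"], "expression": [5.0]})
        records, report = join_tables(scores, groups, {"expression": expr})
        assert len(records) == 3  # nothing silently dropped
        assert pd.isna(records.loc["g2", "expression"])
        assert report["n_genes"] == 3
        assert report["tables"]["expression"]["missing"] == 2

    def test_fill_value_for_partition_columns(self, toy_records):
        scores, groups = toy_records
        pang = pd.DataFrame({"gene_id": ["g1"], "partition_species": ["persistent"]})
        records, _ = join_tables(
            scores, groups, {"pangenome": pang}, fill={"partition_species": "absent"}
        )
        assert records.loc["g2", "partition_species"] == "absent"

    def test_duplicate_gene_id_in_side_table_rejected(self, toy_records):
        scores, groups = toy_records
        dup = pd.DataFrame({"gene_id": ["g1", "g1"], "expression": [1.0, 2.0]})
        with pytest.raises(ValueError, match="g1"):
            join_tables(scores, groups, {"expression": dup})


def brute_force_spearman(x, y):
    """Independent oracle: Pearson correlation of hand-computed average ranks."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_increasing_gives_rho_one(self):
        df = pd.DataFrame({"x": np.arange(12.0), "y": 2 * np.arange(12.0)})
        res = spearman_matrix(df, ["x", "y"])
        assert res.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_monotone_decreasing_gives_rho_minus_one(self):
        df = pd.DataFrame({"x": np.arange(12.0), "y": -np.arange(12.0)})
        res = spearman_matrix(df, ["x", "y"])
        assert res.rho.loc["x", "y"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 21))
        x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        y = rng.integers(0, 6, size=n).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        res = spearman_matrix(df, ["x", "y"], min_pairs=10)
        assert res.rho.loc["x", "y"] == pytest.approx(brute_force_spearman(x, y))

    def test_specific_tied_example(self):
        df = pd.DataFrame({"x": [1, 2, 2, 3] * 3, "y": [1, 3, 2, 4] * 3})
        res = spearman_matrix(df, ["x", "y"], min_pairs=4)
        assert res.rho.loc["x", "y"] == pytest.approx(
            brute_force_spearman(df["x"], df["y"])
        )

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        res = spearman_matrix(df, ["a", "b", "c"])
        assert np.allclose(res.rho, res.rho.T)
        assert np.allclose(np.diag(res.rho), 1.0)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.standard_normal(50)})
        df["y"] = rng.standard_normal(50)
        res1 = spearman_matrix(df, ["x", "y"])
        df2 = pd.DataFrame({"x": np.exp(df["x"]), "y": df["y"] ** 3})
        res2 = spearman_matrix(df2, ["x", "y"])
        assert res1.rho.loc["x", "y"] == pytest.approx(res2.rho.loc["x", "y"])

    def test_too_few_pairs_masked(self):
        df = pd.DataFrame({"x": [1.0, 2, np.nan, 4], "y": [2.0, 1, 3, np.nan]})
        res = spearman_matrix(df, ["x", "y"], min_pairs=10)
        assert np.isnan(res.rho.loc["x", "y"])
        assert not res.significant.loc["x", "y"]
        assert res.masked().loc["x", "y"] == "n.s."

    def test_independent_variables_respect_type_i_control(self):
        """Z-scores generated independently of partitions should show weak,
        non-significant correlations at alpha 0.01."""
        rng = np.random.default_rng(7)
        n = 2000
        df = pd.DataFrame(
            {"mean_Z": rng.standard_normal(n),
             "partition_ord": rng.integers(0, 4, size=n).astype(float)}
        )
        res = spearman_matrix(df, ["mean_Z", "partition_ord"], alpha=0.01)
        assert abs(res.rho.loc["mean_Z", "partition_ord"]) < 0.1
        assert not res.significant.loc["mean_Z", "partition_ord"]


class TestCrossTab:
    def test_consensus_essential_fixture_tnseq_tallies(self):
        table2 = load_table2()
        ct = crosstab(table2, "tnseq_group", "partition_species", row_categories=GROUPS)
        assert ct.total == 53
        assert ct.row_marginals["Highly permissive"] == 6
        assert ct.row_marginals["Intermediate"] == 27
        assert ct.row_marginals["Less permissive"] == 20

    def test_consensus_essential_fixture_all_persistent_at_species_level(self):
        table2 = load_table2()
        ct = crosstab(table2, "tnseq_group", "partition_species")
        assert list(ct.table.columns) == ["Persistent"]
        assert ct.col_marginals["Persistent"] == 53

    def test_marginals_consistent_across_levels(self):
        table2 = load_table2()
        for level in PARTITION_LEVELS:
            ct = crosstab(table2, "tnseq_group", level)
            assert ct.total == 53
            assert ct.row_marginals.sum() == ct.col_marginals.sum() == 53

    def test_empty_records_all_zero(self):
        empty = pd.DataFrame({"a": [], "b": []})
        ct = crosstab(empty, "a", "b", row_categories=["x"], col_categories=["y"])
        assert ct.table.loc["x", "y"] == 0
        assert ct.total == 0

    def test_unknown_category_named_in_error(self):
        df = pd.DataFrame({"a": ["x", "typo"], "b": ["y", "y"]})
        with pytest.raises(ValueError, match="typo"):
            crosstab(df, "a", "b", row_categories=["x"])


class TestEnrichment:
    def test_group_equal_to_universe_gives_p_one(self):
        cat = {f"g{i}": "A" if i < 4 else "B" for i in range(10)}
        out = enrich_categories(list(cat), cat)
        assert (out["p"] == 1.0).all()

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # N=4, K=2, n=2, k=2 -> C(2,2)C(2,0)/C(4,2) = 1/6
        cat = {"g1": "A", "g2": "A", "g3": "B", "g4": "B"}
        out = enrich_categories(["g1", "g2"], cat).set_index("category")
        assert out.loc["A", "p"] == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", range(3))
    def test_fisher_p_matches_enumeration_on_small_tables(self, seed):
        """Small universes: the reported p equals the exact hypergeometric tail."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(6, 13))
        genes = [f"g{i}" for i in range(N)]
        cat = {g: ("A" if rng.random() < 0.5 else "B") for g in genes}
        group = [g for g in genes if rng.random() < 0.4]
        out = enrich_categories(group, cat)
        n = len(group)
        for _, row in out.iterrows():
            expected = stats.hypergeom.sf(row["k"] - 1, N, row["K"], n)
            assert row["p"] == pytest.approx(expected)

    def test_benjamini_hochberg_step_up_by_hand(self):
        # q_i = min over j>=i of p_j * m / j  ->  [0.03, 0.03, 0.03]
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(q, [0.03, 0.03, 0.03])
        cat = {"g1": "A", "g2": "B", "g3": "C"}
        out = enrich_categories(["g1"], cat)
        manual = multipletests(out["p"], method="fdr_bh")[1]
        assert np.allclose(out["q"], manual)

    def test_category_absent_from_universe_skipped_with_warning(self):
        cat = pd.Series({"g1": "A", "g2": "B"})
        with pytest.warns(UserWarning, match="absent"):
            out = enrich_categories(["g1"], cat, universe=["g1"])
        assert "B" not in set(out["category"])
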