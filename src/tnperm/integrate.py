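"""Cross-comparison of Tn-seq groups with external gene-level tables.

Joins permissiveness groups with pangenome partitions (persistent / shell /
cloud per taxonomic level), ortholog essentiality counts and expression
levels; computes a masked Spearman correlation matrix, contingency tables
and category enrichment. The side tables are consumed, not computed —
pangenome construction and ortholog mapping are upstream, out-of-scope
pipelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import GROUPS

PARTITIONS = ("persistent", "shell", "cloud", "absent")
#: ordinal coding used when only partition labels (not family sizes) exist
PARTITION_ORDINAL = {"persistent": 3, "shell": 2, "cloud": 1, "absent": 0}


def load_table2() -> pd.DataFrame:
    """The packaged cross-domain consensus-essential gene table.

    53 orthologs essential across a panel of prokaryotic genomes, with their
    Tn-seq permissiveness group and pangenome partition at four taxonomic
    levels (species, genus, family, phylum).
    """
    ref = resources.files("tnperm.data").joinpath("table2_consensus_essentials.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def join_tables(
    scores: pd.DataFrame,
    groups: pd.DataFrame,
    side_tables: Mapping[str, pd.DataFrame],
    fill: Mapping[str, object] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Left-join side tables onto the Tn-seq gene set.

    ``scores`` needs a mean_Z column and gene_id index (or column); ``groups``
    a group column. Every side table must be keyed by a unique gene_id.
    Missing side values become NA (or the ``fill`` value per column), never
    dropped. Returns (records, join report).
    """
    def _indexed(df: pd.DataFrame, what: str) -> pd.DataFrame:
        df = df.copy()
        if df.index.name != "gene_id":
            if "gene_id" not in df.columns:
                raise ValueError(f"{what}: no gene_id key")
            df = df.set_index("gene_id")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"{what}: duplicate gene_id values {dup}")
        return df

    records = _indexed(scores, "scores")[["mean_Z"]].join(
        _indexed(groups, "groups")[["group"]]
    )
    report: dict = {"n_genes": len(records), "tables": {}}
    for name, table in side_tables.items():
        table = _indexed(table, name)
        matched = int(records.index.isin(table.index).sum())
        records = records.join(table, how="left", rsuffix=f"_{name}")
        report["tables"][name] = {"matched": matched, "missing": len(records) - matched}
    if fill:
        for col, value in fill.items():
            if col in records.columns:
                records[col] = records[col].fillna(value)
    return records, report


# ---------------------------------------------------------------------------
# Spearman correlation with significance masking


def _spearman_p(x: np.ndarray, y: np.ndarray, rho: float, seed: int) -> float:
    """Two-sided p-value for Spearman rho.

    Exact permutation enumeration for n <= 8, seeded Monte Carlo permutation
    (10^4 resamples) for n <= 20, t-approximation above.
    """
    n = len(x)
    if abs(rho) >= 1.0 - 1e-12:
        rho = math.copysign(1.0 - 1e-12, rho)
    if n > 20:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2 * stats.t.sf(abs(t), df=n - 2))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    resamples = 10_000
    count = 0
    for _ in range(resamples):
        if abs(np.corrcoef(rx, rng.permutation(ry))[0, 1]) >= obs - 1e-12:
            count += 1
    return (count + 1) / (resamples + 1)


@dataclass
class SpearmanResult:
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # boolean mask (True = p < alpha)
    n_pairs: pd.DataFrame
    alpha: float

    def masked(self) -> pd.DataFrame:
        """Display frame: coefficients where significant, 'n.s.' elsewhere."""
        out = self.rho.round(2).astype(object)
        out[~self.significant] = "n.s."
        np.fill_diagonal(out.values, 1.0)
        return out


def spearman_matrix(
    records: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.01,
    min_pairs: int = 10,
    seed: int = 0,
) -> SpearmanResult:
    """Pairwise Spearman rho (average ranks, pairwise-complete observations).

    Entries with fewer than ``min_pairs`` complete pairs are NaN and masked.
    """
    k = len(variables)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    npairs = np.zeros((k, k), dtype=int)
    cols = {v: pd.to_numeric(records[v], errors="coerce").to_numpy(dtype=float)
            for v in variables}
    for i in range(k):
        npairs[i, i] = int(np.isfinite(cols[variables[i]]).sum())
        for j in range(i + 1, k):
            x, y = cols[variables[i]], cols[variables[j]]
            ok = np.isfinite(x) & np.isfinite(y)
            npairs[i, j] = npairs[j, i] = int(ok.sum())
            if ok.sum() < min_pairs:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r = float(np.corrcoef(stats.rankdata(x[ok]), stats.rankdata(y[ok]))[0, 1])
            p = _spearman_p(x[ok], y[ok], r, seed)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(variables)
    rho_df = pd.DataFrame(rho, index=idx, columns=idx)
    p_df = pd.DataFrame(pval, index=idx, columns=idx)
    sig = (p_df < alpha) & rho_df.notna()
    np.fill_diagonal(sig.values, True)
    return SpearmanResult(rho=rho_df, pvalues=p_df, significant=sig,
                          n_pairs=pd.DataFrame(npairs, index=idx, columns=idx), alpha=alpha)


# ---------------------------------------------------------------------------
# Contingency tables


@dataclass
class CrossTab:
    table: pd.DataFrame  # counts without marginals
    row_var: str
    col_var: str

    @property
    def row_marginals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def col_marginals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def crosstab(
    records: pd.DataFrame,
    row_var: str,
    col_var: str,
    row_categories: Sequence[str] | None = None,
    col_categories: Sequence[str] | None = None,
) -> CrossTab:
    """Contingency counts of two categorical columns (NA rows excluded).

    When an allowed category list is given, any value outside it raises an
    error naming the offender.
    """
    sub = records[[row_var, col_var]].dropna()
    for var, allowed in ((row_var, row_categories), (col_var, col_categories)):
        if allowed is not None:
            unknown = sorted(set(sub[var]) - set(allowed))
            if unknown:
                raise ValueError(f"unknown {var} category value(s): {unknown}")
    table = pd.crosstab(sub[row_var], sub[col_var])
    if row_categories is not None:
        table = table.reindex(index=list(row_categories), fill_value=0)
    if col_categories is not None:
        table = table.reindex(columns=list(col_categories), fill_value=0)
    return CrossTab(table=table, row_var=row_var, col_var=col_var)


# ---------------------------------------------------------------------------
# Category enrichment


def enrich_categories(
    group_genes: Sequence[str],
    category_map: Mapping[str, str] | pd.Series,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-category overrepresentation of a gene group vs the universe.

    One-sided Fisher exact test (hypergeometric upper tail) per category,
    Benjamini-Hochberg FDR across categories. Returns a frame with columns
    category, k (group hits), n (group size), K (category size), N
    (universe), odds_ratio, p, q, sorted by p.
    """
    cat = pd.Series(dict(category_map)) if not isinstance(category_map, pd.Series) else category_map
    if universe is None:
        universe = list(cat.index)
    universe = list(dict.fromkeys(universe))
    group = [g for g in dict.fromkeys(group_genes) if g in set(universe)]
    N, n = len(universe), len(group)
    group_set = set(group)
    rows = []
    for category in sorted(cat.dropna().unique()):
        members = set(cat.index[cat == category]) & set(universe)
        if not members:
            warnings.warn(f"category {category!r} absent from universe; skipped")
            continue
        K = len(members)
        k = len(members & group_set)
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(dict(category=category, k=k, n=n, K=K, N=N, odds_ratio=odds, p=p))
    out = pd.DataFrame(rows, columns=["category", "k", "n", "K", "N", "odds_ratio", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
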