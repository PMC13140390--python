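"""Gene grouping by insertion permissiveness.

Genes are clustered on their per-library Z-score vectors; k-means, k-medoids
(PAM-style) and DBSCAN candidates are compared by average silhouette width
and the winner — expected to be a 2-cluster solution — names the groups:
the cluster with the higher mean Z is "Highly permissive", the other
"Intermediate". Because a unimodal score distribution offers no natural
essentiality threshold, the bottom 20% of genes by mean Z is then
shortlisted as "Less permissive", a quasi-essential candidate set rather
than a statistically called essential set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

HIGHLY_PERMISSIVE = "Highly permissive"
INTERMEDIATE = "Intermediate"
LESS_PERMISSIVE = "Less permissive"
GROUPS = (HIGHLY_PERMISSIVE, INTERMEDIATE, LESS_PERMISSIVE)


# ---------------------------------------------------------------------------
# k-medoids (PAM-style): greedy BUILD initialisation + alternating medoid
# update on a precomputed Euclidean distance matrix.


def _kmedoids_labels(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]  # BUILD: most central point first
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gain = np.maximum(current[:, None] - D, 0).sum(axis=0)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            sub = D[np.ix_(members, members)]
            new_medoids[j] = members[int(np.argmin(sub.sum(axis=0)))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _silhouette(X: np.ndarray, labels: np.ndarray) -> float | None:
    """Average silhouette width, or None when undefined (a single cluster,
    or every cluster a singleton)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or uniq.size > len(labels) - 1 or counts.max() == 1:
        return None
    return float(silhouette_score(X, labels, metric="euclidean"))


@dataclass
class ClusteringComparison:
    """Silhouette table over candidate clusterings, with the winner."""

    table: pd.DataFrame  # method, parameter, n_clusters, silhouette
    labels: dict[tuple[str, str], np.ndarray]
    winner: tuple[str, str] | None

    def winning_labels(self) -> np.ndarray:
        if self.winner is None:
            raise ValueError("no clustering produced a defined silhouette")
        return self.labels[self.winner]


def compare_clusterings(
    Z: np.ndarray | pd.DataFrame,
    methods: Sequence[str] = ("kmeans", "pam", "dbscan"),
    k_range: Sequence[int] = range(2, 7),
    seed: int = 0,
    dbscan_min_samples: int = 5,
) -> ClusteringComparison:
    """Compare clusterings of the genes x libraries Z matrix by silhouette.

    k-means (50 restarts) and PAM over k in ``k_range``; DBSCAN over an eps
    grid of {0.1..2.0 step 0.1} times the median 4-NN distance. Candidates
    whose silhouette is undefined are recorded as missing and can't win.
    """
    X = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 10:
        raise ValueError("need at least 10 genes to compare clusterings")
    rows = []
    all_labels: dict[tuple[str, str], np.ndarray] = {}

    D = None
    if "pam" in methods:
        D = squareform(pdist(X, metric="euclidean"))

    for method in methods:
        if method == "kmeans":
            for k in k_range:
                km = KMeans(n_clusters=k, n_init=50, random_state=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    labels = km.fit_predict(X)
                rows.append(_row("kmeans", f"k={k}", X, labels))
                all_labels[("kmeans", f"k={k}")] = labels
        elif method == "pam":
            for k in k_range:
                labels = _kmedoids_labels(D, k)
                rows.append(_row("pam", f"k={k}", X, labels))
                all_labels[("pam", f"k={k}")] = labels
        elif method == "dbscan":
            nn = NearestNeighbors(n_neighbors=min(5, X.shape[0]))
            nn.fit(X)
            dist4 = nn.kneighbors(X)[0][:, -1]
            base = float(np.median(dist4))
            if base == 0:
                base = 1e-9
            for mult in np.arange(0.1, 2.01, 0.1):
                eps = mult * base
                labels = DBSCAN(eps=eps, min_samples=dbscan_min_samples).fit_predict(X)
                core = labels != -1
                name = f"eps={mult:.1f}*d4"
                if core.sum() >= 2 and np.unique(labels[core]).size >= 2:
                    sil = _silhouette(X[core], labels[core])
                else:
                    sil = None
                n_clusters = int(np.unique(labels[core]).size) if core.any() else 0
                rows.append(
                    dict(method="dbscan", parameter=name, n_clusters=n_clusters,
                         silhouette=np.nan if sil is None else sil)
                )
                all_labels[("dbscan", name)] = labels
        else:
            raise ValueError(f"unknown clustering method {method!r}")

    table = pd.DataFrame(rows, columns=["method", "parameter", "n_clusters", "silhouette"])
    winner = None
    defined = table.dropna(subset=["silhouette"])
    if len(defined):
        best = defined.loc[defined["silhouette"].idxmax()]
        winner = (best["method"], best["parameter"])
    return ClusteringComparison(table=table, labels=all_labels, winner=winner)


def _row(method: str, parameter: str, X: np.ndarray, labels: np.ndarray) -> dict:
    sil = _silhouette(X, labels)
    return dict(
        method=method,
        parameter=parameter,
        n_clusters=int(np.unique(labels).size),
        silhouette=np.nan if sil is None else sil,
    )


@dataclass
class ClassificationResult:
    """Per-gene cluster labels and permissiveness groups."""

    assignments: pd.DataFrame  # index gene_id; columns cluster, mean_Z, group
    boundary_z: float  # mean_Z midpoint between the two clusters' closest members
    silhouette_table: pd.DataFrame | None = None
    shortlist_fraction: float | None = None
    shortlist_size: int | None = None

    def genes_in(self, group: str) -> list[str]:
        return list(self.assignments.index[self.assignments["group"] == group])


def assign_groups(
    score_table: pd.DataFrame,
    labels: Sequence[int],
    silhouette_table: pd.DataFrame | None = None,
) -> ClassificationResult:
    """Name a 2-cluster solution: higher mean mean_Z -> Highly permissive.

    The reported boundary is the mean_Z midpoint between the closest members
    of the two clusters. Group names are invariant to the integer labels.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(
            f"winning clustering has {uniq.size} clusters, need exactly 2; "
            "re-run with a fixed k=2 clustering as fallback"
        )
    mean_z = score_table["mean_Z"]
    means = {lab: float(mean_z[labels == lab].mean()) for lab in uniq}
    hp_label = max(means, key=means.get)
    lo_label = min(means, key=means.get)
    boundary = 0.5 * (
        float(mean_z[labels == hp_label].min()) + float(mean_z[labels == lo_label].max())
    )
    assignments = pd.DataFrame(
        {
            "cluster": labels,
            "mean_Z": mean_z.to_numpy(dtype=float),
            "group": np.where(labels == hp_label, HIGHLY_PERMISSIVE, INTERMEDIATE),
        },
        index=score_table.index,
    )
    return ClassificationResult(
        assignments=assignments,
        boundary_z=boundary,
        silhouette_table=silhouette_table,
    )


def shortlist_less_permissive(
    result: ClassificationResult,
    fraction: float = 0.2,
    within_intermediate: bool = False,
) -> ClassificationResult:
    """Relabel the bottom ceil(fraction * n) genes by mean_Z as Less permissive.

    Boundary ties break by gene_id lexical order. ``within_intermediate``
    restricts the candidate pool to the Intermediate cluster (the shortlist
    size is still a fraction of all genes). A warning is emitted if any
    shortlisted gene had been Highly permissive.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    assignments = result.assignments.copy()
    n = len(assignments)
    size = math.ceil(fraction * n)
    pool = assignments
    if within_intermediate:
        pool = assignments[assignments["group"] == INTERMEDIATE]
        if size > len(pool):
            warnings.warn(
                f"shortlist of {size} exceeds the Intermediate pool ({len(pool)}); truncating"
            )
            size = len(pool)
    order = pool.reset_index().sort_values(["mean_Z", "gene_id"], kind="mergesort")
    chosen = order["gene_id"].iloc[:size]
    if (assignments.loc[chosen, "group"] == HIGHLY_PERMISSIVE).any():
        warnings.warn("shortlist includes genes from the Highly permissive cluster")
    n_distinct = pool["mean_Z"].nunique()
    if size and n_distinct < len(pool) and size < len(pool):
        boundary_val = order["mean_Z"].iloc[size - 1]
        if (order["mean_Z"] == boundary_val).sum() > 1:
            warnings.warn("ties at the shortlist boundary broken by gene_id order")
    assignments.loc[chosen, "group"] = LESS_PERMISSIVE
    return ClassificationResult(
        assignments=assignments,
        boundary_z=result.boundary_z,
        silhouette_table=result.silhouette_table,
        shortlist_fraction=fraction,
        shortlist_size=size,
    )
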