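"""Cohort stratification by expression signatures.

Ward hierarchical clustering on standardized (z-scored) expression, and
cluster x clinical-annotation association by Pearson chi-square with
per-cell standardized residuals flagging enriched/depleted categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "standardize_matrix",
    "ward_cluster",
    "ClusterAssignment",
    "cluster_annotation_enrichment",
    "ContingencyReport",
    "suggest_k",
]


def standardize_matrix(m: pd.DataFrame, log_transform: bool = False) -> pd.DataFrame:
    """Z-score each feature (column) to mean 0, sample sd 1 (ddof=1).

    Zero-variance features are dropped with a warning; if every feature is
    constant a ValueError is raised.  With ``log_transform`` the matrix is
    first mapped through log2(x + 1), the usual preprocessing for
    reads-per-million expression.
    """
    m = m.astype(float)
    if log_transform:
        m = np.log2(m + 1.0)
    sd = m.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant) == len(m.columns):
        raise ValueError("all features have zero variance")
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} zero-variance feature(s): "
            f"{', '.join(map(str, constant[:5]))}{'...' if len(constant) > 5 else ''}",
            stacklevel=2,
        )
        m = m.drop(columns=constant)
        sd = sd.drop(constant)
    return (m - m.mean(axis=0)) / sd


@dataclass
class ClusterAssignment:
    """A flat cut of a Ward dendrogram."""

    labels: pd.Series  # sample_id -> cluster label in 1..k
    k: int
    linkage: np.ndarray  # scipy linkage matrix (merge order and heights)

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.labels.index)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def ward_cluster(m: pd.DataFrame, k: int) -> ClusterAssignment:
    """Agglomerative clustering with Ward's minimum-variance criterion.

    Operates on Euclidean distances between rows (samples) of ``m`` and
    cuts the tree to exactly ``k`` clusters.  SciPy's linkage breaks
    distance ties deterministically by observation order, so the partition
    is reproducible.
    """
    n = len(m)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    Z = hierarchy.linkage(m.to_numpy(dtype=float), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=m.index, name="cluster")
    return ClusterAssignment(labels=labels, k=int(labels.nunique()), linkage=Z)


@dataclass
class ContingencyReport:
    counts: pd.DataFrame  # clusters x categories
    chi2: float
    dof: int
    p_value: float
    residuals: pd.DataFrame  # standardized (adjusted) residuals
    flags: pd.DataFrame  # 'enriched' / 'depleted' / ''


def cluster_annotation_enrichment(
    assign: ClusterAssignment | pd.Series, annotation: pd.Series
) -> ContingencyReport:
    """Pearson chi-square association between clusters and a categorical label.

    The global test is the uncorrected Pearson chi-square with
    df = (r-1)(c-1).  Per-cell calls use standardized (adjusted) residuals
    r_ij = (O - E) / sqrt(E (1 - row_margin)(1 - col_margin)); cells with
    |r_ij| > 1.96 are flagged enriched (positive) or depleted (negative).
    """
    labels = assign.labels if isinstance(assign, ClusterAssignment) else assign
    annotation = annotation.loc[labels.index]
    if annotation.isna().any():
        raise ValueError("every clustered sample must be annotated")
    if annotation.nunique() < 2:
        raise ValueError("need >= 2 annotation categories")

    counts = pd.crosstab(labels, annotation)
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        empty_rows = counts.index[counts.sum(axis=1) == 0].tolist()
        empty_cols = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"empty margin(s): rows {empty_rows}, columns {empty_cols}")

    chi2, p, dof, expected = stats.chi2_contingency(counts.to_numpy(), correction=False)
    n = counts.to_numpy().sum()
    row_m = counts.sum(axis=1).to_numpy() / n
    col_m = counts.sum(axis=0).to_numpy() / n
    denom = np.sqrt(expected * (1 - row_m[:, None]) * (1 - col_m[None, :]))
    resid = (counts.to_numpy() - expected) / denom
    residuals = pd.DataFrame(resid, index=counts.index, columns=counts.columns)
    flags = residuals.map(
        lambda r: "enriched" if r > 1.96 else ("depleted" if r < -1.96 else "")
    )
    return ContingencyReport(
        counts=counts,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        residuals=residuals,
        flags=flags,
    )


def suggest_k(m: pd.DataFrame, k_range=range(2, 7)) -> int:
    """Suggest a cluster count by silhouette score over Ward cuts.

    Advisory only: the pipeline never applies this automatically; choosing
    k remains the analyst's call.
    """
    from sklearn.metrics import silhouette_score

    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= len(m):
            continue
        labels = ward_cluster(m, k).labels
        s = silhouette_score(m.to_numpy(), labels.to_numpy())
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no feasible k in the requested range")
    return best_k
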