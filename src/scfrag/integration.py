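"""Multi-domain feature integration: assembly, PCA and hierarchical clustering.

Follows the ClustVis-style conventions for multivariate overviews of a
two-group cohort: features are centered and unit-variance scaled, the
decomposition is by SVD, and heatmap ordering uses correlation distance
with average linkage.  Component signs are fixed deterministically by
making each component's largest-magnitude loading positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .group_stats import FeatureMatrix, compare_features


def assemble_matrix(
    bundles: Mapping[str, pd.DataFrame],
    groups: pd.Series,
    selection: str = "all",
    Q: float = 0.05,
) -> FeatureMatrix:
    """Join per-module feature bundles into one samples × features matrix.

    ``bundles`` maps a module name to a DataFrame (index = sample ids,
    columns = features); all bundles must cover the same samples.  With
    ``selection="discoveries"`` only features flagged by the two-stage FDR
    at level ``Q`` are retained.
    """
    if not bundles:
        raise ValueError("no feature bundles")
    sample_sets = {name: set(df.index) for name, df in bundles.items()}
    reference = set(groups.index)
    for name, s in sample_sets.items():
        if s != reference:
            missing = sorted(reference - s) + sorted(s - reference)
            raise ValueError(f"bundle {name!r} sample mismatch: {missing}")
    parts = []
    provenance: dict[str, str] = {}
    for name, df in bundles.items():
        df = df.reindex(groups.index)
        dup = set(df.columns) & set(provenance)
        if dup:
            raise ValueError(f"duplicate feature names across bundles: {sorted(dup)}")
        for col in df.columns:
            provenance[col] = name
        parts.append(df)
    values = pd.concat(parts, axis=1)
    matrix = FeatureMatrix(values=values, groups=groups, provenance=provenance)
    if selection == "all":
        return matrix
    if selection != "discoveries":
        raise ValueError(f"unknown selection {selection!r}")
    table = compare_features(matrix, Q=Q)
    keep = list(table.loc[table["discovery"], "feature"])
    if not keep:
        raise ValueError("empty feature set: no discoveries at the given Q")
    return FeatureMatrix(
        values=values[keep],
        groups=groups,
        provenance={k: provenance[k] for k in keep},
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame               # samples × PC1..PCk
    loadings: pd.DataFrame             # features × PC1..PCk
    explained_variance_fraction: np.ndarray
    scaling: str                       # "unit_variance" or "none"
    dropped_features: list[str]


def run_pca(matrix: FeatureMatrix, scaling: str = "unit_variance") -> PcaResult:
    """Centered (and by default unit-variance scaled) PCA by SVD.

    Constant columns are dropped with a warning under unit-variance scaling
    (their z-score is undefined).  Deterministic up to sign, which is fixed
    by making each component's largest-magnitude loading positive.
    """
    if scaling not in ("unit_variance", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = matrix.values.astype(float)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in features: {bad}")
    if len(X) < 2:
        raise ValueError("PCA needs >= 2 samples")
    dropped: list[str] = []
    if scaling == "unit_variance":
        sd = X.std(ddof=1)
        dropped = list(X.columns[sd == 0])
        if dropped:
            warnings.warn(f"dropping constant features under unit-variance scaling: {dropped}")
            X = X.drop(columns=dropped)
        Xs = (X - X.mean()) / X.std(ddof=1)
    else:
        Xs = X - X.mean()
    A = Xs.to_numpy()
    n = A.shape[0]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    k = min(n - 1, A.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        piv = np.argmax(np.abs(Vt[j]))
        if Vt[j, piv] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    var = s**2 / (n - 1)
    total_var = (A**2).sum() / (n - 1)
    frac = var / total_var if total_var > 0 else np.zeros_like(var)
    pcs = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=X.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=pcs),
        explained_variance_fraction=frac,
        scaling=scaling,
        dropped_features=dropped,
    )


def _scaled(matrix: FeatureMatrix, scaling: str) -> pd.DataFrame:
    X = matrix.values.astype(float)
    if scaling == "unit_variance":
        sd = X.std(ddof=1)
        X = X.drop(columns=list(X.columns[sd == 0]))
        return (X - X.mean()) / X.std(ddof=1)
    return X - X.mean()


def cluster_order(
    matrix: FeatureMatrix,
    distance: str = "correlation",
    linkage: str = "average",
    scaling: str = "unit_variance",
) -> dict:
    """Agglomerative clustering of samples (rows) and features (columns).

    Returns row/column leaf orders, the scipy linkage matrices, and Newick
    exports of both trees.  Leaf order is deterministic: scipy breaks ties
    by input order and no leaf-reordering heuristic is applied.
    """
    if len(matrix.values) < 2:
        raise ValueError("clustering needs >= 2 samples")
    X = _scaled(matrix, scaling)

    def _link(data: np.ndarray):
        if distance == "correlation" and data.shape[1] < 2:
            raise ValueError("correlation distance needs >= 2 dimensions")
        d = pdist(data, metric=distance if distance != "euclidean" else "euclidean")
        d = np.nan_to_num(d, nan=1.0)  # correlation distance of flat vectors
        return hierarchy.linkage(d, method=linkage)

    row_link = _link(X.to_numpy())
    col_link = _link(X.to_numpy().T)
    row_order = list(hierarchy.leaves_list(row_link))
    col_order = list(hierarchy.leaves_list(col_link))
    return {
        "row_order": [X.index[i] for i in row_order],
        "col_order": [X.columns[i] for i in col_order],
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_newick": linkage_to_newick(row_link, list(X.index)),
        "col_newick": linkage_to_newick(col_link, list(X.columns)),
    }


def cut_two(linkage_matrix: np.ndarray) -> np.ndarray:
    """Labels from cutting a dendrogram into two clusters."""
    return hierarchy.fcluster(linkage_matrix, t=2, criterion="maxclust")


def linkage_to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage_matrix)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
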