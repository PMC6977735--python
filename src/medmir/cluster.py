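"""Hierarchical clustering of samples and the pair-cohesion statistic.

Samples are clustered on a feature x sample matrix (miRNA expression or DMR
methylation scores) using 1 - Pearson correlation over pairwise-complete
features (the Cluster 3.0 convention) or Euclidean distance rescaled for
missingness, with average linkage by default.  A patient pair is "cohesive"
when its primary and recurrent samples are direct siblings — merged with
each other at their first join in the dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage

from .errors import DistanceUndefinedError, InputError

DISTANCES = ("pearson", "euclidean")
LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterTree:
    """An agglomeration result in scipy linkage convention: leaves are nodes
    0..n-1; merge row k joins nodes Z[k,0] and Z[k,1] at height Z[k,2] into
    node n+k."""

    labels: list[str]
    merges: np.ndarray  # (n-1, 4) scipy linkage matrix

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: _quote(self.labels[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node = n + k
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            height[node] = h
        return text[2 * n - 2] + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;"):
        return "'" + label.replace("'", "''") + "'"
    return label


def pairwise_complete_distances(
    matrix: pd.DataFrame, distance: str = "pearson"
) -> pd.DataFrame:
    """Sample-by-sample dissimilarities on a feature x sample matrix.

    pearson: 1 - centered Pearson correlation over features observed in both
    samples (requires >= 2 shared features).  euclidean: squared differences
    over shared features, scaled up by n_features / n_shared before the
    square root, so sparsely shared pairs are not spuriously close.
    """
    if distance not in DISTANCES:
        raise InputError(f"unknown distance: {distance}")
    cols = list(matrix.columns)
    if len(cols) < 2:
        raise InputError("need at least two samples to cluster")
    if distance == "pearson":
        corr = matrix.corr(method="pearson", min_periods=2)
        bad = np.argwhere(np.isnan(corr.values))
        for i, j in bad:
            if i < j:
                raise DistanceUndefinedError(
                    f"samples {cols[i]!r} and {cols[j]!r} share <2 observed "
                    "features (or have zero variance)"
                )
        d = 1.0 - corr.values
    else:
        X = matrix.to_numpy(dtype=float)
        n_feat = X.shape[0]
        d = np.zeros((len(cols), len(cols)))
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                both = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
                n_shared = int(both.sum())
                if n_shared == 0:
                    raise DistanceUndefinedError(
                        f"samples {cols[i]!r} and {cols[j]!r} share no observed features"
                    )
                ss = float(((X[both, i] - X[both, j]) ** 2).sum())
                d[i, j] = d[j, i] = np.sqrt(ss * n_feat / n_shared)
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # guard tiny negative from 1 - corr rounding above 1
    return pd.DataFrame(d, index=cols, columns=cols)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of the columns of a feature x sample matrix."""
    if linkage not in LINKAGES:
        raise InputError(f"unknown linkage: {linkage}")
    dmat = pairwise_complete_distances(matrix, distance)
    n = dmat.shape[0]
    condensed = dmat.values[np.triu_indices(n, k=1)]
    Z = scipy_linkage(condensed, method=linkage)
    return ClusterTree(labels=list(matrix.columns), merges=Z)


def pair_cohesion(
    tree: ClusterTree, pair_map: dict[str, tuple[str, str]]
) -> tuple[int, list[str]]:
    """Count pairs whose two samples are direct siblings in the tree.

    ``pair_map`` maps pair id to its (primary sample, recurrent sample)
    labels.  A pair is cohesive iff its two leaves are merged directly with
    each other at their first merge.
    """
    index = {label: i for i, label in enumerate(tree.labels)}
    n = tree.n_leaves
    sibling_leaf_pairs = set()
    for a, b, _, _ in tree.merges:
        a, b = int(a), int(b)
        if a < n and b < n:
            sibling_leaf_pairs.add(frozenset((a, b)))
    cohesive = []
    for pair_id, (s1, s2) in pair_map.items():
        if s1 not in index or s2 not in index:
            raise InputError(f"pair {pair_id}: sample missing from tree")
        if frozenset((index[s1], index[s2])) in sibling_leaf_pairs:
            cohesive.append(pair_id)
    return len(cohesive), sorted(cohesive)
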