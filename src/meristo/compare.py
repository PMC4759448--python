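"""Cross-collection comparison of meristograms.

Interpolated meristograms live on an integer percent-position grid, so a
set of collections can be concatenated into one feature matrix (rows =
collections, columns = (variable, position) pairs restricted to the grid
shared by all inputs).  Principal component analysis of that matrix
reduces the curves to a few axes of shape variation, and UPGMA clustering
of the leading PC scores under several distance metrics renders the
between-taxon structure as ultrametric dendrograms.  Agreement of the
dendrograms across metrics is the usual robustness check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import Meristogram, VARIABLES

__all__ = [
    "PCAResult",
    "DendroNode",
    "build_feature_matrix",
    "run_pca",
    "pairwise_distances",
    "upgma",
    "write_newick",
    "METRICS",
]

METRICS = ("euclidean", "manhattan", "maximum", "minkowski")


def build_feature_matrix(ms: Sequence[Meristogram]) -> pd.DataFrame:
    """Concatenate interpolated meristograms into a collections × (variable,
    position) matrix on the common integer grid.

    The grid is the intersection of the inputs' position ranges; an empty
    intersection or a non-interpolated input is an error.
    """
    if len(ms) < 2:
        raise ValueError("need at least two meristograms to build a feature matrix")
    for m in ms:
        if not m.interpolated:
            raise ValueError(
                f"meristogram {m.label!r} is not interpolated; recompute with "
                "interpolation enabled to obtain a common position grid"
            )
    mais = {m.mai for m in ms}
    if len(mais) > 1:
        raise ValueError(
            f"meristograms computed at different moving-average intervals {sorted(mais)}; "
            "use a single common interval"
        )
    lo = max(int(m.x.min()) for m in ms)
    hi = min(int(m.x.max()) for m in ms)
    if lo > hi:
        raise ValueError("position ranges of the meristograms do not overlap")
    grid = np.arange(lo, hi + 1)

    columns = pd.MultiIndex.from_tuples(
        [(v, int(x)) for v in VARIABLES for x in grid], names=["variable", "position"]
    )
    data = []
    for m in ms:
        x = m.x.astype(int)
        sel = np.isin(x, grid)
        row = np.concatenate([m.curve(v)[sel] for v in VARIABLES])
        data.append(row)
    labels = [m.label for m in ms]
    if len(set(labels)) != len(labels):
        raise ValueError("meristogram labels must be unique")
    return pd.DataFrame(data, index=labels, columns=columns)


@dataclass(frozen=True)
class PCAResult:
    """Scores (collections × components), loadings (features × components)
    and per-component variance fractions of a covariance PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    column_means: pd.Series


def run_pca(fm: pd.DataFrame) -> PCAResult:
    """Covariance PCA of the feature matrix: columns are mean-centered but
    not variance-scaled (all features already share the percent scale).

    The sign of each component is fixed so that the largest-magnitude
    loading entry is positive; components are ordered by decreasing
    variance and their fractions sum to 1.
    """
    if fm.shape[0] < 2:
        raise ValueError("PCA needs at least two collections")
    X = fm.to_numpy(dtype=float)
    means = X.mean(axis=0)
    Xc = X - means
    if not np.any(Xc):
        raise ValueError("feature matrix has zero variance; collections are identical")
    # economy SVD: at most n_rows-1 informative components
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(fm.shape[0] - 1, fm.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    signs = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=fm.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=fm.columns, columns=comp_names)
    var = s**2
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=var / var.sum(),
        column_means=pd.Series(means, index=fm.columns),
    )


def pairwise_distances(
    scores: pd.DataFrame, metric: str = "euclidean", *, minkowski_p: float = 3.0
) -> pd.DataFrame:
    """Symmetric distance matrix over collections under one of the four
    supported metrics (maximum = Chebyshev; Minkowski exponent defaults to
    3 so it is distinct from Euclidean)."""
    if len(scores) < 2:
        raise ValueError("need at least two score vectors")
    X = scores.to_numpy(dtype=float)
    if metric == "euclidean":
        d = pdist(X, "euclidean")
    elif metric == "manhattan":
        d = pdist(X, "cityblock")
    elif metric == "maximum":
        d = pdist(X, "chebyshev")
    elif metric == "minkowski":
        if not minkowski_p > 0:
            raise ValueError(f"Minkowski exponent must be positive, got {minkowski_p}")
        d = pdist(X, "minkowski", p=minkowski_p)
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return pd.DataFrame(squareform(d), index=scores.index, columns=scores.index)


@dataclass(frozen=True)
class DendroNode:
    """Node of a rooted ultrametric dendrogram; leaves carry labels and
    height 0, internal nodes sit at half their merge distance."""

    height: float
    children: tuple["DendroNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaf_labels())
        return tuple(out)

    def clades(self) -> frozenset[frozenset[str]]:
        """All non-trivial leaf bipartitions below this node — the topology,
        independent of heights and child order."""
        out: set[frozenset[str]] = set()

        def walk(node: "DendroNode") -> frozenset[str]:
            if node.is_leaf:
                return frozenset({node.label})
            leaves = frozenset().union(*(walk(ch) for ch in node.children))
            out.add(leaves)
            return leaves

        walk(self)
        return frozenset(out)

    def to_newick(self) -> str:
        def quote(label: str) -> str:
            if any(ch in label for ch in " ()[]:;,'\t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def fmt(node: "DendroNode", parent_height: float | None) -> str:
            if node.is_leaf:
                body = quote(node.label)
            else:
                body = "(" + ",".join(fmt(ch, node.height) for ch in node.children) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.10g}"

        return fmt(self, None) + ";"


def upgma(d: pd.DataFrame, labels: Sequence[str] | None = None) -> DendroNode:
    """Classic UPGMA (size-weighted average linkage) on a distance matrix.

    Node heights are half the merge distance, so the tree is ultrametric.
    Ties in the minimum inter-cluster distance resolve to the pair whose
    sorted leaf-label tuples are lexicographically smallest, which makes the
    result platform-independent.
    """
    D = np.asarray(d, dtype=float)
    if labels is None:
        labels = list(d.index) if isinstance(d, pd.DataFrame) else [str(i) for i in range(len(D))]
    labels = list(labels)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ValueError("distance matrix must be square and match the labels")
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")

    clusters: dict[int, DendroNode] = {
        i: DendroNode(height=0.0, label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in clusters}
    dist = {
        (i, j): float(D[i, j])
        for i, j in itertools.combinations(range(len(labels)), 2)
    }

    def key(i: int) -> tuple[str, ...]:
        return tuple(sorted(clusters[i].leaf_labels()))

    next_id = len(labels)
    while len(clusters) > 1:
        (i, j), dmin = min(
            dist.items(), key=lambda kv: (kv[1], tuple(sorted((key(kv[0][0]), key(kv[0][1])))))
        )
        merged = DendroNode(height=dmin / 2.0, children=(clusters[i], clusters[j]))
        ni, nj = sizes[i], sizes[j]
        del clusters[i], clusters[j]
        for k_ in list(clusters):
            dik = dist.pop((min(i, k_), max(i, k_)))
            djk = dist.pop((min(j, k_), max(j, k_)))
            dist[(k_, next_id)] = (ni * dik + nj * djk) / (ni + nj)
        del dist[(i, j)], sizes[i], sizes[j]
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        next_id += 1

    return next(iter(clusters.values()))


def write_newick(tree: DendroNode, path: str | Path) -> None:
    """Serialize the dendrogram to a Newick file with branch lengths derived
    from node heights."""
    Path(path).write_text(tree.to_newick() + "\n")
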