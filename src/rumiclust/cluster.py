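"""Hierarchical clustering, ordination and extreme-cow selection.

Cows are clustered from the precomputed DTW distance matrix by agglomerative
hierarchical clustering (agnes-style, average linkage by default), the
dendrogram is cut at k clusters, the structure strength is summarised by the
agglomerative coefficient, and the cows are placed in a 2-D ordination by
principal coordinates analysis (classical MDS) of the distance matrix.  The
study cohort is then drawn deterministically: the most extreme cows along
ordination axis 1 in each cluster, paired across clusters by parity, days in
milk and milk yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dtw import DistanceMatrix

__all__ = [
    "ClusterTree",
    "ClusterAssignment",
    "Ordination",
    "SelectionResult",
    "SelectionShortfallError",
    "agglomerative_cluster",
    "agglomerative_coefficient",
    "cut_tree",
    "pcoa",
    "select_extremes",
    "AgnesClustering",
    "PCoA",
]

_LINKAGES = ("average", "complete", "single")


class SelectionShortfallError(ValueError):
    """A cluster holds fewer cows than the requested selection size."""


@dataclass
class ClusterTree:
    """Agglomeration history: scipy linkage matrix plus leaf labels."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    linkage: str = "average"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


@dataclass
class ClusterAssignment:
    """Flat k-cluster labelling; cluster labels are 1..k ordered by
    decreasing size (ties: smallest member index first)."""

    labels: dict[str, int]
    k: int
    agglomerative_coefficient: float

    def members(self, label: int) -> list[str]:
        return [c for c, l in self.labels.items() if l == label]


@dataclass
class Ordination:
    """Principal-coordinates embedding of the cows."""

    labels: tuple[str, ...]
    coordinates: np.ndarray        # (n, 2)
    eigenvalues: np.ndarray        # all n, nonincreasing (negatives reported)
    proportion_explained: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cow_id": self.labels,
                             "axis1": self.coordinates[:, 0],
                             "axis2": self.coordinates[:, 1]})


@dataclass
class SelectionResult:
    selected: dict[int, list[str]]          # cluster label -> ordered cow ids
    blocking_report: pd.DataFrame
    shortfall: dict[int, int]               # cluster label -> missing count


def _as_matrix(d) -> tuple[tuple[str, ...], np.ndarray]:
    if isinstance(d, DistanceMatrix):
        return d.labels, d.values
    values = np.asarray(d, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(values < 0):
        raise ValueError("distances must be nonnegative")
    return tuple(str(i) for i in range(len(values))), values


def agglomerative_cluster(d, linkage: str = "average") -> ClusterTree:
    """Agglomerative hierarchical clustering of a precomputed distance matrix."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    labels, values = _as_matrix(d)
    if len(labels) < 2:
        raise ValueError("need at least 2 cows to cluster")
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(labels, Z, linkage)


def agglomerative_coefficient(tree: ClusterTree) -> float:
    """agnes-style structure statistic in [0, 1].

    For each leaf i let m(i) be the height at which it first merges; the
    coefficient is the mean of 1 - m(i)/h_max, where h_max is the final merge
    height.  0 means no structure (all merges at one height), values near 1
    mean tight clusters joined late.
    """
    n = len(tree.labels)
    if n < 3:
        raise ValueError("agglomerative coefficient needs at least 3 leaves")
    heights = tree.merge_heights
    h_max = float(heights.max())
    if h_max <= 0:
        return 0.0
    first_merge = np.full(n, np.nan)
    for row in range(len(heights)):
        for node in tree.linkage_matrix[row, :2]:
            node = int(node)
            if node < n and np.isnan(first_merge[node]):
                first_merge[node] = heights[row]
    return float(np.mean(1.0 - first_merge / h_max))


def cut_tree(tree: ClusterTree, k: int) -> ClusterAssignment:
    """Cut the dendrogram into k clusters (remove the k-1 highest merges)."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    flat = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    # Relabel: 1..k by decreasing size, ties by smallest member index.
    order = sorted(set(flat),
                   key=lambda c: (-(flat == c).sum(), int(np.argmax(flat == c))))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = {cow: remap[c] for cow, c in zip(tree.labels, flat)}
    coef = agglomerative_coefficient(tree) if n >= 3 else float("nan")
    return ClusterAssignment(labels, k, coef)


def pcoa(d) -> Ordination:
    """Principal coordinates (classical MDS) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns the top-2 axes
    scaled by the square roots of their eigenvalues.  Negative eigenvalues
    (non-Euclidean distances) are reported but their axes are excluded.
    """
    labels, values = _as_matrix(d)
    n = len(labels)
    if n < 3:
        raise ValueError("pcoa needs at least 3 points")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (values ** 2) @ J
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-12
    coords = np.zeros((n, 2))
    for axis in range(2):
        if axis < len(eigval) and eigval[axis] > tol:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])
    pos_sum = eigval[eigval > tol].sum()
    prop = np.where(eigval > tol, eigval / pos_sum, 0.0) if pos_sum > 0 \
        else np.zeros_like(eigval)
    return Ordination(labels, coords, eigval, prop)


def select_extremes(ordination: Ordination, assignment: ClusterAssignment,
                    metadata: pd.DataFrame, n_per_cluster: int,
                    blocking: tuple[str, ...] = ("parity", "dim", "my"),
                    strict: bool = True) -> SelectionResult:
    """Pick the study cohort: extreme cows on ordination axis 1, blocked
    across the two clusters.

    Within each cluster cows are ranked by |axis-1 coordinate| (most extreme
    first).  Pairs are formed greedily: the next most extreme unused cow of
    cluster 1 is matched to the unused cluster-2 cow with equal parity when
    possible, minimising |dDIM|/sd(DIM) + |dMY|/sd(MY); ties go to the more
    extreme, then the smaller id.  ``metadata`` must be indexed by cow_id
    with the blocking columns.
    """
    if assignment.k != 2:
        raise ValueError("extreme selection is defined for k=2 clusters")
    missing = [c for c in assignment.labels if c not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing for cows: {missing[:5]}")

    axis1 = dict(zip(ordination.labels, ordination.coordinates[:, 0]))

    def ranked(label: int) -> list[str]:
        cows = assignment.members(label)
        return sorted(cows, key=lambda c: (-abs(axis1[c]), c))

    c1, c2 = ranked(1), ranked(2)
    shortfall = {lab: max(0, n_per_cluster - len(cows))
                 for lab, cows in ((1, c1), (2, c2))}
    if strict and any(shortfall.values()):
        short = {k: v for k, v in shortfall.items() if v}
        raise SelectionShortfallError(
            f"cluster(s) too small for n_per_cluster={n_per_cluster}: "
            + ", ".join(f"cluster {k} short by {v}" for k, v in short.items()))

    # Normalising scales for the continuous blocking variables.
    scales = {}
    for var in blocking:
        if var == "parity":
            continue
        sd = float(metadata[var].std(ddof=0))
        scales[var] = sd if sd > 0 else 1.0

    def score(a: str, b: str) -> float:
        return sum(abs(float(metadata.loc[a, v]) - float(metadata.loc[b, v]))
                   / scales[v] for v in scales)

    n1 = min(n_per_cluster, len(c1))
    n2 = min(n_per_cluster, len(c2))
    used2: set[str] = set()
    rows = []
    sel1: list[str] = []
    sel2: list[str] = []
    for rank, a in enumerate(c1[:n1], start=1):
        avail = [b for b in c2 if b not in used2]
        partner = None
        if avail and len(sel2) < n2:
            exact = ([b for b in avail
                      if "parity" in blocking
                      and metadata.loc[b, "parity"] == metadata.loc[a, "parity"]]
                     if "parity" in blocking else [])
            pool = exact or avail
            partner = min(pool, key=lambda b: (score(a, b),
                                               -abs(axis1[b]), b))
            used2.add(partner)
            sel2.append(partner)
        sel1.append(a)
        rows.append({
            "rank": rank, "cluster1_cow": a, "cluster2_cow": partner,
            "parity_match": (partner is not None and "parity" in blocking
                             and bool(metadata.loc[a, "parity"]
                                      == metadata.loc[partner, "parity"])),
            **{f"delta_{v}": (abs(float(metadata.loc[a, v])
                                  - float(metadata.loc[partner, v]))
                              if partner is not None else np.nan)
               for v in scales},
        })
    # Any unmatched cluster-2 slots (cluster 1 smaller): fill by extremeness.
    while len(sel2) < n2:
        extra = next(b for b in c2 if b not in used2)
        used2.add(extra)
        sel2.append(extra)

    report = pd.DataFrame(rows)
    return SelectionResult({1: sel1, 2: sel2}, report, shortfall)


class AgnesClustering:
    """sklearn-style clusterer over a precomputed distance matrix.

    Parameters mirror agnes: ``linkage`` in {average, complete, single} and a
    flat cut at ``n_clusters``.  Fitted attributes: ``labels_`` (1..k ints in
    input order), ``tree_``, ``merge_heights_``, ``agglomerative_coefficient_``.
    """

    def __init__(self, n_clusters: int = 2, linkage: str = "average"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "linkage": self.linkage}

    def set_params(self, **params) -> "AgnesClustering":
        for k, v in params.items():
            if k not in ("n_clusters", "linkage"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "AgnesClustering":
        tree = agglomerative_cluster(X, self.linkage)
        assignment = cut_tree(tree, self.n_clusters)
        self.tree_ = tree
        self.assignment_ = assignment
        self.merge_heights_ = tree.merge_heights
        self.agglomerative_coefficient_ = assignment.agglomerative_coefficient
        self.labels_ = np.array([assignment.labels[c] for c in tree.labels])
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


class PCoA:
    """sklearn-style transformer: classical MDS of a distance matrix.

    ``fit_transform(X)`` returns the (n, 2) coordinates; eigenvalues and
    per-axis variance fractions are exposed as fitted attributes.
    """

    def __init__(self, n_components: int = 2):
        if n_components != 2:
            raise ValueError("only the 2-axis ordination used downstream is supported")
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "PCoA":
        for k, v in params.items():
            if k != "n_components":
                raise ValueError(f"unknown parameter {k!r}")
        return self

    def fit(self, X, y=None) -> "PCoA":
        ord_ = pcoa(X)
        self.ordination_ = ord_
        self.coordinates_ = ord_.coordinates
        self.eigenvalues_ = ord_.eigenvalues
        self.proportion_explained_ = ord_.proportion_explained
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "coordinates_"):
            raise RuntimeError("PCoA is not fitted")
        return self.coordinates_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform()
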