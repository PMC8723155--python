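"""Hierarchical clustering trees, heap-style cluster IDs and valid cluster pairs.

The subgroup-identification workflow starts from an agglomerative clustering
of the samples.  This module builds that tree (or ingests one computed
elsewhere, e.g. on a fused multi-omics distance), numbers the clusters the way
a reader numbers a printed dendrogram (full cohort = cluster 1, the split of
rank k by decreasing height yields children 2k and 2k+1), and enumerates the
"valid" branch points -- those where both subclusters reach a minimum size and
are therefore worth testing against clinical outcomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MergeTree",
    "ClusterPair",
    "build_tree",
    "assign_cluster_ids",
    "enumerate_valid_pairs",
    "resolve_min_size",
    "SUPPORTED_LINKAGES",
    "SUPPORTED_METRICS",
]

#: Linkage rules accepted by :func:`build_tree`.
SUPPORTED_LINKAGES = ("ward", "average", "complete", "single", "weighted", "centroid", "median")

#: Common distance metrics; any metric scipy's ``pdist`` knows is accepted,
#: this tuple is only used for the error message on unknown names.
SUPPORTED_METRICS = (
    "euclidean", "sqeuclidean", "cityblock", "cosine", "correlation",
    "chebyshev", "canberra", "braycurtis", "hamming", "jaccard",
)

#: Linkages for which merge heights are guaranteed non-decreasing.
_MONOTONE_LINKAGES = frozenset({"ward", "average", "complete", "single", "weighted"})


@dataclass
class MergeTree:
    """Result of agglomerative clustering over ``n_leaves`` samples.

    ``merges`` follows the scipy convention: row ``i`` merges two children into
    node ``n_leaves + i``; a child index below ``n_leaves`` is a leaf, anything
    else refers to an earlier merge.  ``heights[i]`` is the linkage distance at
    which merge ``i`` happened.
    """

    leaf_ids: list
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float
    linkage: str | None = None

    def __post_init__(self):
        self.leaf_ids = list(self.leaf_ids)
        self.merges = np.asarray(self.merges, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        self.validate()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def validate(self) -> None:
        n = self.n_leaves
        if n < 2:
            raise ValueError("a merge tree needs at least 2 leaves")
        if len(set(self.leaf_ids)) != n:
            raise ValueError("leaf_ids must be unique")
        if self.merges.shape != (n - 1, 2):
            raise ValueError(f"expected {n - 1} merges, got shape {self.merges.shape}")
        if self.heights.shape != (n - 1,):
            raise ValueError("heights length must equal number of merges")
        if np.any(self.heights < 0):
            raise ValueError("merge heights must be non-negative")
        # every leaf and every non-final merge node referenced exactly once
        refs = self.merges.ravel()
        expected = np.arange(2 * n - 2)
        if not np.array_equal(np.sort(refs), expected):
            raise ValueError("each leaf and non-final merge must appear exactly once as a child")
        for i in range(n - 1):
            for c in self.merges[i]:
                if c >= n + i:
                    raise ValueError(f"merge {i} references a later node {c}")
        if self.linkage in _MONOTONE_LINKAGES and np.any(np.diff(self.heights) < -1e-9):
            warnings.warn(
                f"merge heights are not monotone for linkage '{self.linkage}'",
                UserWarning,
                stacklevel=2,
            )

    # -- conversions -----------------------------------------------------

    @classmethod
    def from_linkage(cls, Z: np.ndarray, leaf_ids, linkage: str | None = None) -> "MergeTree":
        """Build from a scipy linkage matrix (4 columns)."""
        Z = np.asarray(Z, dtype=float)
        return cls(leaf_ids=leaf_ids, merges=Z[:, :2].astype(int), heights=Z[:, 2], linkage=linkage)

    def to_linkage(self) -> np.ndarray:
        """Return the scipy-style linkage matrix (with cluster sizes)."""
        n = self.n_leaves
        sizes = np.empty(n - 1)
        for i, (a, b) in enumerate(self.merges):
            sa = 1 if a < n else sizes[a - n]
            sb = 1 if b < n else sizes[b - n]
            sizes[i] = sa + sb
        return np.column_stack([self.merges.astype(float), self.heights, sizes])

    def members(self) -> list[frozenset]:
        """Member sample-ID sets for every merge node, in merge order."""
        n = self.n_leaves
        sets: list[frozenset] = []
        for a, b in self.merges:
            sa = frozenset([self.leaf_ids[a]]) if a < n else sets[a - n]
            sb = frozenset([self.leaf_ids[b]]) if b < n else sets[b - n]
            sets.append(sa | sb)
        return sets

    def leaf_order(self) -> list[int]:
        """Leaf indices in dendrogram display order."""
        return hierarchy.leaves_list(self.to_linkage()).tolist()

    # -- export ----------------------------------------------------------

    def to_merge_table(self) -> pd.DataFrame:
        """4-column merge table: child_a, child_b, height, size."""
        Z = self.to_linkage()
        return pd.DataFrame(
            {
                "child_a": Z[:, 0].astype(int),
                "child_b": Z[:, 1].astype(int),
                "height": Z[:, 2],
                "size": Z[:, 3].astype(int),
            }
        )

    @classmethod
    def from_merge_table(cls, table: pd.DataFrame, leaf_ids, linkage: str | None = None) -> "MergeTree":
        """Ingest an externally computed merge table (child_a, child_b, height[, size])."""
        return cls(
            leaf_ids=leaf_ids,
            merges=table[["child_a", "child_b"]].to_numpy(dtype=int),
            heights=table["height"].to_numpy(dtype=float),
            linkage=linkage,
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths equal to height differences."""
        n = self.n_leaves

        def node_height(idx: int) -> float:
            return 0.0 if idx < n else self.heights[idx - n]

        def emit(idx: int, parent_height: float) -> str:
            bl = parent_height - node_height(idx)
            if idx < n:
                return f"{self.leaf_ids[idx]}:{bl:g}"
            a, b = self.merges[idx - n]
            h = self.heights[idx - n]
            return f"({emit(a, h)},{emit(b, h)}):{bl:g}"

        a, b = self.merges[-1]
        h = self.heights[-1]
        return f"({emit(a, h)},{emit(b, h)});"


@dataclass
class ClusterPair:
    """One branching point of the tree: left vs right subcluster.

    Cluster IDs are heap-style: the split of rank ``k`` (splits ranked by
    decreasing merge height) produces children ``2k`` (left) and ``2k+1``
    (right); the whole cohort is cluster 1.
    """

    split_rank: int
    cid_left: int
    cid_right: int
    members_left: frozenset
    members_right: frozenset
    parent_cid: int
    height: float
    is_valid: bool | None = None

    @property
    def n_left(self) -> int:
        return len(self.members_left)

    @property
    def n_right(self) -> int:
        return len(self.members_right)


def _as_condensed_distance(data, distance, sample_ids):
    """Return a condensed distance vector from a metric name or a precomputed matrix."""
    if isinstance(distance, str):
        metric = distance.lower()
        try:
            d = pdist(np.asarray(data, dtype=float), metric=metric)
        except ValueError as exc:
            raise ValueError(
                f"unknown distance metric '{distance}'; common options: "
                + ", ".join(SUPPORTED_METRICS)
            ) from exc
    else:
        if isinstance(distance, pd.DataFrame):
            mat = distance.reindex(index=sample_ids, columns=sample_ids).to_numpy(dtype=float)
            if np.isnan(mat).any() and not np.isnan(np.asarray(distance, dtype=float)).any():
                missing = [s for s in sample_ids if s not in distance.index]
                raise ValueError(f"precomputed distance is missing samples: {missing}")
        else:
            mat = np.asarray(distance, dtype=float)
        n = len(sample_ids)
        if mat.shape != (n, n):
            raise ValueError(f"precomputed distance must be {n}x{n}, got {mat.shape}")
        if not np.allclose(mat, mat.T, atol=1e-8, equal_nan=True):
            raise ValueError("precomputed distance matrix is not symmetric")
        if not np.allclose(np.diag(mat), 0.0):
            raise ValueError("precomputed distance matrix must have a zero diagonal")
        d = squareform(mat, checks=False)
    if not np.all(np.isfinite(d)):
        bad = np.argwhere(~np.isfinite(squareform(d)))
        i, j = bad[0]
        raise ValueError(
            f"non-finite distance between samples '{sample_ids[i]}' and '{sample_ids[j]}'"
        )
    return d


def build_tree(data, distance="euclidean", linkage="ward") -> MergeTree:
    """Hierarchically cluster samples into a :class:`MergeTree`.

    Parameters
    ----------
    data : pandas.DataFrame or array-like
        Samples x features matrix; the index provides sample IDs.  May be
        ``None`` when ``distance`` is a precomputed matrix with IDs.
    distance : str or array-like
        A metric name (passed to scipy ``pdist``) or a precomputed square,
        symmetric, zero-diagonal distance matrix.
    linkage : str
        One of ``ward, average, complete, single, weighted, centroid, median``.
    """
    if linkage not in SUPPORTED_LINKAGES:
        raise ValueError(
            f"unknown linkage '{linkage}'; supported: " + ", ".join(SUPPORTED_LINKAGES)
        )
    if data is None:
        if isinstance(distance, pd.DataFrame):
            sample_ids = list(distance.index)
            values = None
        else:
            raise ValueError("either data or an ID-labeled precomputed distance is required")
    elif isinstance(data, pd.DataFrame):
        sample_ids = list(data.index)
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        sample_ids = list(range(values.shape[0]))
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample IDs must be unique")

    d = _as_condensed_distance(values, distance, sample_ids)
    Z = hierarchy.linkage(d, method=linkage)
    return MergeTree.from_linkage(Z, sample_ids, linkage=linkage)


def assign_cluster_ids(tree: MergeTree) -> list[ClusterPair]:
    """Enumerate all n-1 splits with heap-style cluster IDs, validity unset.

    Splits are ranked by decreasing merge height; ties go to the split whose
    parent cluster was created later in merge order.  Within a split, the side
    containing the sample with the smallest input position is "left".
    """
    n = tree.n_leaves
    member_sets = tree.members()
    pos = {sid: i for i, sid in enumerate(tree.leaf_ids)}

    # rank merges by decreasing height, ties: later merge first
    order = sorted(range(n - 1), key=lambda i: (-tree.heights[i], -i))
    rank_of = {m: k + 1 for k, m in enumerate(order)}  # merge idx -> 1-based rank

    # cluster ID of each node: root is 1, child of rank-k split is 2k / 2k+1
    def side_sets(m):
        a, b = tree.merges[m]
        sa = frozenset([tree.leaf_ids[a]]) if a < n else member_sets[a - n]
        sb = frozenset([tree.leaf_ids[b]]) if b < n else member_sets[b - n]
        if min(pos[s] for s in sa) <= min(pos[s] for s in sb):
            return sa, sb, a, b
        return sb, sa, b, a

    cid_of_node: dict[int, int] = {2 * n - 2: 1}  # root merge node
    for m in range(n - 1):
        k = rank_of[m]
        _, _, left_node, right_node = side_sets(m)
        cid_of_node[left_node] = 2 * k
        cid_of_node[right_node] = 2 * k + 1

    pairs = []
    for k, m in enumerate(order, start=1):
        left, right, _, _ = side_sets(m)
        pairs.append(
            ClusterPair(
                split_rank=k,
                cid_left=2 * k,
                cid_right=2 * k + 1,
                members_left=left,
                members_right=right,
                parent_cid=cid_of_node[n + m],
                height=float(tree.heights[m]),
            )
        )
    return pairs


def resolve_min_size(min_size, n: int) -> int:
    """Convert a size threshold to a count: fractions round up (ceiling)."""
    if min_size is None:
        min_size = 0.05
    if 0 < min_size < 1:
        return math.ceil(min_size * n)
    count = int(min_size)
    if count < 1 or count != min_size:
        raise ValueError("min_size must be a positive integer count or a fraction in (0, 1)")
    return count


def enumerate_valid_pairs(splits: list[ClusterPair], min_size=0.05):
    """Flag each split valid iff both sides have >= min_size members.

    Returns ``(splits, m)`` where ``m`` is the number of valid pairs -- the
    Bonferroni factor used downstream.  ``min_size`` may be an absolute count
    or a fraction of the sample size (rounded up).
    """
    if not splits:
        return splits, 0
    n = max(p.n_left + p.n_right for p in splits)  # root split size = n
    count = resolve_min_size(min_size, n)
    if count > n // 2:
        warnings.warn(
            f"min_size={count} exceeds n/2={n // 2}: no valid pairs possible",
            UserWarning,
            stacklevel=2,
        )
    m = 0
    for p in splits:
        p.is_valid = min(p.n_left, p.n_right) >= count
        m += p.is_valid
    return splits, m
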