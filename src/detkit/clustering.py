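"""Single-linkage hierarchical clustering of per-frame unit cells.

The clustering operates on pairwise lattice distances in reduced G6 space
(A^2).  Cutting the dendrogram at a threshold (default 5000 A^2) yields flat
clusters; each cluster's component-wise median reduced cell is the natural
re-indexing target when a dataset contains several crystal forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .cells import UnitCell, g6_from_cell, niggli_reduce, _transformed_g6_variants
from .exceptions import DetkitError, ReductionError

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "ClusterSummary",
    "pairwise_distance_matrix",
    "single_linkage",
    "cut_threshold",
    "summarize_clusters",
    "dendrogram_to_newick",
    "clustering_log",
]

DEFAULT_THRESHOLD = 5000.0  # A^2


def pairwise_distance_matrix(
    cells: list[UnitCell], metric: str = "ncdist", frame_ids=None
) -> np.ndarray:
    """Condensed pairwise distance matrix (A^2) between unit cells.

    ``metric`` is ``"ncdist"`` (symmetry-aware, default) or ``"euclidean"``
    (plain distance between reduced G6 vectors).  Cells are Niggli-reduced
    once up front; a reduction failure is reported with the offending frame
    id (or index when ids are not given).
    """
    n = len(cells)
    if n < 2:
        raise DetkitError(f"need at least 2 cells to build a distance matrix, got {n}")
    if metric not in ("ncdist", "euclidean"):
        raise DetkitError(f"unknown metric {metric!r}; expected 'ncdist' or 'euclidean'")
    ids = list(frame_ids) if frame_ids is not None else list(range(n))

    reduced_g6 = np.empty((n, 6))
    variants = None
    if metric == "ncdist":
        variants = []
    for i, cell in enumerate(cells):
        try:
            reduced_g6[i] = g6_from_cell(niggli_reduce(cell).reduced)
            if variants is not None:
                variants.append(_transformed_g6_variants(cell))
        except ReductionError as exc:
            raise ReductionError(f"frame {ids[i]}: {exc}") from exc

    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        if metric == "euclidean":
            out[k : k + n - 1 - i] = np.linalg.norm(
                reduced_g6[i + 1 :] - reduced_g6[i], axis=1
            )
        else:
            d12 = np.linalg.norm(
                variants[i][None, :, :] - reduced_g6[i + 1 :, None, :], axis=2
            ).min(axis=1)
            block = np.stack([variants[j] for j in range(i + 1, n)])
            d21 = np.linalg.norm(block - reduced_g6[i], axis=2).min(axis=1)
            out[k : k + n - 1 - i] = np.minimum(d12, d21)
        k += n - 1 - i
    return out


@dataclass(frozen=True)
class Dendrogram:
    """Single-linkage merge tree.

    ``merges`` follows the SciPy linkage convention: row t merges nodes
    ``merges[t, 0]`` and ``merges[t, 1]`` (leaves are 0..n-1, internal nodes
    n+t) at height ``merges[t, 2]`` (A^2) into a cluster of
    ``merges[t, 3]`` members.  ``leaves`` are frame identifiers in input
    order.
    """

    merges: np.ndarray
    leaves: list = field(default_factory=list)

    def __post_init__(self):
        n = self.n_leaves
        if self.merges.shape != (n - 1, 4):
            raise DetkitError(
                f"{n} leaves require {n - 1} merges, got shape {self.merges.shape}"
            )
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < 0):
            raise DetkitError("single-linkage merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def single_linkage(dist: np.ndarray, frame_ids=None) -> Dendrogram:
    """Single-linkage clustering of a condensed distance matrix."""
    dist = np.asarray(dist, dtype=float)
    m = dist.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n < 2 or n * (n - 1) // 2 != m:
        raise DetkitError(f"invalid condensed matrix length {m}")
    z = sch.linkage(dist, method="single")
    leaves = list(frame_ids) if frame_ids is not None else list(range(n))
    if len(leaves) != n:
        raise DetkitError(f"{n} observations but {len(leaves)} frame ids")
    return Dendrogram(merges=z, leaves=leaves)


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clusters from a threshold cut.

    Two frames share a label iff they are connected by merges at height
    strictly below the threshold.  Labels are ordered by descending cluster
    size (ties: smallest member index), so singletons carry the largest
    labels.  ``singleton`` flags size-1 clusters.
    """

    labels: np.ndarray
    threshold: float
    singleton: np.ndarray

    @property
    def n_clusters(self) -> int:
        """Total number of flat clusters, singletons included."""
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def n_non_singleton(self) -> int:
        return int(np.unique(self.labels[~self.singleton]).size)

    @property
    def n_singletons(self) -> int:
        return int(self.singleton.sum())


def cut_threshold(dend: Dendrogram, threshold: float = DEFAULT_THRESHOLD) -> ClusterAssignment:
    """Cut a dendrogram at ``threshold`` (A^2): flat clusters are the
    connected components of merges with height strictly below the threshold
    (a merge exactly at the threshold does not join)."""
    if not threshold > 0:
        raise DetkitError(f"threshold must be positive, got {threshold}")
    n = dend.n_leaves
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (i, j, h, _) in enumerate(dend.merges):
        node = n + t
        if h < threshold:
            parent[find(int(i))] = node
            parent[find(int(j))] = node

    roots = np.array([find(i) for i in range(n)])
    order = {}
    members: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        members.setdefault(r, []).append(i)
    # descending size, ties by smallest member index
    for new, r in enumerate(
        sorted(members, key=lambda r: (-len(members[r]), members[r][0]))
    ):
        order[r] = new
    labels = np.array([order[r] for r in roots])
    sizes = np.bincount(labels)
    singleton = sizes[labels] == 1
    return ClusterAssignment(labels=labels, threshold=float(threshold), singleton=singleton)


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster member counts, median reduced cells and MAD spreads."""

    table: pd.DataFrame
    median_cells: list[UnitCell]

    @property
    def n_clusters(self) -> int:
        return len(self.table)


_PARAMS = ["a", "b", "c", "alpha", "beta", "gamma"]


def summarize_clusters(cells: list[UnitCell], assignment: ClusterAssignment) -> ClusterSummary:
    """Component-wise medians and median absolute deviations of the
    Niggli-reduced member cells, one row per cluster, ordered by descending
    size (the label order)."""
    if len(cells) != len(assignment.labels):
        raise DetkitError(
            f"{len(cells)} cells but {len(assignment.labels)} labels"
        )
    reduced = np.array(
        [niggli_reduce(c).reduced.parameters for c in cells]
    )
    rows = []
    medians = []
    for label in range(assignment.n_clusters):
        mask = assignment.labels == label
        params = reduced[mask]
        med = np.median(params, axis=0)
        mad = np.median(np.abs(params - med), axis=0)
        row = {"cluster_id": label, "n_members": int(mask.sum())}
        row.update({f"median_{p}": med[k] for k, p in enumerate(_PARAMS)})
        row.update({f"mad_{p}": mad[k] for k, p in enumerate(_PARAMS)})
        rows.append(row)
        medians.append(UnitCell(*med))
    return ClusterSummary(table=pd.DataFrame(rows), median_cells=medians)


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Serialize the merge tree as a Newick string.

    Branch lengths are height differences (leaves sit at height 0), so the
    root-to-leaf path length equals the final merge height.
    """
    n = dend.n_leaves
    height = {i: 0.0 for i in range(n)}

    def name(i):
        s = str(dend.leaves[i])
        if any(ch in s for ch in "(),:;'\" \t\n[]"):
            s = "'" + s.replace("'", "''") + "'"
        return s

    node_str = {i: name(i) for i in range(n)}
    for t, (i, j, h, _) in enumerate(dend.merges):
        i, j = int(i), int(j)
        li = h - height[i]
        lj = h - height[j]
        node = n + t
        node_str[node] = f"({node_str[i]}:{li:.10g},{node_str[j]}:{lj:.10g})"
        height[node] = h
    return node_str[2 * n - 2] + ";"


def clustering_log(
    summary: ClusterSummary, assignment: ClusterAssignment, frame_ids, metric: str
) -> str:
    """Plain-text clustering report: counts, median cells, members."""
    lines = [
        "detkit unit-cell clustering log",
        f"metric: {metric}",
        f"threshold: {assignment.threshold:g} A^2",
        f"frames: {len(frame_ids)}",
        f"clusters (non-singleton): {assignment.n_non_singleton}",
        f"singletons: {assignment.n_singletons}",
        "",
    ]
    ids = np.asarray([str(f) for f in frame_ids])
    for _, row in summary.table.iterrows():
        label = int(row["cluster_id"])
        med = ", ".join(f"{row[f'median_{p}']:.2f}" for p in _PARAMS)
        mad = ", ".join(f"{row[f'mad_{p}']:.3f}" for p in _PARAMS)
        tag = " [singleton]" if row["n_members"] == 1 else ""
        lines.append(f"cluster {label}{tag}: {int(row['n_members'])} members")
        lines.append(f"  median cell: ({med})")
        lines.append(f"  MAD:         ({mad})")
        members = ids[assignment.labels == label]
        lines.append("  members: " + " ".join(members))
        lines.append("")
    return "\n".join(lines)
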