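"""Conformational clustering from a pairwise RMSD matrix.

Two algorithms, both operating on a precomputed matrix:

* GROMOS (Daura et al.): iteratively take the frame with the most
  neighbours within the cut-off as a cluster centre, remove it together
  with its neighbours, and repeat until every frame is assigned.
* Hierarchical average-linkage agglomeration, cut at the distance cut-off
  (delegating to scikit-learn's AgglomerativeClustering).

Populations are weighted: each cluster's population is the sum of its
members' statistical weights.  Cluster ids are assigned in order of
decreasing weighted population (id 0 = most populated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .geometry import RmsdMatrix


@dataclass(frozen=True)
class ClusterResult:
    """A total partition of frames with weighted populations."""

    assignment: np.ndarray          # (n_frames,) cluster id, 0 = largest
    centers: np.ndarray             # (n_clusters,) central frame index
    populations: np.ndarray         # (n_clusters,) weighted, non-increasing
    cutoff: float
    algorithm: str

    def __post_init__(self) -> None:
        pops = np.asarray(self.populations, dtype=float)
        if abs(pops.sum() - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1 within 1e-9")
        if np.any(np.diff(pops) > 1e-12):
            raise ValueError("populations must be sorted non-increasing")
        ids = np.unique(self.assignment)
        if not np.array_equal(ids, np.arange(len(pops))):
            raise ValueError("assignment must use contiguous cluster ids 0..k-1")

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)


def _normalise_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights length {w.shape} does not match {n} frames")
    return w / w.sum()


def _finalise(raw_labels: np.ndarray, raw_centers: dict[int, int],
              w: np.ndarray, cutoff: float, algorithm: str) -> ClusterResult:
    """Relabel clusters by descending weighted population (ties: centre index)."""
    raw_ids = sorted(raw_centers)
    pops = np.array([w[raw_labels == rid].sum() for rid in raw_ids])
    order = sorted(range(len(raw_ids)),
                   key=lambda k: (-pops[k], raw_centers[raw_ids[k]]))
    remap = {raw_ids[k]: new for new, k in enumerate(order)}
    assignment = np.array([remap[r] for r in raw_labels])
    centers = np.array([raw_centers[raw_ids[k]] for k in order])
    populations = pops[order]
    populations = populations / populations.sum()
    return ClusterResult(assignment=assignment, centers=centers,
                         populations=populations, cutoff=cutoff,
                         algorithm=algorithm)


def gromos_cluster(
    matrix: RmsdMatrix | np.ndarray,
    cutoff: float = 0.15,
    weights=None,
) -> ClusterResult:
    """GROMOS/Daura clustering of a distance matrix at the given cut-off (nm).

    Neighbour counting is unweighted (frame counts), as in the original
    algorithm; weights enter only in the population computation.  The
    neighbour criterion is strict (d < cutoff) and ties between candidate
    centres go to the lowest frame index.
    """
    d = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix)
    if d.size == 0:
        raise ValueError("empty distance matrix")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = d.shape[0]
    w = _normalise_weights(n, weights)
    adj = d < cutoff
    np.fill_diagonal(adj, True)
    active = np.ones(n, dtype=bool)
    labels = np.full(n, -1)
    centers: dict[int, int] = {}
    cid = 0
    while active.any():
        counts = (adj & active[None, :]).sum(axis=1)
        counts[~active] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = active & adj[center]
        labels[members] = cid
        centers[cid] = center
        active &= ~members
        cid += 1
    return _finalise(labels, centers, w, cutoff, "gromos")


def _medoid(d: np.ndarray, members: np.ndarray) -> int:
    sub = d[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def hierarchical_cluster(
    matrix: RmsdMatrix | np.ndarray,
    cutoff: float,
    weights=None,
) -> ClusterResult:
    """Average-linkage agglomerative clustering cut at ``cutoff`` (nm).

    The tree is built from the precomputed distance matrix; merges happen
    while the average linkage distance is strictly below the cut-off.
    Cluster centres are medoids (member minimising the summed intra-cluster
    distance).
    """
    d = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix)
    if d.size == 0:
        raise ValueError("empty distance matrix")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = d.shape[0]
    w = _normalise_weights(n, weights)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        model = AgglomerativeClustering(
            n_clusters=None, distance_threshold=cutoff,
            metric="precomputed", linkage="average",
        )
        labels = model.fit_predict(d)
    centers = {int(c): _medoid(d, np.flatnonzero(labels == c))
               for c in np.unique(labels)}
    return _finalise(labels, centers, w, cutoff, "hierarchical")


_ALGORITHMS = {"gromos": gromos_cluster, "hierarchical": hierarchical_cluster}


def cluster_count_curve(
    matrix: RmsdMatrix | np.ndarray,
    cutoffs,
    algorithm: str = "gromos",
    weights=None,
) -> list[tuple[float, int]]:
    """Number of clusters as a function of the RMSD cut-off."""
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    cutoffs = list(cutoffs)
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be sorted ascending")
    fn = _ALGORITHMS[algorithm]
    return [(float(c), fn(matrix, c, weights).n_clusters) for c in cutoffs]


def write_cluster_result(result: ClusterResult, assignment_path: str | Path,
                         summary_path: str | Path | None = None) -> None:
    """Write the frame→cluster table (TSV) and a JSON summary."""
    with open(assignment_path, "w") as fh:
        fh.write("frame\tcluster\n")
        for i, c in enumerate(result.assignment):
            fh.write(f"{i}\t{int(c)}\n")
    if summary_path is not None:
        summary = {
            "algorithm": result.algorithm,
            "cutoff_nm": result.cutoff,
            "n_clusters": result.n_clusters,
            "populations": [float(p) for p in result.populations],
            "centers": [int(c) for c in result.centers],
        }
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
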