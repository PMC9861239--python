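"""Conformational clustering: pairwise-RMSD matrices and the gromos algorithm.

The gromos (Daura) algorithm partitions frames using a pairwise
superposition-minimized RMSD matrix and a distance cutoff: repeatedly, the
unassigned frame with the most unassigned neighbours within the cutoff
becomes a centroid, and it plus its neighbours form the next cluster.  With
a fixed cutoff the number of clusters is a direct readout of how broad a
conformational ensemble is — the comparison this pipeline uses between
metal-free and metal-bound trajectories (cutoff 1.8 Å by convention here).

The RMSD matrix is computed in tiles of batched Kabsch problems so that
ensembles of several thousand frames fit in ordinary memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError, ShapeError
from .structio import Selection, Structure, Trajectory, apply_selection

__all__ = [
    "RmsdMatrix",
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "cluster_centroid_structures",
]


@dataclass
class RmsdMatrix:
    """Symmetric matrix of pairwise minimized RMSDs (Å), zero diagonal."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError("RMSD matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-6:
            raise ShapeError("RMSD matrix must be symmetric within 1e-6")
        if np.any(np.diag(v) != 0.0):
            raise ShapeError("RMSD matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise ShapeError("RMSD entries must be >= 0")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_rmsd_matrix(
    traj: Trajectory, sel: Selection | None = None, tile: int = 256
) -> RmsdMatrix:
    """All-against-all superposition-minimized RMSD over the selection.

    Each pair is superposed independently (pairwise Kabsch).  Uses the
    singular-value identity rmsd²·N = |X|² + |Y|² − 2(σ₁+σ₂±σ₃) on batched
    cross-covariance SVDs, tiled to bound memory.
    """
    if sel is not None:
        traj = apply_selection(traj, sel)
    m = traj.n_frames
    if m < 2:
        raise InsufficientDataError("pairwise RMSD needs at least 2 frames")
    n_atoms = traj.n_atoms
    X = traj.coords - traj.coords.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", X, X)
    out = np.zeros((m, m))
    for i0 in range(0, m, tile):
        i1 = min(i0 + tile, m)
        for j0 in range(i0, m, tile):
            j1 = min(j0 + tile, m)
            H = np.einsum("aik,bil->abkl", X[i0:i1], X[j0:j1])
            U, S, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
            tr = S[..., 0] + S[..., 1] + d * S[..., 2]
            msd = (sq[i0:i1, None] + sq[None, j0:j1] - 2.0 * tr) / n_atoms
            block = np.sqrt(np.clip(msd, 0.0, None))
            out[i0:i1, j0:j1] = block
            out[j0:j1, i0:i1] = block.T
    np.fill_diagonal(out, 0.0)
    return RmsdMatrix(out)


@dataclass
class ClusterResult:
    """A total partition of frames, centroids first-class.

    Cluster ids are 0-based in discovery order, which by construction is
    non-increasing population order.
    """

    assignment: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    cutoff: float

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def to_dataframe(self):
        import pandas as pd

        is_centroid = np.zeros(len(self.assignment), dtype=bool)
        is_centroid[self.centroids] = True
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.assignment)),
                "cluster": self.assignment,
                "is_centroid": is_centroid,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_frames": int(len(self.assignment)),
            "n_clusters": int(self.n_clusters),
            "sizes": self.sizes.tolist(),
            "centroids": self.centroids.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def gromos_cluster(matrix: RmsdMatrix, cutoff: float) -> ClusterResult:
    """Daura/gromos clustering of an RMSD matrix at a distance cutoff (Å).

    Neighbourhood is the closed ball (distance <= cutoff).  Ties in
    neighbour count are broken toward the lowest frame index, which makes
    the partition deterministic.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    d = matrix.values
    n = matrix.n
    within = d <= cutoff
    np.fill_diagonal(within, False)
    unassigned = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=np.int64)
    centroids: list[int] = []
    sizes: list[int] = []
    cid = 0
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(unassigned & (within[center] | (np.arange(n) == center)))
        assignment[members] = cid
        unassigned[members] = False
        centroids.append(center)
        sizes.append(len(members))
        cid += 1
    return ClusterResult(assignment, np.array(centroids), np.array(sizes), cutoff)


def cluster_centroid_structures(
    result: ClusterResult, traj: Trajectory, k: int
) -> list[Structure]:
    """Centroid frames of the ``k`` most-populated clusters, as structures."""
    if not (1 <= k <= result.n_clusters):
        raise IndexError(f"k={k} outside 1..{result.n_clusters}")
    return [traj.frame(int(result.centroids[c])) for c in range(k)]
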