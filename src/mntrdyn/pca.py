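"""Essential-dynamics PCA on Cartesian Cα coordinates.

Workflow: take one or more trajectories of the same dimer, restrict to an
equilibrated time window, merge the frames, superpose everything onto the
iteratively refined mean structure, and eigendecompose the sample
covariance of the flattened 3N coordinates.  The leading eigenvectors are
the collective motions ("essential modes"); projections place every frame
on those modes, and correlation-style factor loadings aggregated per
residue locate the residues that carry each mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    ShapeError,
    StructuralMismatchError,
    WindowError,
)
from .geometry import iterative_mean_superpose
from .structio import AtomTable, Selection, Trajectory, apply_selection

__all__ = [
    "PCAResult",
    "LoadingProfile",
    "merge_and_superpose",
    "fit_pca",
    "project",
    "residue_loadings",
]


@dataclass
class PCAResult:
    """Eigendecomposition of the coordinate covariance (Å²)."""

    mean_coords: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, orthonormal
    variance_fractions: np.ndarray
    zero_variance: bool = False

    @property
    def component_count(self) -> int:
        return self.eigenvectors.shape[1]

    def scree_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "zero_variance": self.zero_variance,
        }

    def scree_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.scree_dict(), fh, indent=2)


@dataclass
class LoadingProfile:
    """Per-residue factor-loading magnitudes for one component."""

    component: int
    chain_ids: np.ndarray
    res_nums: np.ndarray
    values: np.ndarray
    per_coordinate: np.ndarray = field(repr=False, default=None)
    zero_variance_coords: np.ndarray = field(repr=False, default=None)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chain_id": self.chain_ids,
                "res_num": self.res_nums,
                "loading": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def merge_and_superpose(
    trajs: list[Trajectory],
    sel: Selection | None = None,
    window: tuple[float | None, float | None] | None = None,
    return_origin: bool = False,
):
    """Merge trajectory windows and superpose onto the iterative mean.

    Returns the ``(total_frames, 3N)`` coordinate matrix (plus a per-frame
    origin index and the selected atom table when ``return_origin`` is
    true).  All inputs must share the selection's atom identities.
    """
    if not trajs:
        raise InsufficientDataError("no trajectories to merge")
    pieces = []
    origin = []
    table: AtomTable | None = None
    for k, traj in enumerate(trajs):
        if window is not None:
            traj = traj.window(*window)
        if sel is not None:
            traj = apply_selection(traj, sel)
        if table is None:
            table = traj.table
        elif table != traj.table:
            raise StructuralMismatchError(
                f"trajectory {k} has a different atom table under the selection"
            )
        pieces.append(traj.coords)
        origin.append(np.full(traj.n_frames, k))
    coords = np.concatenate(pieces, axis=0)
    fitted, _ = iterative_mean_superpose(coords)
    flat = fitted.reshape(fitted.shape[0], -1)
    if return_origin:
        return flat, np.concatenate(origin), table
    return flat


def fit_pca(coords: np.ndarray) -> PCAResult:
    """PCA of a ``(frames, 3N)`` coordinate matrix via the sample covariance.

    Components are sorted by eigenvalue, descending; tiny negative
    eigenvalues from round-off are clipped to zero.  A zero total variance
    (static input) is flagged rather than an error.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 1:
        raise ShapeError("coords must be (frames, 3N)")
    m = coords.shape[0]
    if m < 2:
        raise InsufficientDataError("PCA needs at least 2 frames")
    mean = coords.mean(axis=0)
    centered = coords - mean
    cov = centered.T @ centered / (m - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    if total > 0:
        fractions = eigval / total
        zero_variance = False
    else:
        fractions = np.zeros_like(eigval)
        zero_variance = True
    return PCAResult(mean, eigval, eigvec, fractions, zero_variance)


def project(coords: np.ndarray, pca: PCAResult, component: int) -> np.ndarray:
    """Per-frame projection of centered coordinates onto one component."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if component >= pca.component_count:
        raise ShapeError(
            f"component {component} >= component_count {pca.component_count}"
        )
    if coords.shape[1] != pca.mean_coords.shape[0]:
        raise ShapeError("coordinate dimension does not match the PCA model")
    return (coords - pca.mean_coords) @ pca.eigenvectors[:, component]


def residue_loadings(
    pca: PCAResult,
    coords: np.ndarray,
    component: int,
    table: AtomTable | None = None,
) -> LoadingProfile:
    """Correlation-style factor loadings of one component, per residue.

    Per coordinate: eigenvector element × √eigenvalue ÷ coordinate SD —
    i.e. the Pearson correlation between that coordinate and the
    component's projection series.  Zero-variance coordinates get loading 0
    (flagged).  Per residue (one atom per residue expected, e.g. a Cα
    selection): the Euclidean norm over the atom's x,y,z loadings.
    """
    coords = np.asarray(coords, dtype=float)
    if component >= pca.component_count:
        raise ShapeError(
            f"component {component} >= component_count {pca.component_count}"
        )
    sd = coords.std(axis=0, ddof=1)
    vec = pca.eigenvectors[:, component]
    lam = pca.eigenvalues[component]
    # constant coordinates: treat round-off-level SDs as zero variance
    zero = sd <= 1e-10 * max(1.0, float(sd.max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_coord = np.where(zero, 0.0, vec * np.sqrt(lam) / np.where(zero, 1.0, sd))
    per_atom = np.linalg.norm(per_coord.reshape(-1, 3), axis=1)
    if table is not None:
        chain_ids = table.chain_id
        res_nums = table.res_num
    else:
        chain_ids = np.full(per_atom.shape[0], "")
        res_nums = np.arange(1, per_atom.shape[0] + 1)
    return LoadingProfile(
        component, chain_ids, res_nums, per_atom, per_coord, zero
    )
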