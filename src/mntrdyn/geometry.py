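"""Geometric kernels: angles, dihedrals, Kabsch superposition, RMSD/RMSF, Rg.

All distances are in Å and all angles in degrees.  Planar angles lie in
[0, 180]; dihedrals are signed in (−180, 180] with the IUPAC convention
(positive = clockwise rotation of the far bond viewed along the central
bond).  Superposition is unweighted least squares over all selected atoms;
reflections are excluded by the standard determinant correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    SelectionError,
    ShapeError,
)

__all__ = [
    "RigidTransform",
    "angle",
    "dihedral",
    "kabsch",
    "superpose",
    "rmsd",
    "rmsf",
    "radius_of_gyration",
    "iterative_mean_superpose",
    "crystal_ca_rmsd",
]

_EPS = 1e-12


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ShapeError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise DegenerateGeometryError("rotation determinant != +1")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise DegenerateGeometryError("rotation is not orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def angle(p1, p2, p3) -> float | np.ndarray:
    """Planar angle at vertex ``p2`` in degrees, in [0, 180].

    Accepts single points or broadcastable ``(..., 3)`` stacks.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < _EPS) or np.any(n2 < _EPS):
        raise DegenerateGeometryError("coincident points in angle()")
    cosang = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    out = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Signed torsion of planes (p1,p2,p3) and (p2,p3,p4) in (−180, 180].

    IUPAC sign convention via the standard two-plane atan2 formula.
    Vectorised over leading dimensions.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(b2n < _EPS):
        raise DegenerateGeometryError("central bond has zero length")
    if np.any(np.linalg.norm(n1, axis=-1) < _EPS) or np.any(
        np.linalg.norm(n2, axis=-1) < _EPS
    ):
        raise DegenerateGeometryError("collinear triple in dihedral()")
    m1 = np.cross(b2 / b2n[..., None], n1)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    out = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (−180, 180]
    out = np.where(np.isclose(out, -180.0), 180.0, out)
    return float(out) if out.ndim == 0 else out


def _check_pointset(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ShapeError(f"{name} must be (N, 3)")
    return x


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper-rotation transform and the minimized RMSD (Å).
    Requires >= 3 non-collinear points in each set.
    """
    mobile = _check_pointset(mobile, "mobile")
    reference = _check_pointset(reference, "reference")
    if mobile.shape != reference.shape:
        raise ShapeError(
            f"point counts differ: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points for superposition")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    X = mobile - cm
    Y = reference - cr
    if np.linalg.matrix_rank(X, tol=1e-9) < 2 or np.linalg.matrix_rank(Y, tol=1e-9) < 2:
        raise DegenerateGeometryError("collinear point set in kabsch()")
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    aligned = mobile @ R.T + t
    value = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return RigidTransform(R, t), value


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Mobile coordinates after optimal superposition onto reference."""
    tf, _ = kabsch(mobile, reference)
    return tf.apply(mobile)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no refit) RMSD between two equal-shape coordinate sets."""
    a = _check_pointset(a, "a")
    b = _check_pointset(b, "b")
    if a.shape != b.shape:
        raise ShapeError("shapes differ in rmsd()")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def iterative_mean_superpose(
    coords: np.ndarray, tol: float = 1e-6, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto the iteratively refined mean structure.

    Fit–average–refit until the mean moves by less than ``tol`` Å (RMS).
    Returns ``(superposed_coords, mean_coords)``.  Removes the reference bias
    a fixed first-frame fit would imprint on covariance analyses.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ShapeError("coords must be (n_frames, n_atoms, 3)")
    if coords.shape[0] < 1:
        raise InsufficientDataError("no frames")
    work = coords.copy()
    ref = work[0] - work[0].mean(axis=0)
    for _ in range(max_iter):
        for f in range(work.shape[0]):
            work[f] = superpose(work[f], ref)
        mean = work.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1))))
        ref = mean
        if shift < tol:
            break
    return work, ref


def rmsf(coords: np.ndarray) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time mean (Å).

    ``coords`` is ``(n_frames, n_atoms, 3)`` and is superposed onto the
    iterative mean before the fluctuation is taken.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3:
        raise ShapeError("coords must be (n_frames, n_atoms, 3)")
    if coords.shape[0] < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    fitted, mean = iterative_mean_superpose(coords)
    d2 = np.sum((fitted - mean) ** 2, axis=2)
    return np.sqrt(d2.mean(axis=0))


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted radius of gyration of one frame (Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise SelectionError("radius_of_gyration needs a non-empty (N, 3) set")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def crystal_ca_rmsd(struct_a, struct_b, chain_pairs=None) -> float:
    """Chain-matched common-residue Cα RMSD between two structures (Å).

    Pairs chains in alphabetical order by default (or per ``chain_pairs``,
    a list of ``(chain_of_a, chain_of_b)``), intersects the residue numbers
    that carry a Cα in both, and returns the Kabsch-minimized RMSD over the
    union of matched Cα atoms.  This mirrors how crystal structures of the
    same dimer with slightly different modelled ranges are compared.
    """
    from .structio import Structure

    def ca_map(s: Structure, chain: str) -> dict[int, np.ndarray]:
        t = s.table
        mask = (t.chain_id == chain) & (t.atom_name == "CA") & ~t.hetero
        return {
            int(rn): s.coords[i]
            for i, rn in zip(np.flatnonzero(mask), t.res_num[mask])
        }

    if chain_pairs is None:
        ca = struct_a.table.protein_chain_order()
        cb = struct_b.table.protein_chain_order()
        if len(ca) != len(cb):
            raise ShapeError("structures have different chain counts")
        chain_pairs = list(zip(ca, cb))

    xs, ys = [], []
    for cha, chb in chain_pairs:
        ma = ca_map(struct_a, cha)
        mb = ca_map(struct_b, chb)
        common = sorted(set(ma) & set(mb))
        if not common:
            raise SelectionError(f"no common Cα residues for chains {cha}/{chb}")
        xs.extend(ma[r] for r in common)
        ys.extend(mb[r] for r in common)
    _, value = kabsch(np.asarray(xs), np.asarray(ys))
    return value
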