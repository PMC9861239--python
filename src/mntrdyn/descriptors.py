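"""Frame-by-frame geometric activation descriptors of the MntR dimer.

Four named readouts of the dimer conformation, evaluated per frame:

``dbh_dihedral``
    The signed dihedral over the backbone carbonyl C atoms of residues
    47, 36, 189 and 178 (continuous dimer numbering; 189 and 178 are
    residues 47 and 36 of the second chain).  It measures the relative
    orientation of the two DNA-binding helices — the activation readout.
``hinge_angle``
    The planar angle over backbone C atoms of residues 64, 75 and 86 of one
    chain, vertex at residue 75; quantifies the hinge-like bend of the
    linker helix between the DNA-binding and dimerization domains.
``interchain_ca_distance``
    Distance between the Cα atoms of the same residue (Lys41 by default)
    in the two chains.
``site2_gap``
    Distance across the second metal-binding site: minimum separation of
    the Asp8 and Glu99 side-chain carboxylate oxygens of one chain, with a
    flagged Cα–Cα fallback for coarse models without side chains.

"Backbone C" means the carbonyl carbon (PDB atom name ``C``), not Cα; the
Cα-based descriptors say Cα explicitly.  Atom names and residue numbers are
overridable on every function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DescriptorAtomError, UnitError
from .structio import Trajectory, continuous_inverse

__all__ = [
    "DescriptorSeries",
    "dbh_dihedral_series",
    "hinge_angle_series",
    "interchain_ca_distance_series",
    "site2_gap_series",
]

DESCRIPTOR_UNITS = {
    "dbh_dihedral": "degrees",
    "hinge_angle": "degrees",
    "interchain_ca_distance": "angstrom",
    "site2_gap": "angstrom",
}


@dataclass
class DescriptorSeries:
    """One scalar descriptor per frame, with units and sampling interval."""

    name: str
    values: np.ndarray
    units: str
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.name in DESCRIPTOR_UNITS and DESCRIPTOR_UNITS[self.name] != self.units:
            raise UnitError(f"{self.name} must be in {DESCRIPTOR_UNITS[self.name]}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self.values)),
                "time_ps": self.times_ps,
                "value": self.values,
                "units": self.units,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _atom_coords(traj: Trajectory, chain: str, res: int, atom_name: str) -> np.ndarray:
    try:
        idx = traj.table.index_of(chain, res, atom_name)
    except KeyError:
        raise DescriptorAtomError(
            f"required atom {chain}:{res}:{atom_name} is missing"
        ) from None
    return traj.coords[:, idx, :]


def _resolve_continuous(traj: Trajectory, res: int) -> tuple[str, int]:
    return continuous_inverse(traj.table.chain_lengths(), res)


def dbh_dihedral_series(
    traj: Trajectory,
    residues: tuple[int, int, int, int] = (47, 36, 189, 178),
    atom_name: str = "C",
) -> DescriptorSeries:
    """Signed DNA-binding-helix dihedral per frame, in degrees.

    ``residues`` are continuous dimer indices in the order defining the
    torsion; the defaults are the two symmetric helix positions of each
    chain (47/36 and their second-chain images 189/178).
    """
    from .geometry import dihedral

    pts = []
    for res in residues:
        chain, rnum = _resolve_continuous(traj, res)
        pts.append(_atom_coords(traj, chain, rnum, atom_name))
    values = dihedral(*pts)
    return DescriptorSeries(
        "dbh_dihedral",
        np.atleast_1d(values),
        "degrees",
        traj.frame_interval,
        {"residues": tuple(residues), "atom_name": atom_name},
    )


def hinge_angle_series(
    traj: Trajectory,
    chain: str | None = None,
    residues: tuple[int, int, int] = (64, 75, 86),
    atom_name: str = "C",
) -> DescriptorSeries:
    """Linker-helix hinge angle per frame (vertex at the middle residue).

    With ``chain=None`` the mean over both chains is returned (the
    per-system convention used for summary statistics); pass a chain id for
    a single-chain series.
    """
    from .geometry import angle

    chains = [chain] if chain is not None else traj.table.protein_chain_order()
    per_chain = []
    for ch in chains:
        pts = [_atom_coords(traj, ch, r, atom_name) for r in residues]
        per_chain.append(np.atleast_1d(angle(*pts)))
    values = np.mean(per_chain, axis=0)
    return DescriptorSeries(
        "hinge_angle",
        values,
        "degrees",
        traj.frame_interval,
        {"residues": tuple(residues), "atom_name": atom_name,
         "chains": tuple(chains)},
    )


def interchain_ca_distance_series(
    traj: Trajectory, res_num: int = 41
) -> DescriptorSeries:
    """Distance between the Cα atoms of ``res_num`` in the two chains (Å)."""
    chains = traj.table.protein_chain_order()
    if len(chains) < 2:
        raise DescriptorAtomError(
            f"need two protein chains for the inter-chain distance, have {chains}"
        )
    a = _atom_coords(traj, chains[0], res_num, "CA")
    b = _atom_coords(traj, chains[1], res_num, "CA")
    values = np.linalg.norm(a - b, axis=-1)
    return DescriptorSeries(
        "interchain_ca_distance",
        np.atleast_1d(values),
        "angstrom",
        traj.frame_interval,
        {"res_num": res_num, "chains": tuple(chains[:2])},
    )


_CARBOXYLATE_OXYGENS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "CYS": ("SG",),  # the disulfide-mimic mutant of the site
}


def site2_gap_series(
    traj: Trajectory,
    chain: str,
    res_a: int = 8,
    res_b: int = 99,
) -> DescriptorSeries:
    """Gap across the second metal site of one chain (Å).

    Minimum distance over the side-chain carboxylate-oxygen pairs of the two
    residues; falls back to the Cα–Cα distance (flagged in ``meta``) when the
    side chains are absent, e.g. on backbone-only coarse models.
    """
    table = traj.table

    def side_chain_indices(res: int) -> list[int]:
        mask = (table.chain_id == chain) & (table.res_num == res) & ~table.hetero
        if not mask.any():
            raise DescriptorAtomError(f"residue {chain}:{res} is missing")
        res_name = str(table.res_name[np.flatnonzero(mask)[0]])
        names = _CARBOXYLATE_OXYGENS.get(res_name, ())
        return [
            i for i in np.flatnonzero(mask) if table.atom_name[i] in names
        ]

    ia = side_chain_indices(res_a)
    ib = side_chain_indices(res_b)
    fallback = not ia or not ib
    if fallback:
        try:
            ia = [table.index_of(chain, res_a, "CA")]
            ib = [table.index_of(chain, res_b, "CA")]
        except KeyError:
            raise DescriptorAtomError(
                f"neither side-chain atoms nor Cα present for "
                f"{chain}:{res_a}/{chain}:{res_b}"
            ) from None
    # min over all atom pairs, per frame
    d = np.linalg.norm(
        traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :], axis=-1
    )
    values = d.reshape(traj.n_frames, -1).min(axis=1)
    return DescriptorSeries(
        "site2_gap",
        values,
        "angstrom",
        traj.frame_interval,
        {"chain": chain, "residues": (res_a, res_b), "ca_fallback": fallback},
    )
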