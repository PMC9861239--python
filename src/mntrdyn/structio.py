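"""Structure and trajectory containers plus multi-model PDB I/O.

The in-memory model is deliberately light: an :class:`AtomTable` (parallel
numpy arrays of atom identities, shared by every frame), a single-conformer
:class:`Structure`, and a :class:`Trajectory` whose coordinates are one
``(n_frames, n_atoms, 3)`` array.  Multi-model PDB files are the trajectory
interchange format (one ``MODEL`` per frame); parsing and fixed-width writing
are delegated to :mod:`biotite.structure.io.pdb`, wrapped in the validation
rules this pipeline needs (line-numbered parse errors, insertion-code
rejection, altloc filtering).

Residues are numbered per chain, 1-based, as in the source PDB files.  The
dimer-wide *continuous* numbering used by the inter-helix dihedral descriptor
(residue 189 = residue 47 of the second chain when the first chain has 142
residues) is provided by :func:`continuous_index` / :func:`continuous_inverse`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bpdb

from .errors import (
    CoordinateOverflowError,
    IndexMappingError,
    PdbParseError,
    SelectionError,
    ShapeError,
    StructuralMismatchError,
)

__all__ = [
    "AtomRecord",
    "AtomTable",
    "Structure",
    "Trajectory",
    "Selection",
    "read_pdb_models",
    "write_pdb",
    "apply_selection",
    "continuous_index",
    "continuous_inverse",
]

WATER_RES_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "DOD"})

# PDB %8.3f coordinate field limits
_COORD_MIN = -999.999
_COORD_MAX = 9999.999


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position (Å)."""

    chain_id: str
    res_num: int
    res_name: str
    atom_name: str
    position: np.ndarray
    hetero: bool = False
    element: str = ""


class AtomTable:
    """Ordered atom identities shared by all frames of a trajectory."""

    def __init__(
        self,
        chain_id: np.ndarray,
        res_num: np.ndarray,
        res_name: np.ndarray,
        atom_name: np.ndarray,
        hetero: np.ndarray | None = None,
        element: np.ndarray | None = None,
    ):
        n = len(chain_id)
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_num = np.asarray(res_num, dtype=np.int64)
        self.res_name = np.asarray(res_name, dtype="U5")
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.hetero = (
            np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, dtype=bool)
        )
        self.element = (
            np.array([nm.strip()[:1] for nm in self.atom_name], dtype="U2")
            if element is None
            else np.asarray(element, dtype="U2")
        )
        if not (
            len(self.res_num) == len(self.res_name) == len(self.atom_name)
            == len(self.hetero) == len(self.element) == n
        ):
            raise ShapeError("atom table columns differ in length")

    def __len__(self) -> int:
        return len(self.chain_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomTable):
            return NotImplemented
        return (
            np.array_equal(self.chain_id, other.chain_id)
            and np.array_equal(self.res_num, other.res_num)
            and np.array_equal(self.res_name, other.res_name)
            and np.array_equal(self.atom_name, other.atom_name)
            and np.array_equal(self.hetero, other.hetero)
        )

    def subset(self, mask: np.ndarray) -> "AtomTable":
        return AtomTable(
            self.chain_id[mask],
            self.res_num[mask],
            self.res_name[mask],
            self.atom_name[mask],
            self.hetero[mask],
            self.element[mask],
        )

    def index_of(self, chain_id: str, res_num: int, atom_name: str) -> int:
        """Index of one atom; raises ``KeyError`` when absent."""
        hits = np.flatnonzero(
            (self.chain_id == chain_id)
            & (self.res_num == res_num)
            & (self.atom_name == atom_name)
        )
        if hits.size == 0:
            raise KeyError(f"atom {chain_id}:{res_num}:{atom_name} not in table")
        return int(hits[0])

    def protein_chain_order(self) -> list[str]:
        """Protein chain ids, alphabetical (the dimer convention)."""
        chains = sorted(set(self.chain_id[~self.hetero]))
        if not chains:
            chains = sorted(set(self.chain_id))
        return chains

    def chain_lengths(self) -> list[tuple[str, int]]:
        """(chain_id, n_residues) for protein chains, in alphabetical chain order."""
        out = []
        for ch in self.protein_chain_order():
            mask = (self.chain_id == ch) & ~self.hetero
            out.append((ch, len(np.unique(self.res_num[mask]))))
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chain_id": self.chain_id,
                "res_num": self.res_num,
                "res_name": self.res_name,
                "atom_name": self.atom_name,
                "hetero": self.hetero,
                "element": self.element,
            }
        )

    def records(self, coords: np.ndarray) -> list[AtomRecord]:
        return [
            AtomRecord(
                str(self.chain_id[i]),
                int(self.res_num[i]),
                str(self.res_name[i]),
                str(self.atom_name[i]),
                np.asarray(coords[i], dtype=float),
                bool(self.hetero[i]),
                str(self.element[i]),
            )
            for i in range(len(self))
        ]


@dataclass
class Structure:
    """One conformer: an atom table plus one coordinate per atom (Å)."""

    table: AtomTable
    coords: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.table), 3):
            raise ShapeError(
                f"coords shape {self.coords.shape} != ({len(self.table)}, 3)"
            )
        if len(self.table) == 0:
            raise SelectionError("empty structure")
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("non-finite coordinates")

    @property
    def atoms(self) -> list[AtomRecord]:
        return self.table.records(self.coords)

    def to_trajectory(self, frame_interval: float = 100.0) -> "Trajectory":
        return Trajectory(self.table, self.coords[None, :, :], frame_interval, self.label)


@dataclass
class Trajectory:
    """Ordered frames over a shared atom table.

    ``frame_interval`` is the sampling interval in picoseconds per frame.
    """

    table: AtomTable
    coords: np.ndarray
    frame_interval: float = 100.0
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.table), 3):
            raise ShapeError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{len(self.table)} atoms"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, i: int) -> Structure:
        return Structure(self.table, self.coords[i], f"{self.label}[{i}]")

    def window(self, t_min_ps: float | None, t_max_ps: float | None) -> "Trajectory":
        """Frames with t_min ≤ t < t_max (either bound may be None)."""
        from .errors import WindowError

        t = self.times_ps
        mask = np.ones(self.n_frames, dtype=bool)
        if t_min_ps is not None:
            mask &= t >= t_min_ps
        if t_max_ps is not None:
            mask &= t < t_max_ps
        if not mask.any():
            raise WindowError(
                f"window [{t_min_ps}, {t_max_ps}) ps selects no frame of "
                f"{self.n_frames} x {self.frame_interval} ps"
            )
        return Trajectory(self.table, self.coords[mask], self.frame_interval, self.label)


@dataclass(frozen=True)
class Selection:
    """Atom selection: chains, per-chain residue windows, atom names, stripping.

    ``strip_head``/``strip_tail`` remove the first/last residues of every
    protein chain (the flexible termini that add noise to clustering and PCA).
    Hydrogens, waters and hetero atoms are excluded unless asked for, since no
    geometric descriptor needs them.

    ``strip_tail`` counts from the nominal full chain length ``chain_length``
    (the highest residue number present when not given); pin ``chain_length``
    to make stripping idempotent on already-stripped chains.
    """

    chains: frozenset | str = "all"
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset | str = "all"
    strip_head: int = 0
    strip_tail: int = 0
    chain_length: int | None = None
    include_hetero: bool = False
    include_hydrogens: bool = False
    include_waters: bool = False

    @staticmethod
    def ca(strip_head: int = 0, strip_tail: int = 0,
           chain_length: int | None = None) -> "Selection":
        return Selection(atom_names=frozenset({"CA"}), strip_head=strip_head,
                         strip_tail=strip_tail, chain_length=chain_length)

    def resolve(self, table: AtomTable) -> np.ndarray:
        mask = np.ones(len(table), dtype=bool)
        if not self.include_hetero:
            mask &= ~table.hetero
        if not self.include_waters:
            mask &= ~np.isin(table.res_name, list(WATER_RES_NAMES))
        if not self.include_hydrogens:
            mask &= ~np.isin(table.element, ["H", "D"])
        if self.chains != "all":
            mask &= np.isin(table.chain_id, list(self.chains))
        if self.residue_range is not None:
            lo, hi = self.residue_range
            mask &= (table.res_num >= lo) & (table.res_num <= hi)
        if self.atom_names != "all":
            mask &= np.isin(table.atom_name, list(self.atom_names))
        if self.strip_head or self.strip_tail:
            for ch, _length in table.chain_lengths():
                in_chain = table.chain_id == ch
                res = table.res_num
                L = (self.chain_length if self.chain_length is not None
                     else int(res[in_chain & ~table.hetero].max()))
                if self.strip_head + self.strip_tail >= L:
                    raise SelectionError(
                        f"strip_head+strip_tail >= length of chain {ch} ({L})"
                    )
                # keep residues strip_head < r <= L − strip_tail
                keep = (res > self.strip_head) & (res <= L - self.strip_tail)
                mask &= ~in_chain | keep | table.hetero
        if not mask.any():
            raise SelectionError("selection resolves to zero atoms")
        return mask


def apply_selection(traj: Trajectory, sel: Selection) -> Trajectory:
    """Subset a trajectory; atom order is preserved."""
    mask = sel.resolve(traj.table)
    return Trajectory(
        traj.table.subset(mask), traj.coords[:, mask, :], traj.frame_interval, traj.label
    )


# ---------------------------------------------------------------------------
# continuous dimer numbering
# ---------------------------------------------------------------------------

def continuous_index(
    chain_order: Sequence[tuple[str, int]], chain_id: str, res_num: int
) -> int:
    """Map (chain, per-chain residue) to the dimer-wide continuous index.

    ``chain_order`` is a list of ``(chain_id, length)``; residue r of the k-th
    chain maps to r plus the total length of all preceding chains.  For an
    MntR dimer with two 142-residue chains, (B, 47) -> 189.
    """
    offset = 0
    for ch, length in chain_order:
        if ch == chain_id:
            if not (1 <= res_num <= length):
                raise IndexMappingError(
                    f"residue {res_num} outside chain {ch} (length {length})"
                )
            return offset + res_num
        offset += length
    raise IndexMappingError(f"chain {chain_id!r} not in chain order")


def continuous_inverse(
    chain_order: Sequence[tuple[str, int]], index: int
) -> tuple[str, int]:
    """Inverse of :func:`continuous_index`."""
    offset = 0
    for ch, length in chain_order:
        if offset < index <= offset + length:
            return ch, index - offset
        offset += length
    raise IndexMappingError(f"continuous index {index} outside dimer (total {offset})")


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------

def _as_text(source) -> str:
    if isinstance(source, (str, os.PathLike)):
        p = Path(source)
        try:
            if p.is_file():
                return p.read_text()
        except (OSError, ValueError):
            pass
        if isinstance(source, os.PathLike):
            raise FileNotFoundError(f"no such PDB file: {source}")
        if "\n" in source or source.startswith(("ATOM", "HETATM", "MODEL", "HEADER")):
            return source
        raise FileNotFoundError(f"no such PDB file: {source}")
    raise TypeError("source must be a path or PDB text")


def _validate_pdb_lines(text: str) -> None:
    """Cheap per-line scan so parse errors can name the offending line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PdbParseError("truncated ATOM/HETATM record", lineno)
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise PdbParseError(
                    f"unparseable coordinate field {fieldtxt!r}", lineno
                ) from None
        try:
            int(line[22:26].strip())
        except ValueError:
            raise PdbParseError(
                f"unparseable residue number {line[22:26].strip()!r}", lineno
            ) from None


def read_pdb_models(source, frame_interval: float = 100.0, label: str = "") -> Trajectory:
    """Read a (multi-model) PDB file or text into a :class:`Trajectory`.

    One ``MODEL`` becomes one frame; a file without MODEL records yields a
    single frame.  HETATM records (metal ions in particular) are retained.
    Alternate locations other than blank/'A' are dropped; insertion-coded
    residues are rejected outright.
    """
    text = _as_text(source)
    _validate_pdb_lines(text)
    pdb_file = bpdb.PDBFile.read(io.StringIO(text))
    try:
        atoms = pdb_file.get_structure(model=None, altloc="all")
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        msg = str(exc)
        if "model" in msg.lower() or "array length" in msg.lower():
            raise StructuralMismatchError(
                f"models have inconsistent atom tables: {msg}"
            ) from exc
        raise PdbParseError(msg) from exc

    if np.any(atoms.ins_code != ""):
        bad = np.flatnonzero(atoms.ins_code != "")[0]
        raise PdbParseError(
            f"insertion-coded residue {atoms.chain_id[bad]}:"
            f"{atoms.res_id[bad]}{atoms.ins_code[bad]} not supported"
        )

    if "altloc_id" in atoms.get_annotation_categories():
        keep = np.isin(atoms.altloc_id, ["", " ", "A"])
        if not keep.all():
            atoms = atoms[..., keep]

    table = AtomTable(
        atoms.chain_id,
        atoms.res_id,
        atoms.res_name,
        atoms.atom_name,
        atoms.hetero,
        atoms.element,
    )
    coords = np.asarray(atoms.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    if label == "" and isinstance(source, (str, os.PathLike)):
        try:
            label = Path(source).stem
        except (OSError, ValueError):
            label = ""
    return Trajectory(table, coords, frame_interval, label)


def _to_biotite(traj: Trajectory):
    n = traj.n_atoms
    stack = bst.AtomArrayStack(traj.n_frames, n)
    stack.chain_id = traj.table.chain_id.astype("U4")
    stack.res_id = traj.table.res_num.astype(int)
    stack.ins_code = np.full(n, "", dtype="U1")
    stack.res_name = traj.table.res_name.astype("U5")
    stack.hetero = traj.table.hetero.astype(bool)
    stack.atom_name = traj.table.atom_name.astype("U6")
    stack.element = traj.table.element.astype("U2")
    stack.coord = traj.coords.astype(np.float32)
    return stack


def write_pdb(traj: Trajectory | Structure, path) -> None:
    """Write a trajectory as a multi-model PDB (or a structure as single-model).

    A one-frame trajectory is written without MODEL records (single-model
    dialect), so crystal-style files round-trip unchanged.  Coordinates must
    fit the fixed-width %8.3f field.
    """
    if isinstance(traj, Structure):
        traj = traj.to_trajectory()
    coords = traj.coords
    if coords.min() < _COORD_MIN or coords.max() > _COORD_MAX:
        raise CoordinateOverflowError(
            f"coordinate outside [{_COORD_MIN}, {_COORD_MAX}] Å does not fit "
            "the PDB %8.3f field"
        )
    stack = _to_biotite(traj)
    pdb_file = bpdb.PDBFile()
    if traj.n_frames == 1:
        pdb_file.set_structure(stack[0])
    else:
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))
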