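"""Reading protein structures and exposing per-residue coordinate sets.

Structures are parsed from PDB ATOM records (one chain at a time) into a
light-weight :class:`Structure` of :class:`Residue` objects.  Residues are
renumbered 1..L in chain order; the original author numbering is kept only
as metadata.  Three coordinate "bases" are supported for inter-residue
distance computations: the Cα atom, the Cβ atom (falling back to Cα for
glycine or truncated side chains), and the full set of heavy (non-hydrogen)
atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

_HYDROGEN_ELEMENTS = ("H", "D")


class ContactBase(str, Enum):
    """Atom set used to measure the distance between two residues."""

    CA = "CA"
    CB = "CB"
    HEAVY = "HEAVY"


@dataclass(frozen=True)
class Residue:
    """One residue with the coordinates needed by every contact base.

    ``heavy_atoms`` holds all non-hydrogen atoms (backbone and side chain);
    ``ca``/``cb`` are views into it when those atoms exist.
    """

    seq_index: int
    res_name: str
    ca: np.ndarray | None
    cb: np.ndarray | None
    heavy_atoms: np.ndarray  # shape (n_atoms, 3)
    atom_names: tuple[str, ...] = ()
    orig_id: str = ""

    def __post_init__(self) -> None:
        if len(self.heavy_atoms) == 0:
            raise ValueError(f"residue {self.seq_index}: empty heavy-atom set")


@dataclass
class Structure:
    """An ordered chain of residues with contiguous 1-based indices."""

    id: str
    residues: list[Residue]
    ca_only: bool = False
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"structure {self.id!r} has no residues")
        for pos, res in enumerate(self.residues, start=1):
            if res.seq_index != pos:
                raise ValueError(
                    f"structure {self.id!r}: residue indices are not "
                    f"contiguous 1..L (found {res.seq_index} at position {pos})"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(r.res_name for r in self.residues)


def read_structure(
    path: str | Path,
    chain_id: str,
    residue_range: tuple[int, int] | None = None,
) -> Structure:
    """Read one chain from a PDB file into a :class:`Structure`.

    Only ATOM records are used; hydrogens are dropped and the first altloc
    conformer is kept.  ``residue_range`` is an inclusive span in the
    original author numbering, used to carve domains out of full chains.
    A chain that carries only Cα atoms is returned with ``ca_only=True``
    so the caller can decide whether to discard it.
    """
    path = Path(path)
    atoms = PDBFile.read(str(path)).get_structure(model=1, altloc="first")
    atoms = atoms[(atoms.chain_id == chain_id) & ~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records for chain {chain_id!r}")
    atoms = atoms[~np.isin(atoms.element, _HYDROGEN_ELEMENTS)]
    if residue_range is not None:
        lo, hi = residue_range
        atoms = atoms[(atoms.res_id >= lo) & (atoms.res_id <= hi)]
    if atoms.array_length() == 0:
        raise ValueError(
            f"{path}: chain {chain_id!r} has no residues after filtering"
        )

    residues: list[Residue] = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    prev_num: int | None = None
    contiguous = True
    for k in range(len(starts) - 1):
        seg = atoms[starts[k] : starts[k + 1]]
        num = int(seg.res_id[0])
        icode = str(seg.ins_code[0]) if hasattr(seg, "ins_code") else ""
        if prev_num is not None and num != prev_num + 1:
            contiguous = False
        prev_num = num
        names = tuple(str(n) for n in seg.atom_name)
        coords = np.asarray(seg.coord, dtype=float)
        ca = coords[names.index("CA")] if "CA" in names else None
        cb = coords[names.index("CB")] if "CB" in names else None
        residues.append(
            Residue(
                seq_index=k + 1,
                res_name=str(seg.res_name[0]),
                ca=ca,
                cb=cb,
                heavy_atoms=coords,
                atom_names=names,
                orig_id=f"{num}{icode}".strip(),
            )
        )
    if not contiguous:
        logger.warning(
            "%s chain %s: original residue numbering has gaps/jumps; "
            "renumbered 1..%d", path.name, chain_id, len(residues)
        )

    ca_only = all(
        len(r.heavy_atoms) == 1 and r.ca is not None for r in residues
    )
    if ca_only:
        logger.warning(
            "%s chain %s is a Calpha-only trace (flagged, not discarded)",
            path.name, chain_id,
        )
    sid = f"{path.stem}{chain_id}"
    return Structure(id=sid, residues=residues, ca_only=ca_only, source=str(path))


def base_coordinates(
    s: Structure, base: ContactBase | str
) -> np.ndarray | list[np.ndarray]:
    """Per-residue coordinates for ``base``.

    CA and CB return an ``(L, 3)`` array (CB substitutes Cα for glycine or
    a missing side chain); HEAVY returns a list of per-residue atom arrays.
    """
    base = ContactBase(base)
    if base is ContactBase.CA:
        missing = [r.seq_index for r in s.residues if r.ca is None]
        if missing:
            raise ValueError(
                f"structure {s.id!r}: residues without Calpha: {missing}"
            )
        return np.array([r.ca for r in s.residues], dtype=float)
    if base is ContactBase.CB:
        coords = np.empty((s.length, 3), dtype=float)
        for k, r in enumerate(s.residues):
            if r.cb is not None:
                coords[k] = r.cb
            elif r.ca is not None:
                if r.res_name != "GLY":
                    logger.warning(
                        "structure %s residue %d (%s): missing Cbeta, "
                        "substituting Calpha", s.id, r.seq_index, r.res_name
                    )
                coords[k] = r.ca
            else:
                raise ValueError(
                    f"structure {s.id!r} residue {r.seq_index}: "
                    "neither Cbeta nor Calpha present"
                )
        return coords
    return [np.asarray(r.heavy_atoms, dtype=float) for r in s.residues]


def write_structure(s: Structure, path: str | Path, chain_id: str = "A") -> None:
    """Write a structure as a minimal single-chain PDB file."""
    n_atoms = sum(len(r.heavy_atoms) for r in s.residues)
    arr = struc.AtomArray(n_atoms)
    idx = 0
    for r in s.residues:
        names: Sequence[str] = r.atom_names
        if len(names) != len(r.heavy_atoms):
            names = [f"X{k + 1}" for k in range(len(r.heavy_atoms))]
        for name, coord in zip(names, r.heavy_atoms):
            arr.chain_id[idx] = chain_id
            arr.res_id[idx] = r.seq_index
            arr.res_name[idx] = r.res_name
            arr.atom_name[idx] = name
            arr.element[idx] = name[0] if name else "C"
            arr.hetero[idx] = False
            arr.coord[idx] = np.asarray(coord, dtype=float)
            idx += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
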