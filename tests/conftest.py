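"""Shared fixtures: hand-written PDB snippets and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from contactfold import ContactBase
from contactfold.synthetic import make_coil, make_helix, make_sheet


def pdb_atom(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    x: float,
    y: float,
    z: float,
    element: str | None = None,
    altloc: str = " ",
    record: str = "ATOM",
) -> str:
    if len(name) < 4:
        name = f" {name:<3}"
    element = element or name.strip()[0]
    return (
        f"{record:<6}{serial:>5} {name}{altloc}{res_name:<3} {chain}"
        f"{res_seq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {element:>2}"
    )


def ala_residue(serial0: int, res_seq: int, chain: str = "A",
                origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> list[str]:
    """Full backbone + CB alanine: 5 heavy atoms."""
    ox, oy, oz = origin
    atoms = [
        ("N", -1.458, 0.0, 0.0),
        ("CA", 0.0, 0.0, 0.0),
        ("C", 0.55, 1.42, 0.0),
        ("O", 1.20, 1.78, 0.97),
        ("CB", 0.54, -0.78, 1.21),
    ]
    return [
        pdb_atom(serial0 + k, name, "ALA", chain, res_seq,
                 ox + dx, oy + dy, oz + dz)
        for k, (name, dx, dy, dz) in enumerate(atoms)
    ]


@pytest.fixture
def three_ala_pdb(tmp_path):
    """3 ALA residues with full backbone + CB, plus decoys the parser must
    ignore: a hydrogen, a HETATM, and a foreign chain."""
    lines = []
    for k in range(3):
        lines += ala_residue(1 + 5 * k, k + 1, origin=(3.8 * k, 0.0, 0.0))
    lines.append(pdb_atom(90, "HB1", "ALA", "A", 1, 0.5, -1.5, 1.2, element="H"))
    lines.append(pdb_atom(91, "O", "HOH", "A", 99, 9.0, 9.0, 9.0, record="HETATM"))
    lines.append(pdb_atom(92, "CA", "GLY", "B", 1, 0.0, 5.0, 0.0))
    path = tmp_path / "three_ala.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def gly_pdb(tmp_path):
    """ALA then GLY (no CB) in chain A."""
    lines = ala_residue(1, 1)
    for k, (name, dx, dy, dz) in enumerate(
        [("N", -1.458, 0.0, 0.0), ("CA", 0.0, 0.0, 0.0), ("C", 0.55, 1.42, 0.0),
         ("O", 1.20, 1.78, 0.97)]
    ):
        lines.append(pdb_atom(10 + k, name, "GLY", "A", 2, 3.8 + dx, dy, dz))
    path = tmp_path / "gly.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def gapped_numbering_pdb(tmp_path):
    """Residues numbered 10, 11, 13 (insertion gap)."""
    lines = []
    for k, num in enumerate((10, 11, 13)):
        lines += ala_residue(1 + 5 * k, num, origin=(3.8 * k, 0.0, 0.0))
    path = tmp_path / "gapped.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)

def brute_force_contacts(structure, base, cutoff, min_separation=3):
    """O(L^2 * A^2) all-pairs enumeration, independent of the library path."""
    base = ContactBase(base)
    coords = []
    for r in structure.residues:
        if base is ContactBase.CA:
            coords.append([r.ca])
        elif base is ContactBase.CB:
            coords.append([r.cb if r.cb is not None else r.ca])
        else:
            coords.append(list(r.heavy_atoms))
    contacts = set()
    L = structure.length
    for i in range(L):
        for j in range(i + 1, L):
            if j - i < min_separation:
                continue
            best = min(
                float(np.linalg.norm(np.asarray(a) - np.asarray(b)))
                for a in coords[i]
                for b in coords[j]
            )
            if best <= cutoff:
                contacts.add((i + 1, j + 1))
    return contacts


def mann_whitney_auc(pos, neg):
    """AUC as the pairwise win fraction with ties counted 1/2."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_structure(rng):
    """A small (<= 30 residue) structure of a random flavour."""
    kind = rng.integers(0, 3)
    seed = int(rng.integers(0, 2**31 - 1))
    if kind == 0:
        return make_helix(int(rng.integers(6, 31)), sid=f"h{seed}")
    if kind == 1:
        return make_sheet(
            int(rng.integers(2, 4)), int(rng.integers(3, 9)), sid=f"s{seed}"
        )
    return make_coil(int(rng.integers(8, 31)), seed=seed, sid=f"c{seed}")
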