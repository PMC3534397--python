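"""Residue contact maps under parameterized (base, cutoff) definitions.

A contact map is the set of residue index pairs (i, j), i < j, whose
base-atom distance is at or below a cutoff and whose sequence separation
j - i is at least ``min_separation`` (default 3, i.e. neighbours at
separation 1 and 2 are never contacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ContactBase, Structure, base_coordinates

logger = logging.getLogger(__name__)

#: Cutoff grid used throughout the retrieval experiments (angstrom).
CANONICAL_CUTOFFS: tuple[float, ...] = (
    4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0,
    10.0, 12.0, 15.0, 20.0, 30.0, 50.0, 100.0,
)

DEFAULT_MIN_SEPARATION = 3


@dataclass(frozen=True)
class ContactDefinition:
    """One (base, cutoff, min_separation) contact definition."""

    base: ContactBase
    cutoff: float
    min_separation: int = DEFAULT_MIN_SEPARATION
    separation_bin: tuple[int, int | None] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", ContactBase(self.base))
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.min_separation < 1:
            raise ValueError(
                f"min_separation must be >= 1, got {self.min_separation}"
            )

    @property
    def label(self) -> str:
        s = f"{self.base.value}_{self.cutoff:g}"
        if self.separation_bin is not None:
            lo, hi = self.separation_bin
            s += f"_sep{lo}-{hi if hi is not None else 'inf'}"
        return s


def canonical_definitions(
    bases: Iterable[ContactBase | str] = ContactBase,
    cutoffs: Iterable[float] = CANONICAL_CUTOFFS,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list[ContactDefinition]:
    """The full bases x cutoffs grid (3 x 15 = 45 definitions by default)."""
    return [
        ContactDefinition(ContactBase(b), c, min_separation)
        for b in bases
        for c in cutoffs
    ]


@dataclass(frozen=True)
class ContactMap:
    """Set of contacting residue pairs for one structure and definition."""

    structure_id: str
    length: int
    definition: ContactDefinition
    contacts: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        sep = self.definition.min_separation
        for i, j in self.contacts:
            if not (1 <= i < j <= self.length):
                raise ValueError(
                    f"contact ({i}, {j}) out of range for length {self.length}"
                )
            if j - i < sep:
                raise ValueError(
                    f"contact ({i}, {j}) violates min separation {sep}"
                )

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.contacts))


def n_eligible_pairs(length: int, min_separation: int) -> int:
    """Number of (i, j) pairs with i < j and j - i >= min_separation."""
    total = length * (length - 1) // 2
    near = sum(max(length - s, 0) for s in range(1, min_separation))
    return total - near


def build_contact_map(s: Structure, d: ContactDefinition) -> ContactMap:
    """Build the contact map of ``s`` under definition ``d``.

    The base distance is the Cα–Cα distance (CA), the Cβ–Cβ distance with
    the glycine Cα substitution (CB), or the minimum over all heavy-atom
    pairs of the two residues (HEAVY).  A distance exactly equal to the
    cutoff counts as a contact.
    """
    L = s.length
    if L < d.min_separation + 1:
        logger.warning(
            "structure %s (length %d) has no pairs at separation >= %d; "
            "empty contact map", s.id, L, d.min_separation
        )
        return ContactMap(s.id, L, d, frozenset())

    dmat = _base_distance_matrix(s, d.base)
    ii, jj = np.triu_indices(L, k=d.min_separation)
    mask = dmat[ii, jj] <= d.cutoff
    contacts = frozenset(
        (int(i) + 1, int(j) + 1) for i, j in zip(ii[mask], jj[mask])
    )
    return ContactMap(s.id, L, d, contacts)


def _base_distance_matrix(s: Structure, base: ContactBase) -> np.ndarray:
    if base is not ContactBase.HEAVY:
        coords = base_coordinates(s, base)
        return cdist(coords, coords)
    atom_lists = base_coordinates(s, ContactBase.HEAVY)
    counts = [len(a) for a in atom_lists]
    coords = np.vstack(atom_lists)
    ridx = np.repeat(np.arange(s.length), counts)
    atom_d = cdist(coords, coords)
    dmat = np.full((s.length, s.length), np.inf)
    ii = np.broadcast_to(ridx[:, None], atom_d.shape)
    jj = np.broadcast_to(ridx[None, :], atom_d.shape)
    np.minimum.at(dmat, (ii.ravel(), jj.ravel()), atom_d.ravel())
    return dmat


def occupancy(m: ContactMap, denominator: str = "eligible") -> float:
    """Fraction of residue pairs in contact.

    ``denominator="eligible"`` (default) divides by the pairs at separation
    >= min_separation, so a saturating cutoff yields 1.0; ``"all"`` divides
    by every i < j pair, for sensitivity checks.
    """
    if denominator == "eligible":
        denom = n_eligible_pairs(m.length, m.definition.min_separation)
    elif denominator == "all":
        denom = m.length * (m.length - 1) // 2
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError(
            f"map {m.structure_id!r}: no eligible pairs at length {m.length}"
        )
    return len(m.contacts) / denom


def filter_by_separation(
    m: ContactMap, lo: int, hi: int | None = None
) -> ContactMap:
    """Keep contacts with lo <= j - i <= hi (inclusive; ``hi=None`` unbounded)."""
    if lo < m.definition.min_separation:
        raise ValueError(
            f"lo={lo} below the map's min separation {m.definition.min_separation}"
        )
    if hi is not None and lo > hi:
        raise ValueError(f"empty separation bin [{lo}, {hi}]")
    kept = frozenset(
        (i, j)
        for i, j in m.contacts
        if j - i >= lo and (hi is None or j - i <= hi)
    )
    d = replace(m.definition, min_separation=lo, separation_bin=(lo, hi))
    return ContactMap(m.structure_id, m.length, d, kept)


# ---------------------------------------------------------------------------
# Plain-text serialization

def write_map_tsv(m: ContactMap, path: str | Path) -> None:
    d = m.definition
    with open(path, "w") as fh:
        fh.write(f"# id: {m.structure_id}\n")
        fh.write(f"# length: {m.length}\n")
        fh.write(f"# base: {d.base.value}\n")
        fh.write(f"# cutoff: {d.cutoff:g}\n")
        fh.write(f"# min_separation: {d.min_separation}\n")
        for i, j in sorted(m.contacts):
            fh.write(f"{i}\t{j}\n")


def read_map_tsv(path: str | Path) -> ContactMap:
    meta: dict[str, str] = {}
    contacts = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line:
                i, j = line.split("\t")
                contacts.add((int(i), int(j)))
    d = ContactDefinition(
        ContactBase(meta["base"]),
        float(meta["cutoff"]),
        int(meta["min_separation"]),
    )
    return ContactMap(meta["id"], int(meta["length"]), d, frozenset(contacts))


def write_casp_rr(m: ContactMap, path: str | Path) -> None:
    """CASP-RR-like rows ``i j 0 cutoff 1.0`` for interoperability."""
    with open(path, "w") as fh:
        for i, j in sorted(m.contacts):
            fh.write(f"{i} {j} 0 {m.definition.cutoff:g} 1.0\n")
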