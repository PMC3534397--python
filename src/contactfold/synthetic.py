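"""Synthetic structures, fold families, and corrupted alignments.

Stand-in data with the statistical structure the retrieval analysis
assumes: groups of structures sharing an idealized topology (helix
bundles, antiparallel sheets, mixed folds) with per-member coordinate
noise, exact gold alignments inherited from the shared backbone, and
"threading-like" corrupted alignments with controlled block-shift error.

Geometry is deliberately minimal: every residue carries only a Cα and a
Cβ pseudo-atom (heavy_atoms = {Cα, Cβ}), which is enough to exercise all
three contact bases.  Helices use the ideal α-helix parameters (1.5 Å
rise, 100° twist, 2.3 Å radius); sheet Cβ atoms alternate sides of the
sheet plane so that cross-strand Cβ pairs alternate near/far, the way
side chains of neighbouring β strands can point in opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .alignments import PairwiseAlignment
from .retrieval import DatasetIndex, IndexEntry
from .structure_io import Residue, Structure

HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
CB_LENGTH = 1.53
STRAND_STEP = 3.4
SHEET_SPACING = 4.8
CLASH_DISTANCE = 3.5


# ---------------------------------------------------------------------------
# Elementary generators

def _structure_from_atoms(
    sid: str, ca: np.ndarray, cb: np.ndarray, res_name: str = "ALA"
) -> Structure:
    residues = [
        Residue(
            seq_index=k + 1,
            res_name=res_name,
            ca=ca[k],
            cb=cb[k],
            heavy_atoms=np.stack([ca[k], cb[k]]),
            atom_names=("CA", "CB"),
        )
        for k in range(len(ca))
    ]
    return Structure(id=sid, residues=residues)


def _helix_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    theta = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n)
    ca = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * np.arange(n)]
    )
    radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    cb = ca + CB_LENGTH * radial
    return ca, cb


def make_helix(n: int, sid: str = "helix") -> Structure:
    """Ideal α-helix with Cβ pointing radially outward from the axis."""
    if n < 4:
        raise ValueError(f"a helix needs at least 4 residues, got {n}")
    ca, cb = _helix_coords(n)
    return _structure_from_atoms(sid, ca, cb)


def _sheet_coords(
    n_strands: int, strand_len: int, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    ca_rows, cb_rows = [], []
    for s in range(n_strands):
        slots = np.arange(strand_len)
        if s % 2 == 1:
            slots = slots[::-1]  # antiparallel: odd strands run backwards
        x = STRAND_STEP * slots
        y = np.full(strand_len, spacing * s)
        z = np.zeros(strand_len)
        ca = np.column_stack([x, y, z])
        # pleat: Cbeta side alternates with position ALONG the strand, so
        # cross-strand pairs offset by one slot point to opposite sides
        zsign = np.where(slots % 2 == 0, 1.0, -1.0)
        cb = ca + np.column_stack(
            [np.zeros(strand_len), np.zeros(strand_len), CB_LENGTH * zsign]
        )
        ca_rows.append(ca)
        cb_rows.append(cb)
    return np.vstack(ca_rows), np.vstack(cb_rows)


def make_sheet(
    n_strands: int,
    strand_len: int,
    strand_spacing: float = SHEET_SPACING,
    sid: str = "sheet",
) -> Structure:
    """Antiparallel β-sheet of extended strands (Cα step 3.4 Å)."""
    if n_strands < 2:
        raise ValueError(f"a sheet needs at least 2 strands, got {n_strands}")
    if strand_len < 3:
        raise ValueError(f"strands need at least 3 residues, got {strand_len}")
    ca, cb = _sheet_coords(n_strands, strand_len, strand_spacing)
    return _structure_from_atoms(sid, ca, cb)


def make_coil(n: int, seed: int = 0, sid: str = "coil") -> Structure:
    """Self-avoiding-ish random walk with 3.8 Å Cα steps; a compact
    unstructured chain for oracle and property tests."""
    if n < 2:
        raise ValueError("a coil needs at least 2 residues")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
    cb_dir = rng.normal(size=(n, 3))
    cb_dir /= np.linalg.norm(cb_dir, axis=1, keepdims=True)
    return _structure_from_atoms(sid, ca, ca + CB_LENGTH * cb_dir)


# ---------------------------------------------------------------------------
# Fold specifications

@dataclass(frozen=True)
class SSElement:
    """One placed secondary-structure element.

    ``euler`` are XYZ Euler angles in degrees applied to the element's
    local coordinates (helix axis = z, strand axis = x) before adding
    ``translation``.
    """

    kind: str  # "helix" | "strand"
    length: int
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pleat_offset: int = 0  # shifts the strand Cbeta alternation phase


@dataclass(frozen=True)
class FoldSpec:
    fold_id: str
    elements: tuple[SSElement, ...]
    loop_length: int = 2
    class_id: str = "other"

    @property
    def total_length(self) -> int:
        n = sum(e.length for e in self.elements)
        return n + self.loop_length * (len(self.elements) - 1)


def _element_coords(e: SSElement) -> tuple[np.ndarray, np.ndarray]:
    if e.kind == "helix":
        ca, cb = _helix_coords(e.length)
    elif e.kind == "strand":
        slots = np.arange(e.length)
        ca = np.column_stack(
            [STRAND_STEP * slots, np.zeros(e.length), np.zeros(e.length)]
        )
        zsign = np.where((slots + e.pleat_offset) % 2 == 0, 1.0, -1.0)
        cb = ca.copy()
        cb[:, 2] += CB_LENGTH * zsign
    else:
        raise ValueError(f"unknown element kind {e.kind!r}")
    rot = Rotation.from_euler("xyz", e.euler, degrees=True)
    t = np.asarray(e.translation)
    return rot.apply(ca) + t, rot.apply(cb) + t


def build_fold_structure(
    spec: FoldSpec, sid: str | None = None
) -> tuple[Structure, list[str]]:
    """Assemble the placed elements, bridging them with straight loops.

    Loop residues are pushed slightly outward from the fold centroid to
    avoid bumping into element atoms.  Returns the structure and the
    per-residue element kind ("helix" / "strand" / "loop").
    """
    placed = [_element_coords(e) for e in spec.elements]
    centroid = np.vstack([ca for ca, _ in placed]).mean(axis=0)
    ca_all: list[np.ndarray] = []
    cb_all: list[np.ndarray] = []
    kinds: list[str] = []
    for k, (e, (ca, cb)) in enumerate(zip(spec.elements, placed)):
        if k > 0 and spec.loop_length > 0:
            start = ca_all[-1]
            end = ca[0]
            chord = end - start
            u = chord / max(np.linalg.norm(chord), 1e-9)
            out = (start + end) / 2.0 - centroid
            out = out - (out @ u) * u  # bump perpendicular to the chord
            norm = np.linalg.norm(out)
            out = out / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            for m in range(1, spec.loop_length + 1):
                f = m / (spec.loop_length + 1)
                p = start + f * chord + (3.4 * np.sin(np.pi * f)) * out
                ca_all.append(p)
                cb_all.append(p + np.array([0.0, 0.0, CB_LENGTH]))
                kinds.append("loop")
        ca_all.extend(ca)
        cb_all.extend(cb)
        kinds.extend([e.kind] * e.length)
    struct = _structure_from_atoms(
        sid or spec.fold_id, np.asarray(ca_all), np.asarray(cb_all)
    )
    return struct, kinds


def min_nonadjacent_ca_distance(s: Structure) -> float:
    """Smallest Cα–Cα distance over residue pairs with |i - j| > 1."""
    ca = np.array([r.ca for r in s.residues])
    d = cdist(ca, ca)
    L = len(ca)
    ii, jj = np.triu_indices(L, k=2)
    return float(d[ii, jj].min())


# ---------------------------------------------------------------------------
# Fold families

def make_fold_family(
    spec: FoldSpec,
    n_members: int,
    noise_sigma: float = 0.5,
    indel_prob: float = 0.0,
    seed: int = 0,
) -> tuple[list[Structure], dict[tuple[str, str], PairwiseAlignment]]:
    """Noisy copies of one fold plus exact gold alignments between them.

    Each member adds isotropic per-atom Gaussian noise to the shared
    backbone; with ``indel_prob`` loop residues are independently deleted.
    The gold alignment of two members is the correspondence inherited
    from the shared backbone, restricted to residues kept in both.
    """
    if n_members < 2:
        raise ValueError("a family needs at least 2 members")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base, kinds = build_fold_structure(spec)
    ca0 = np.array([r.ca for r in base.residues])
    cb0 = np.array([r.cb for r in base.residues])
    L = base.length

    members: list[Structure] = []
    kept_positions: list[np.ndarray] = []
    for m in range(n_members):
        keep = np.ones(L, dtype=bool)
        if indel_prob > 0:
            for k in range(L):
                if kinds[k] == "loop" and rng.random() < indel_prob:
                    keep[k] = False
        ca = ca0[keep] + rng.normal(0.0, noise_sigma, (keep.sum(), 3))
        cb = cb0[keep] + rng.normal(0.0, noise_sigma, (keep.sum(), 3))
        members.append(
            _structure_from_atoms(f"{spec.fold_id}m{m}", ca, cb)
        )
        kept_positions.append(np.flatnonzero(keep))

    gold: dict[tuple[str, str], PairwiseAlignment] = {}
    for a, b in combinations(range(n_members), 2):
        pa, pb = kept_positions[a], kept_positions[b]
        ranka = {pos: k + 1 for k, pos in enumerate(pa)}
        rankb = {pos: k + 1 for k, pos in enumerate(pb)}
        shared = sorted(set(pa) & set(pb))
        pairs = tuple((ranka[p], rankb[p]) for p in shared)
        qid, tid = members[a].id, members[b].id
        gold[(qid, tid)] = PairwiseAlignment(qid, tid, pairs, source="gold")
    return members, gold


# ---------------------------------------------------------------------------
# Alignment corruption

@dataclass(frozen=True)
class CorruptionModel:
    """Threading-like misalignment: contiguous blocks shifted on the
    template side, residues dropped from the alignment."""

    shift_prob: float = 0.5
    max_shift: int = 3
    block_length: float = 6.0
    unaligned_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.shift_prob, self.unaligned_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")


def corrupt_alignment(
    gold: PairwiseAlignment,
    model: CorruptionModel,
    rng: np.random.Generator | None = None,
) -> PairwiseAlignment:
    """Shift blocks of template indices and drop residues, keeping the
    result monotone and one-to-one."""
    if len(gold.pairs) == 0:
        raise ValueError("cannot corrupt an empty alignment")
    if rng is None:
        rng = np.random.default_rng(model.seed)

    pairs = list(gold.pairs)
    shifted: list[tuple[int, int]] = []
    pos = 0
    while pos < len(pairs):
        blk = max(1, int(rng.geometric(1.0 / model.block_length)))
        block = pairs[pos : pos + blk]
        if rng.random() < model.shift_prob:
            k = int(rng.integers(1, model.max_shift + 1))
            if rng.random() < 0.5:
                k = -k
            block = [(q, t + k) for q, t in block if t + k >= 1]
        shifted.extend(block)
        pos += blk

    kept: list[tuple[int, int]] = []
    prev_q = prev_t = 0
    for q, t in shifted:
        if q <= prev_q or t <= prev_t:
            continue  # monotonicity forbids this pair after the shift
        if model.unaligned_prob > 0 and rng.random() < model.unaligned_prob:
            continue
        kept.append((q, t))
        prev_q, prev_t = q, t
    if not kept:  # degenerate corruption: keep one anchor pair
        kept = [gold.pairs[0]]
    return PairwiseAlignment(
        gold.query_id, gold.template_id, tuple(kept), source="corrupted"
    )


# ---------------------------------------------------------------------------
# Cross-fold ("threading-like") alignments between unrelated structures

_MIN_RUN = 4  # every aligned residue keeps an in-run partner >= 3 apart


def _cross_fold_alignment(
    qid: str, tid: str, qlen: int, tlen: int, rng: np.random.Generator
) -> PairwiseAlignment:
    """Monotone alignment of two unrelated structures: runs of constant
    offset (length >= 4) separated by random indels, the way a generic
    aligner strings secondary-structure fragments together."""
    pairs: list[tuple[int, int]] = []
    q = int(rng.integers(1, 4))
    t = int(rng.integers(1, 4))
    while q <= qlen - _MIN_RUN + 1 and t <= tlen - _MIN_RUN + 1:
        run = int(rng.integers(_MIN_RUN, 13))
        run = min(run, qlen - q + 1, tlen - t + 1)
        if run < _MIN_RUN:
            break
        pairs.extend((q + k, t + k) for k in range(run))
        q += run + int(rng.integers(0, 5))
        t += run + int(rng.integers(0, 5))
    if not pairs:  # tiny chains: fall back to a short identity stub
        n = min(qlen, tlen, _MIN_RUN)
        pairs = [(k + 1, k + 1) for k in range(n)]
    return PairwiseAlignment(qid, tid, tuple(pairs), source="cross-fold")


# ---------------------------------------------------------------------------
# Benchmark assembly

_ARCHETYPES = ("helix_bundle", "sheet4", "mixed_ab", "sheet5", "mixed_a+b")

_CLASS_OF_ARCHETYPE = {
    "helix_bundle": "a",
    "sheet4": "b",
    "mixed_ab": "a/b",
    "sheet5": "b",
    "mixed_a+b": "a+b",
}


def _fold_spec(fold_idx: int) -> FoldSpec:
    """Deterministic catalog of distinct fold topologies."""
    arch = _ARCHETYPES[fold_idx % len(_ARCHETYPES)]
    var = fold_idx // len(_ARCHETYPES)  # size variant for extra folds
    fid = f"F{fold_idx:02d}"
    if arch == "helix_bundle":
        h = 14 + 2 * var
        elements = (
            SSElement("helix", h),
            SSElement("helix", h, euler=(180.0, 0.0, 0.0),
                      translation=(10.0, 0.0, HELIX_RISE * (h - 1))),
            SSElement("helix", h, translation=(5.0, 9.0, 0.0)),
        )
    elif arch == "sheet4":
        L = 8 + var
        elements = tuple(
            SSElement(
                "strand", L,
                euler=(0.0, 0.0, 180.0) if s % 2 else (0.0, 0.0, 0.0),
                translation=(
                    (STRAND_STEP * (L - 1) if s % 2 else 0.0),
                    SHEET_SPACING * s,
                    0.0,
                ),
                pleat_offset=(L - 1) % 2 if s % 2 else 0,
            )
            for s in range(4)
        )
    elif arch == "sheet5":
        L = 6 + var
        elements = tuple(
            SSElement(
                "strand", L,
                euler=(0.0, 0.0, 180.0) if s % 2 else (0.0, 0.0, 0.0),
                translation=(
                    (STRAND_STEP * (L - 1) if s % 2 else 0.0),
                    5.2 * s,
                    0.0,
                ),
                pleat_offset=(L - 1) % 2 if s % 2 else 0,
            )
            for s in range(5)
        )
    elif arch == "mixed_ab":
        h, L = 12 + var, 7
        elements = (
            SSElement("strand", L),
            SSElement("strand", L, euler=(0.0, 0.0, 180.0),
                      translation=(STRAND_STEP * (L - 1), SHEET_SPACING, 0.0),
                      pleat_offset=(L - 1) % 2),
            SSElement("helix", h, euler=(0.0, 90.0, 0.0),
                      translation=(0.0, 2.4, 9.0)),
        )
    else:  # mixed_a+b: helix, then a hairpin stacked above the helix top
        h, L = 12 + var, 7
        ztop = HELIX_RISE * (h - 1) + 4.5
        elements = (
            SSElement("helix", h),
            SSElement("strand", L, translation=(4.0, 0.0, ztop)),
            SSElement("strand", L, euler=(0.0, 0.0, 180.0),
                      translation=(4.0 + STRAND_STEP * (L - 1), SHEET_SPACING, ztop),
                      pleat_offset=(L - 1) % 2),
        )
    return FoldSpec(
        fold_id=fid,
        elements=elements,
        loop_length=2,
        class_id=_CLASS_OF_ARCHETYPE[arch],
    )


@dataclass
class Benchmark:
    """A desk-scale retrieval dataset: structures, labels, alignments."""

    index: DatasetIndex
    structures: dict[str, Structure]
    alignments: dict[tuple[str, str], PairwiseAlignment]
    gold_alignments: dict[tuple[str, str], PairwiseAlignment] = field(
        default_factory=dict
    )
    seed: int = 0


def make_benchmark(
    n_folds: int = 5,
    members_per_fold: int = 4,
    class_mix: Sequence[str] | None = None,
    noise_sigma: float = 0.5,
    corruption: CorruptionModel | None = None,
    indel_prob: float = 0.0,
    seed: int = 0,
) -> Benchmark:
    """Generate a complete retrieval benchmark, reproducible from ``seed``.

    Distinct fold topologies are drawn from a fixed archetype catalog
    (``class_mix`` restricts it to archetypes of the named classes).  Gold
    alignments connect members of the same fold; unrelated pairs get
    threading-like fragment alignments.  When ``corruption`` is given,
    every alignment is corrupted and the gold set is kept alongside.
    """
    if n_folds < 2:
        raise ValueError("a benchmark needs at least 2 folds")
    if members_per_fold < 2:
        raise ValueError("each fold needs at least 2 members")
    rng = np.random.default_rng(seed)

    fold_indices: list[int]
    if class_mix is None:
        fold_indices = list(range(n_folds))
    else:
        wanted = list(class_mix)
        pool = {c: [k for k, a in enumerate(_ARCHETYPES) if _CLASS_OF_ARCHETYPE[a] == c]
                for c in set(wanted)}
        fold_indices = []
        used: dict[str, int] = {}
        for c in (wanted * n_folds)[:n_folds]:
            if not pool.get(c):
                raise ValueError(f"no archetype for class {c!r}")
            cnt = used.get(c, 0)
            base = pool[c][cnt % len(pool[c])]
            var = cnt // len(pool[c])
            fold_indices.append(base + var * len(_ARCHETYPES))
            used[c] = cnt + 1

    entries: list[IndexEntry] = []
    structures: dict[str, Structure] = {}
    alignments: dict[tuple[str, str], PairwiseAlignment] = {}
    fold_members: dict[str, list[str]] = {}
    for pos, fi in enumerate(fold_indices):
        # relabel positionally so fold ids are unique and ordered even when
        # class_mix reuses archetypes
        spec = replace(_fold_spec(fi), fold_id=f"F{pos:02d}")
        members, gold = make_fold_family(
            spec,
            members_per_fold,
            noise_sigma=noise_sigma,
            indel_prob=indel_prob,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fold_members[spec.fold_id] = [m.id for m in members]
        for k, m in enumerate(members):
            structures[m.id] = m
            entries.append(
                IndexEntry(
                    structure_id=m.id,
                    fold_id=spec.fold_id,
                    superfamily_id=f"{spec.fold_id}S{k % 2}",
                    class_id=spec.class_id,
                )
            )
        alignments.update(gold)

    ids = sorted(structures)
    for qid, tid in combinations(ids, 2):
        if (qid, tid) in alignments:
            continue
        alignments[(qid, tid)] = _cross_fold_alignment(
            qid, tid, structures[qid].length, structures[tid].length, rng
        )

    gold_alignments: dict[tuple[str, str], PairwiseAlignment] = {}
    if corruption is not None:
        gold_alignments = dict(alignments)
        crng = np.random.default_rng(corruption.seed)
        alignments = {
            key: corrupt_alignment(a, corruption, rng=crng)
            for key, a in sorted(alignments.items())
        }

    index = DatasetIndex(entries)
    return Benchmark(
        index=index,
        structures=structures,
        alignments=alignments,
        gold_alignments=gold_alignments,
        seed=seed,
    )
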