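"""Fraction of common contacts (FCC) between two contact maps.

A query contact (a_i, a_j) is *common* when both endpoints are aligned to
template residues (b_m, b_n) that are themselves in contact in the
template map.  The FCC of the query is the number of query residues that
take part in at least one common contact, divided by the number of aligned
residues; it ranges from 0 to 1.  With ``relax=1`` a template contact
within one residue of (b_m, b_n) at either endpoint also matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .alignments import PairwiseAlignment
from .contact_maps import ContactMap


@dataclass(frozen=True)
class FCCResult:
    query_id: str
    template_id: str
    fcc: float
    n_common_contacts: int
    n_query_residues_in_common: int
    n_aligned: int
    relax: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.fcc <= 1.0
        assert (
            self.n_query_residues_in_common
            <= min(2 * self.n_common_contacts, self.n_aligned)
        )


def common_contacts(
    mq: ContactMap,
    mt: ContactMap,
    a: PairwiseAlignment,
    relax: int = 0,
) -> frozenset[tuple[int, int]]:
    """Query contacts whose aligned template pair is also in contact."""
    if mq.structure_id != a.query_id or mt.structure_id != a.template_id:
        raise ValueError(
            f"id mismatch: maps ({mq.structure_id}, {mt.structure_id}) vs "
            f"alignment ({a.query_id}, {a.template_id})"
        )
    if relax not in (0, 1):
        raise ValueError(f"relax must be 0 or 1, got {relax}")
    q2t = a.query_to_template()
    out = set()
    for (ai, aj) in mq.contacts:
        bm, bn = q2t.get(ai), q2t.get(aj)
        if bm is None or bn is None:
            continue
        lo, hi = (bm, bn) if bm < bn else (bn, bm)
        if relax == 0:
            if (lo, hi) in mt.contacts:
                out.add((ai, aj))
        else:
            for dm, dn in product((-1, 0, 1), repeat=2):
                m2, n2 = lo + dm, hi + dn
                cand = (m2, n2) if m2 < n2 else (n2, m2)
                if cand in mt.contacts:
                    out.add((ai, aj))
                    break
    return frozenset(out)


def fraction_common_contacts(
    mq: ContactMap,
    mt: ContactMap,
    a: PairwiseAlignment,
    relax: int = 0,
    symmetric: bool = False,
) -> FCCResult:
    """FCC of the query through alignment ``a`` (optionally the mean of
    both directions)."""
    if len(a.pairs) == 0:
        raise ValueError("FCC is undefined for an empty alignment")
    cc = common_contacts(mq, mt, a, relax=relax)
    residues = {i for pair in cc for i in pair}
    fcc = len(residues) / len(a.pairs)
    if symmetric:
        rev = fraction_common_contacts(mt, mq, a.flipped(), relax=relax)
        fcc = (fcc + rev.fcc) / 2.0
    return FCCResult(
        query_id=a.query_id,
        template_id=a.template_id,
        fcc=fcc,
        n_common_contacts=len(cc),
        n_query_residues_in_common=len(residues),
        n_aligned=len(a.pairs),
        relax=relax,
    )


def score_pairs(
    maps: Mapping[str, ContactMap],
    alignments: Mapping[tuple[str, str], PairwiseAlignment],
    pair_list: Sequence[tuple[str, str, str]],
    relax: int = 0,
) -> pd.DataFrame:
    """Score a (query_id, template_id, label) pair list.

    Alignments may be keyed in either direction; a reversed entry is
    flipped on the fly.  Returns a frame with columns query_id,
    template_id, label, n_aligned, n_common, fcc.
    """
    rows = []
    for qid, tid, label in pair_list:
        mq, mt = maps.get(qid), maps.get(tid)
        if mq is None or mt is None:
            missing = qid if mq is None else tid
            raise KeyError(f"no contact map for structure {missing!r}")
        a = alignments.get((qid, tid))
        if a is None:
            rev = alignments.get((tid, qid))
            if rev is None:
                raise KeyError(f"no alignment for pair ({qid}, {tid})")
            a = rev.flipped()
        res = fraction_common_contacts(mq, mt, a, relax=relax)
        rows.append(
            (qid, tid, label, res.n_aligned, res.n_common_contacts, res.fcc)
        )
    return pd.DataFrame(
        rows,
        columns=["query_id", "template_id", "label", "n_aligned", "n_common", "fcc"],
    )


def write_scores_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
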