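"""Fold-retrieval evaluation: pair sets, ROC/AUC, fold-averaged curves.

For each fold, within-fold pairs are positives and the fold's
representative paired with every foreign structure gives the negatives.
Pairs are ranked by FCC; the per-fold ROC curves are averaged pointwise
(TPR at common FPR) across folds to summarize one contact definition.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .alignments import PairwiseAlignment
from .contact_maps import ContactDefinition, ContactMap, filter_by_separation, occupancy
from .fcc import fraction_common_contacts

logger = logging.getLogger(__name__)

FPR_GRID = np.linspace(0.0, 1.0, 1001)

CLASS_LABELS = ("a", "b", "a/b", "a+b", "other")


@dataclass(frozen=True)
class IndexEntry:
    structure_id: str
    fold_id: str
    superfamily_id: str
    class_id: str


@dataclass
class DatasetIndex:
    """Structure -> fold / superfamily / class labels, plus representatives."""

    entries: list[IndexEntry]
    representatives: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.structure_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate structure ids in dataset index")
        for fold, rep in self.representatives.items():
            if rep not in set(ids):
                raise ValueError(f"representative {rep!r} of {fold!r} not in index")

    def groups(self, level: str = "fold") -> dict[str, list[str]]:
        key = {"fold": "fold_id", "superfamily": "superfamily_id"}[level]
        out: dict[str, list[str]] = {}
        for e in self.entries:
            out.setdefault(getattr(e, key), []).append(e.structure_id)
        return {g: sorted(m) for g, m in out.items()}

    def representative(self, group_id: str, level: str = "fold") -> str:
        if level == "fold" and group_id in self.representatives:
            return self.representatives[group_id]
        members = self.groups(level)[group_id]
        return min(members)

    def class_of_group(self, group_id: str, level: str = "fold") -> str:
        key = {"fold": "fold_id", "superfamily": "superfamily_id"}[level]
        for e in self.entries:
            if getattr(e, key) == group_id:
                return e.class_id
        raise KeyError(group_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DatasetIndex":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = [
            IndexEntry(r.structure_id, r.fold_id, r.superfamily_id, r.class_id)
            for r in df.itertuples()
        ]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("structure_id\tfold_id\tsuperfamily_id\tclass_id\n")
            for e in self.entries:
                fh.write(
                    f"{e.structure_id}\t{e.fold_id}\t{e.superfamily_id}\t{e.class_id}\n"
                )


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )


def build_pair_sets(
    idx: DatasetIndex, group_id: str, level: str = "fold"
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Positives: all within-group pairs; negatives: representative vs every
    structure of a different group."""
    groups = idx.groups(level)
    if group_id not in groups:
        raise KeyError(f"unknown {level} {group_id!r}")
    members = groups[group_id]
    if len(members) < 2:
        raise ValueError(f"{level} {group_id!r} has fewer than 2 members")
    positives = list(combinations(members, 2))
    rep = idx.representative(group_id, level)
    foreign = sorted(
        sid for g, mem in groups.items() if g != group_id for sid in mem
    )
    if not foreign:
        raise ValueError("dataset contains a single group; no negatives")
    negatives = [(rep, sid) for sid in foreign]
    return positives, negatives


def roc_curve(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> ROCCurve:
    """ROC over a descending-score threshold sweep; tied scores step
    simultaneously, so the trapezoidal AUC equals the Mann–Whitney
    statistic with ties counted 1/2."""
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise ValueError("need at least one positive and one negative score")
    y = np.concatenate(
        [np.ones(len(pos_scores)), np.zeros(len(neg_scores))]
    )
    s = np.concatenate([np.asarray(pos_scores, float), np.asarray(neg_scores, float)])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, auc, len(pos_scores), len(neg_scores))


def _tpr_on_grid(c: ROCCurve, grid: np.ndarray) -> np.ndarray:
    # Exact evaluation of the ROC polyline: vertical segments collapse to
    # their top at the knot, diagonal tie-blocks stay linear in between.
    u, first_idx = np.unique(c.fpr, return_index=True)
    # points arrive in sweep order, so per unique FPR the first TPR is the
    # segment entry value and the last is the top of any vertical jump
    last_idx = np.r_[first_idx[1:], len(c.fpr)] - 1
    tpr_in, tpr_top = c.tpr[first_idx], c.tpr[last_idx]
    seg = np.clip(np.searchsorted(u, grid, side="right") - 1, 0, len(u) - 2)
    x0, x1 = u[seg], u[seg + 1]
    y0, y1 = tpr_top[seg], tpr_in[seg + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(x1 > x0, (grid - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0)
    y = y0 + frac * (y1 - y0)
    on_knot = np.isin(grid, u)
    if on_knot.any():
        knot_pos = np.searchsorted(u, grid[on_knot])
        y[on_knot] = tpr_top[knot_pos]
    return y


def average_roc(curves: Sequence[ROCCurve], grid: np.ndarray = FPR_GRID) -> ROCCurve:
    """Pointwise mean TPR of several curves on a common FPR grid."""
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    tprs = np.stack([_tpr_on_grid(c, grid) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    return ROCCurve(
        grid.copy(),
        mean_tpr,
        auc,
        sum(c.n_pos for c in curves),
        sum(c.n_neg for c in curves),
    )


@dataclass
class RetrievalResult:
    auc_table: pd.DataFrame          # fold_id, definition, auc, mean_occupancy, n_pos, n_neg
    averaged: dict[str, ROCCurve]    # definition label -> fold-averaged curve
    summary: pd.DataFrame            # definition, avg_auc, mean_occupancy


def run_retrieval(
    idx: DatasetIndex,
    maps: Mapping[ContactDefinition, Mapping[str, ContactMap]],
    alignments: Mapping[tuple[str, str], PairwiseAlignment],
    definitions: Sequence[ContactDefinition] | None = None,
    class_filter: str | None = None,
    separation_bin: tuple[int, int | None] | None = None,
    relax: int = 0,
    level: str = "fold",
) -> RetrievalResult:
    """Per-fold ROC + fold-averaged ROC/AUC for each contact definition."""
    if definitions is None:
        definitions = list(maps.keys())
    groups = idx.groups(level)
    eligible = [
        g for g, members in sorted(groups.items()) if len(members) >= 2
    ]
    if class_filter is not None:
        eligible = [
            g for g in eligible if idx.class_of_group(g, level) == class_filter
        ]
    if not eligible:
        raise ValueError("no groups left to evaluate")

    rows = []
    averaged: dict[str, ROCCurve] = {}
    summary_rows = []
    for d in definitions:
        dmaps = dict(maps[d])
        if separation_bin is not None:
            lo, hi = separation_bin
            dmaps = {
                sid: filter_by_separation(m, lo, hi) for sid, m in dmaps.items()
            }
        occs = {sid: occupancy(m) for sid, m in dmaps.items()}
        curves = []
        for g in eligible:
            positives, negatives = build_pair_sets(idx, g, level)
            pos = [_score(dmaps, alignments, q, t, relax) for q, t in positives]
            neg = [_score(dmaps, alignments, q, t, relax) for q, t in negatives]
            c = roc_curve(pos, neg)
            curves.append(c)
            members = groups[g]
            rows.append(
                (
                    g,
                    d.label,
                    c.auc,
                    float(np.mean([occs[sid] for sid in members])),
                    c.n_pos,
                    c.n_neg,
                )
            )
        avg = average_roc(curves)
        averaged[d.label] = avg
        summary_rows.append(
            (d.label, avg.auc, float(np.mean(list(occs.values()))))
        )
    auc_table = pd.DataFrame(
        rows,
        columns=["fold_id", "definition", "auc", "mean_occupancy", "n_pos", "n_neg"],
    )
    summary = pd.DataFrame(
        summary_rows, columns=["definition", "avg_auc", "mean_occupancy"]
    )
    return RetrievalResult(auc_table, averaged, summary)


def _score(
    dmaps: Mapping[str, ContactMap],
    alignments: Mapping[tuple[str, str], PairwiseAlignment],
    qid: str,
    tid: str,
    relax: int,
) -> float:
    mq, mt = dmaps.get(qid), dmaps.get(tid)
    if mq is None or mt is None:
        raise KeyError(
            f"missing contact map for pair ({qid}, {tid})"
        )
    a = alignments.get((qid, tid))
    if a is None:
        rev = alignments.get((tid, qid))
        if rev is None:
            raise KeyError(f"missing alignment for pair ({qid}, {tid})")
        a = rev.flipped()
    return fraction_common_contacts(mq, mt, a, relax=relax).fcc


def best_definition_per_fold(
    auc_table: pd.DataFrame, min_auc: float = 0.7
) -> Counter:
    """Count, per definition, the folds for which it attains the maximal
    AUC; ties all count, folds whose best AUC is below ``min_auc`` are
    dropped."""
    counts: Counter = Counter()
    for _, grp in auc_table.groupby("fold_id"):
        best = grp["auc"].max()
        if best < min_auc:
            continue
        for label in grp.loc[grp["auc"] == best, "definition"]:
            counts[label] += 1
    return counts


def occupancy_auc_profile(summary: pd.DataFrame) -> pd.DataFrame:
    """(mean occupancy, fold-averaged AUC) per definition, sorted by
    occupancy."""
    out = summary[["definition", "mean_occupancy", "avg_auc"]].copy()
    return out.sort_values("mean_occupancy", kind="stable").reset_index(drop=True)


def best_tmscore_by_rank(
    scored_pairs: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Best TM-score among the top-k FCC-ranked pairs, k = 1..n ranks.

    Pairs with equal FCC collapse to one rank carrying their mean TM-score.
    """
    if len(scored_pairs) == 0:
        raise ValueError("no scored pairs")
    df = pd.DataFrame(scored_pairs, columns=["fcc", "tm"])
    ranked = (
        df.groupby("fcc", sort=True)["tm"].mean().sort_index(ascending=False)
    )
    return np.maximum.accumulate(ranked.to_numpy())
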