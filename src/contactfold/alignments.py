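"""Pairwise residue alignments: representation, readers, and sensitivity.

An alignment is a monotone one-to-one set of (query index, template index)
correspondences.  Two dialects are read: aligned FASTA (two gapped records
of equal length) and the three-line alignment block of TM-align's plain
text output.  ``alignment_sensitivity`` scores a test alignment against a
gold-standard one, optionally tolerating small template-index shifts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

_GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """Monotone one-to-one residue correspondences between two proteins."""

    query_id: str
    template_id: str
    pairs: tuple[tuple[int, int], ...]
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", tuple((int(q), int(t)) for q, t in self.pairs)
        )
        prev_q, prev_t = 0, 0
        for q, t in self.pairs:
            if q <= prev_q or t <= prev_t:
                raise ValueError(
                    f"alignment {self.query_id}/{self.template_id}: pairs must "
                    f"be strictly increasing in both coordinates, got ({q},{t}) "
                    f"after ({prev_q},{prev_t})"
                )
            prev_q, prev_t = q, t

    def __len__(self) -> int:
        return len(self.pairs)

    def query_to_template(self) -> dict[int, int]:
        return dict(self.pairs)

    def flipped(self) -> "PairwiseAlignment":
        """Same correspondences with query and template swapped."""
        return PairwiseAlignment(
            self.template_id,
            self.query_id,
            tuple((t, q) for q, t in self.pairs),
            source=self.source,
        )


def pairs_from_gapped(query_row: str, template_row: str) -> tuple[tuple[int, int], ...]:
    """Column-to-index mapping of two gapped rows of equal length."""
    if len(query_row) != len(template_row):
        raise ValueError(
            f"gapped rows differ in length ({len(query_row)} vs {len(template_row)})"
        )
    pairs = []
    q = t = 0
    for cq, ct in zip(query_row, template_row):
        if cq != _GAP:
            q += 1
        if ct != _GAP:
            t += 1
        if cq != _GAP and ct != _GAP:
            pairs.append((q, t))
    return tuple(pairs)


def read_alignment(
    path: str | Path,
    format: str = "afasta",
    query_id: str | None = None,
    template_id: str | None = None,
) -> PairwiseAlignment:
    """Read a pairwise alignment from ``afasta`` or ``tmalign`` text.

    The first record/row is the query.  Explicit ids override the ones
    found in the file (TM-align blocks carry no usable ids).
    """
    path = Path(path)
    if format in ("afasta", "aligned-fasta", "fasta"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 2:
            raise ValueError(
                f"{path}: aligned FASTA must contain exactly 2 records, "
                f"found {len(records)}"
            )
        qrec, trec = records
        pairs = pairs_from_gapped(str(qrec.seq), str(trec.seq))
        qid = query_id or qrec.id
        tid = template_id or trec.id
    elif format in ("tmalign", "tmalign-text"):
        qrow, trow = _tmalign_block(path)
        pairs = pairs_from_gapped(qrow, trow)
        qid = query_id or path.stem + "_q"
        tid = template_id or path.stem + "_t"
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not pairs:
        raise ValueError(f"{path}: alignment has zero aligned columns")
    return PairwiseAlignment(qid, tid, pairs, source=format)


_SEQ_ROW = re.compile(r"^[A-Za-z\-\.]+$")
_CONN_ROW = re.compile(r"^[:\. ]+$")


def _tmalign_block(path: Path) -> tuple[str, str]:
    """Locate the seq / connector / seq triple in TM-align plain output."""
    lines = Path(path).read_text().splitlines()
    for k in range(len(lines) - 2):
        top, mid, bot = lines[k], lines[k + 1], lines[k + 2]
        if (
            top
            and len(top) == len(bot)
            and _SEQ_ROW.match(top)
            and _SEQ_ROW.match(bot)
            and len(mid) <= len(top)
            and _CONN_ROW.match(mid or " ")
        ):
            return top.replace(".", _GAP), bot.replace(".", _GAP)
    raise ValueError(f"{path}: no TM-align alignment block found")


def write_alignment_fasta(
    a: PairwiseAlignment,
    path: str | Path,
    query_seq: str | None = None,
    template_seq: str | None = None,
    query_length: int | None = None,
    template_length: int | None = None,
) -> None:
    """Write an alignment as two gapped FASTA records.

    Residue letters default to 'X'; sequences or lengths, when given, fix
    the letters and the unaligned tails.
    """
    qlen = len(query_seq) if query_seq else (query_length or max((q for q, _ in a.pairs), default=0))
    tlen = len(template_seq) if template_seq else (template_length or max((t for _, t in a.pairs), default=0))
    qseq = query_seq or "X" * qlen
    tseq = template_seq or "X" * tlen
    qrow, trow = [], []
    q = t = 1
    for pq, pt in a.pairs:
        while q < pq:
            qrow.append(qseq[q - 1]); trow.append(_GAP); q += 1
        while t < pt:
            qrow.append(_GAP); trow.append(tseq[t - 1]); t += 1
        qrow.append(qseq[q - 1]); trow.append(tseq[t - 1]); q += 1; t += 1
    while q <= qlen:
        qrow.append(qseq[q - 1]); trow.append(_GAP); q += 1
    while t <= tlen:
        qrow.append(_GAP); trow.append(tseq[t - 1]); t += 1
    with open(path, "w") as fh:
        fh.write(f">{a.query_id}\n{''.join(qrow)}\n")
        fh.write(f">{a.template_id}\n{''.join(trow)}\n")


def alignment_sensitivity(
    test: PairwiseAlignment,
    gold: PairwiseAlignment,
    tolerance: int = 0,
    denominator: str = "gold",
    query_length: int | None = None,
) -> float:
    """Fraction of gold pairs recovered by ``test``.

    A gold pair (q, t) counts as recovered when ``test`` aligns q to some
    t' with ``|t' - t| <= tolerance``.  The default denominator is the
    number of gold pairs; ``denominator="query_length"`` divides by the
    query length instead (requires ``query_length``).
    """
    if (test.query_id, test.template_id) != (gold.query_id, gold.template_id):
        raise ValueError(
            f"alignment id mismatch: test {test.query_id}/{test.template_id} "
            f"vs gold {gold.query_id}/{gold.template_id}"
        )
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not gold.pairs:
        raise ValueError("gold alignment is empty")
    lookup = test.query_to_template()
    hits = sum(
        1
        for q, t in gold.pairs
        if q in lookup and abs(lookup[q] - t) <= tolerance
    )
    if denominator == "gold":
        denom = len(gold.pairs)
    elif denominator == "query_length":
        if not query_length:
            raise ValueError("query_length required for that denominator")
        denom = query_length
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return hits / denom
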