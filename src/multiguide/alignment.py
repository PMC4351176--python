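"""Multiple sequence alignment and gap/mismatch consensus.

The common-target search operates on a consensus string over
{A,C,G,T,-,X}: a column shows its base when every row agrees, '-' when
any row has a gap, and 'X' when all rows hold bases but disagree
(strict unanimity — there is deliberately no majority rule, since a
single disagreeing sequence already breaks a guide:target match).

Alignments can be ingested from aligned FASTA / Clustal files (e.g.
ClustalW2 output), or produced internally: optimal pairwise global
alignment under affine gap scoring (match +2, mismatch −1, gap open −5,
gap extend −1), extended to more sequences by center-star progressive
merging with the "once a gap, always a gap" rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import Align, AlignIO

from .search import SequenceRecord

__all__ = [
    "AlignScores",
    "MultiAlignment",
    "Consensus",
    "pairwise_align",
    "progressive_align",
    "read_alignment",
    "write_alignment_fasta",
    "compute_consensus",
    "column_to_sequence_coord",
]

GAP = "-"
MISMATCH = "X"

_FORMATS = {"aligned-FASTA": "fasta", "fasta": "fasta", "Clustal": "clustal", "clustal": "clustal"}


@dataclass(frozen=True)
class AlignScores:
    """Affine scoring defaults: match +2, mismatch −2, gap −5 open −0.2 extend.

    Gap extension is deliberately cheap relative to mismatches so that
    whole unshared blocks (private exons of isoforms, indels between
    paralogs) are spanned by single long gaps, while exactly shared
    blocks align end-to-end.  Heavier extension penalties make the
    optimal global alignment of block-structured sequences a mosaic
    that chases chance matches inside unrelated regions (~0.6 apparent
    identity between random blocks), which destroys the unanimity
    consensus the common-site search runs on.  Isolated substitutions
    (runs up to ~5) still align gaplessly under these values.
    """

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -5.0  # score of the first gapped position
    gap_extend: float = -0.2  # each additional gapped position


class MultiAlignment:
    """Ordered gapped rows of equal length with column->coordinate maps."""

    def __init__(self, rows: list[tuple[str, str]], score: Optional[float] = None):
        if not rows:
            raise ValueError("alignment has no rows")
        ids = [rid for rid, _ in rows]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate row ids in alignment: {ids}")
        lengths = {len(g) for _, g in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        (self.length,) = lengths
        if self.length == 0:
            raise ValueError("alignment has zero columns")
        self.rows = [(rid, gapped.upper()) for rid, gapped in rows]
        self.score = score
        # per-row column -> ungapped coordinate (-1 at gap columns)
        self._maps: dict[str, np.ndarray] = {}
        for rid, gapped in self.rows:
            arr = np.full(self.length, -1, dtype=np.int64)
            pos = 0
            for c, ch in enumerate(gapped):
                if ch != GAP:
                    arr[c] = pos
                    pos += 1
            self._maps[rid] = arr

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def gapped(self, row_id: str) -> str:
        for rid, g in self.rows:
            if rid == row_id:
                return g
        raise KeyError(f"unknown row id {row_id!r}")

    def sequences(self) -> dict[str, str]:
        """Ungapped sequence per row (degapping the alignment)."""
        return {rid: g.replace(GAP, "") for rid, g in self.rows}

    def column_to_sequence_coord(self, row_id: str, column: int) -> Optional[int]:
        """0-based ungapped coordinate of the row residue at ``column``.

        Returns ``None`` when the row has a gap there.
        """
        if row_id not in self._maps:
            raise KeyError(f"unknown row id {row_id!r}")
        if not 0 <= column < self.length:
            raise IndexError(f"column {column} outside alignment of length {self.length}")
        v = int(self._maps[row_id][column])
        return None if v == -1 else v


def column_to_sequence_coord(aln: MultiAlignment, row_id: str, column: int) -> Optional[int]:
    return aln.column_to_sequence_coord(row_id, column)


@dataclass(frozen=True)
class Consensus:
    """Per-column summary over {A,C,G,T,-,X} of a MultiAlignment."""

    symbols: str


def compute_consensus(aln: MultiAlignment) -> Consensus:
    """Strict consensus: base on unanimity, '-' on any gap, 'X' otherwise."""
    out = []
    gapped = [g for _, g in aln.rows]
    for col in zip(*gapped):
        if GAP in col:
            out.append(GAP)
        elif len(set(col)) == 1:
            out.append(col[0])
        else:
            out.append(MISMATCH)
    return Consensus("".join(out))


def _aligner(scores: AlignScores) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scores.match
    al.mismatch_score = scores.mismatch
    al.open_gap_score = scores.gap_open
    al.extend_gap_score = scores.gap_extend
    return al


def pairwise_align(
    a: str,
    b: str,
    scores: Optional[AlignScores] = None,
    ids: tuple[str, str] = ("seq1", "seq2"),
) -> MultiAlignment:
    """Optimal global alignment of two sequences under affine gap scoring."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    scores = scores or AlignScores()
    result = _aligner(scores).align(a.upper(), b.upper())
    best = result[0]  # deterministic first optimal alignment
    return MultiAlignment(
        [(ids[0], str(best[0])), (ids[1], str(best[1]))], score=result.score
    )


def _merge_into_star(
    master_center: str,
    other_rows: list[tuple[str, str]],
    pair_center: str,
    pair_other: str,
    other_id: str,
) -> tuple[str, list[tuple[str, str]]]:
    """Merge one (center, other) pairwise alignment into the growing MSA.

    Both ``master_center`` and ``pair_center`` degap to the same center
    sequence; gaps present in either view are kept ("once a gap, always
    a gap").
    """
    new_center = []
    new_rows = {rid: [] for rid, _ in other_rows}
    new_other = []
    i = j = 0
    li, lj = len(master_center), len(pair_center)
    while i < li or j < lj:
        m_gap = i < li and master_center[i] == GAP
        p_gap = j < lj and pair_center[j] == GAP
        if i < li and j < lj and not m_gap and not p_gap:
            new_center.append(master_center[i])
            for rid, g in other_rows:
                new_rows[rid].append(g[i])
            new_other.append(pair_other[j])
            i += 1
            j += 1
        elif m_gap:
            new_center.append(GAP)
            for rid, g in other_rows:
                new_rows[rid].append(g[i])
            new_other.append(GAP)
            i += 1
        elif p_gap:
            new_center.append(GAP)
            for rid, _ in other_rows:
                new_rows[rid].append(GAP)
            new_other.append(pair_other[j])
            j += 1
        else:  # pragma: no cover - exhausted one side without gaps (impossible)
            raise AssertionError("center rows out of sync during star merge")
    merged = [(rid, "".join(new_rows[rid])) for rid, _ in other_rows]
    merged.append((other_id, "".join(new_other)))
    return "".join(new_center), merged


def progressive_align(
    records: list[SequenceRecord], scores: Optional[AlignScores] = None
) -> MultiAlignment:
    """Center-star progressive alignment of two or more sequences.

    The center is the record maximizing summed pairwise identity
    (matching columns / alignment length) against all others; the rest
    are merged one at a time through their pairwise alignment to the
    center.  Output rows keep the input order.
    """
    if len(records) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids: {ids}")
    scores = scores or AlignScores()
    if len(records) == 2:
        aln = pairwise_align(
            records[0].residues, records[1].residues, scores, ids=(ids[0], ids[1])
        )
        return aln

    n = len(records)
    pair: dict[tuple[int, int], MultiAlignment] = {}
    identity = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(
                records[i].residues, records[j].residues, scores, ids=("a", "b")
            )
            ga, gb = aln.rows[0][1], aln.rows[1][1]
            ident = sum(x == y and x != GAP for x, y in zip(ga, gb)) / aln.length
            identity[i, j] = identity[j, i] = ident
            pair[(i, j)] = aln
    center = int(np.argmax(identity.sum(axis=1)))

    master_center = records[center].residues
    rows: list[tuple[str, str]] = []
    for k in range(n):
        if k == center:
            continue
        key = (center, k) if center < k else (k, center)
        aln = pair[key]
        pc = aln.rows[0][1] if key[0] == center else aln.rows[1][1]
        po = aln.rows[1][1] if key[0] == center else aln.rows[0][1]
        master_center, rows = _merge_into_star(master_center, rows, pc, po, ids[k])
    rows.append((ids[center], master_center))
    by_id = dict(rows)
    return MultiAlignment([(rid, by_id[rid]) for rid in ids])


def read_alignment(path: str | Path, format: str = "aligned-FASTA") -> MultiAlignment:
    """Read an alignment from aligned FASTA or Clustal format."""
    if format not in _FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}; use aligned-FASTA or Clustal")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), _FORMATS[format])
    except ValueError as exc:
        raise ValueError(f"cannot read alignment {path}: {exc}") from exc
    return MultiAlignment([(rec.id, str(rec.seq)) for rec in msa])


def write_alignment_fasta(aln: MultiAlignment, path: str | Path):
    with open(path, "w") as fh:
        for rid, gapped in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(gapped), 70):
                fh.write(gapped[i : i + 70] + "\n")
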