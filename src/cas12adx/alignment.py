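"""Pairwise global alignment and center-star multiple alignment.

Barcode loci are short (~300-500 nt) and panels small (a handful of species),
so a textbook Needleman-Wunsch with linear gap penalties plus a center-star
merge ("once a gap, always a gap") is fast, dependency-free and fully
deterministic.  Users with a preferred aligner can supply aligned FASTA and
bypass this module entirely.

Coordinates are 0-based half-open internally; human-readable reports render
1-based fully-closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cas12adx.sequence_core import (
    GAP,
    IUPAC_SETS,
    BarcodePanel,
    SeqRecord,
    SequenceValidationError,
    _clean,
)

# 4-bit base masks: two IUPAC characters match iff their masks intersect
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        bytes(_MASK[c] for c in seq), dtype=np.uint8).copy()

__all__ = ["AlnParams", "MsaResult", "nw_align", "star_msa", "project"]


@dataclass(frozen=True)
class AlnParams:
    """Scoring for global alignment: match reward, mismatch and linear gap
    penalties (both negative)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap >= 0:
            raise ValueError("gap penalty must be negative")


def nw_align(a: str, b: str, p: AlnParams = AlnParams()) -> tuple[float, str, str]:
    """Optimal global alignment of two ungapped sequences.

    Returns ``(score, gapped_a, gapped_b)``.  Ties in the dynamic program are
    broken deterministically: diagonal (substitution) over up (gap in ``b``)
    over left (gap in ``a``).  Empty sequences align against all-gaps.
    """
    a = _clean(a, where="nw_align a") if a else ""
    b = _clean(b, where="nw_align b") if b else ""
    if GAP in a or GAP in b:
        raise SequenceValidationError("nw_align inputs must be ungapped")
    n, m = len(a), len(b)
    DIAG, UP, LEFT = 0, 1, 2
    # score[i, j]: best score aligning a[:i] with b[:j]; ptr encodes the move.
    # Filled along anti-diagonals so each wavefront is a vector operation.
    sub = np.where(
        (_encode(a)[:, None] & _encode(b)[None, :]) > 0, p.match, p.mismatch,
    ) if n and m else np.zeros((n, m))
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    score[1:, 0] = np.arange(1, n + 1) * p.gap
    score[0, 1:] = np.arange(1, m + 1) * p.gap
    ptr[1:, 0] = UP
    ptr[0, 1:] = LEFT
    for d in range(2, n + m + 1):
        i = np.arange(max(1, d - m), min(n, d - 1) + 1)
        if i.size == 0:
            continue
        j = d - i
        best = score[i - 1, j - 1] + sub[i - 1, j - 1]
        move = np.full(i.size, DIAG, dtype=np.int8)
        up = score[i - 1, j] + p.gap
        mask = up > best  # strict: ties keep the higher-priority move
        best[mask] = up[mask]
        move[mask] = UP
        left = score[i, j - 1] + p.gap
        mask = left > best
        best[mask] = left[mask]
        move[mask] = LEFT
        score[i, j] = best
        ptr[i, j] = move
    ga: list[str] = []
    gb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == DIAG and i > 0 and j > 0:
            ga.append(a[i - 1]); gb.append(b[j - 1]); i -= 1; j -= 1
        elif move == UP and i > 0:
            ga.append(a[i - 1]); gb.append(GAP); i -= 1
        else:
            ga.append(GAP); gb.append(b[j - 1]); j -= 1
    return float(score[n, m]), "".join(reversed(ga)), "".join(reversed(gb))


@dataclass
class MsaResult:
    """A multiple alignment with bidirectional sequence<->column coordinate maps.

    ``rows`` holds ``(record_id, species, gapped_sequence)`` in input order.
    ``col_of[row_id][residue_index]`` gives the alignment column of a residue;
    ``res_of[row_id]`` is the partial inverse (columns holding a gap are
    absent from it).
    """

    rows: list[tuple[str, str, str]]
    ncol: int = field(init=False)
    col_of: dict[str, list[int]] = field(init=False)
    res_of: dict[str, dict[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        lengths = {len(g) for _, _, g in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.ncol = lengths.pop()
        self.col_of, self.res_of = {}, {}
        for rid, _, gapped in self.rows:
            cols: list[int] = []
            inv: dict[int, int] = {}
            for col, ch in enumerate(gapped):
                if ch != GAP:
                    inv[col] = len(cols)
                    cols.append(col)
            self.col_of[rid] = cols
            self.res_of[rid] = inv

    def row(self, rid: str) -> tuple[str, str, str]:
        for r in self.rows:
            if r[0] == rid:
                return r
        raise KeyError(rid)

    def rows_of_species(self, species: str) -> list[tuple[str, str, str]]:
        return [r for r in self.rows if r[1] == species]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, sp, _ in self.rows:
            seen.setdefault(sp)
        return list(seen)


def project(msa: MsaResult, row_id: str, pos: int) -> int:
    """Alignment column holding residue ``pos`` (0-based, ungapped) of a row."""
    cols = msa.col_of[row_id]
    if not 0 <= pos < len(cols):
        raise IndexError(
            f"residue {pos} out of range for row {row_id!r} (length {len(cols)})"
        )
    return cols[pos]


def star_msa(panel: BarcodePanel | list[SeqRecord],
             p: AlnParams = AlnParams()) -> MsaResult:
    """Center-star multiple alignment.

    The center is the record maximizing the sum of pairwise alignment scores
    against all others (ties go to the earliest record in input order); every
    other record is aligned to the center pairwise and merged under "once a
    gap, always a gap".  Row order follows the input.  Substitution-only
    panels (no indels) come out gap-free.
    """
    records = panel.records if isinstance(panel, BarcodePanel) else list(panel)
    if len(records) == 1:
        warnings.warn("single-record panel: trivial one-row MSA")
        r = records[0]
        return MsaResult(rows=[(r.id, r.species, r.ungapped)])
    seqs = [r.ungapped for r in records]
    k = len(records)
    pair: dict[tuple[int, int], tuple[float, str, str]] = {}
    sums = [0.0] * k
    for i in range(k):
        for j in range(i + 1, k):
            res = nw_align(seqs[i], seqs[j], p)
            pair[(i, j)] = res
            sums[i] += res[0]
            sums[j] += res[0]
    center = max(range(k), key=lambda i: (sums[i], -i))
    lc = len(seqs[center])

    def center_alignment(other: int) -> tuple[str, str]:
        """Pairwise alignment oriented as (center row, other row)."""
        if other > center:
            _, gc, go = pair[(center, other)]
        else:
            # nw_align is not argument-symmetric in gap placement; realign
            # with the center first to keep merge orientation consistent.
            _, gc, go = nw_align(seqs[center], seqs[other], p)
        return gc, go

    # inserts[i] = characters of `other` falling between center residues
    # i-1 and i (i == lc means after the last residue)
    profiles: dict[int, tuple[list[str], list[str]]] = {}
    master_ins = [0] * (lc + 1)
    for other in range(k):
        if other == center:
            continue
        gc, go = center_alignment(other)
        inserts: list[str] = ["" for _ in range(lc + 1)]
        aligned: list[str] = []
        ci = 0
        for cc, oc in zip(gc, go):
            if cc == GAP:
                inserts[ci] += oc
            else:
                aligned.append(oc)
                ci += 1
        profiles[other] = (inserts, aligned)
        for i in range(lc + 1):
            master_ins[i] = max(master_ins[i], len(inserts[i]))

    def build_center_row() -> str:
        out = []
        for i in range(lc):
            out.append(GAP * master_ins[i])
            out.append(seqs[center][i])
        out.append(GAP * master_ins[lc])
        return "".join(out)

    def build_other_row(other: int) -> str:
        inserts, aligned = profiles[other]
        out = []
        for i in range(lc):
            ins = inserts[i]
            out.append(ins + GAP * (master_ins[i] - len(ins)))
            out.append(aligned[i])
        ins = inserts[lc]
        out.append(ins + GAP * (master_ins[lc] - len(ins)))
        return "".join(out)

    rows: list[tuple[str, str, str]] = []
    for idx, r in enumerate(records):
        gapped = build_center_row() if idx == center else build_other_row(idx)
        rows.append((r.id, r.species, gapped))
    return MsaResult(rows=rows)
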