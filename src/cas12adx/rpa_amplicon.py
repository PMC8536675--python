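"""Primer location and in-silico RPA amplicon prediction.

Recombinase polymerase amplification (RPA) runs isothermally (~37 C) and
tolerates a few primer-template mismatches, so primers are located by a
Hamming sliding window with a configurable mismatch allowance (default 2)
under IUPAC set-intersection semantics — no indels, matching how a primer
anneals.  An amplicon is any forward span paired with a downstream
reverse-primer span; its length includes both primer footprints (gel
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

from cas12adx.guide_design import DesignParams, GuideCandidate, spacer_window
from cas12adx.sequence_core import (
    GAP,
    SeqRecord,
    SequenceValidationError,
    iupac_match,
    revcomp,
    _clean,
)

__all__ = ["PrimerSet", "AmpliconHit", "TRNL_RPAF", "TRNL_RPAR",
           "locate_primer", "predict_amplicon"]

#: Universal chloroplast trnL RPA primer pair for Phyllanthus barcoding
#: (forward 35 nt, reverse 34 nt).
TRNL_RPAF = "TGTTGTCAATATTGACATGTAGAATGGGACTCTAT"
TRNL_RPAR = "GCAGAGACTCAATGGAAGCTGTTCTAACAAACGG"


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair with a per-primer mismatch allowance."""

    fwd: str = TRNL_RPAF
    rev: str = TRNL_RPAR
    max_mm: int = 2

    def __post_init__(self) -> None:
        for name in ("fwd", "rev"):
            s = _clean(getattr(self, name), where=f"{name} primer")
            if GAP in s:
                raise SequenceValidationError(f"{name} primer may not contain gaps")
            object.__setattr__(self, name, s)
        if self.max_mm < 0:
            raise ValueError("max_mm must be >= 0")


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted amplicon on one sequence record.

    Spans are 0-based half-open on the plus strand; ``length`` includes both
    primer footprints (``rev_end - fwd_start``).  ``contains_guide`` is set
    only when a guide was supplied and its whole PAM+spacer window lies
    strictly between the primer footprints.
    """

    seq_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    length: int
    contains_guide: bool | None = None

    def __post_init__(self) -> None:
        if self.fwd_end > self.rev_start:
            raise ValueError("forward primer must end before the reverse site")
        if self.length != self.rev_end - self.fwd_start:
            raise ValueError("length must equal rev_end - fwd_start")


def locate_primer(seq: str, primer: str, orientation: str = "fwd",
                  max_mm: int = 2) -> list[tuple[int, int]]:
    """All spans where a primer binds with at most ``max_mm`` mismatches.

    Forward primers are matched as-is on the plus strand; reverse primers as
    their reverse complement (the plus-strand footprint of a primer annealing
    to the minus strand).  Returns 0-based half-open spans sorted by start;
    a primer longer than the sequence yields an empty list.
    """
    seq = _clean(seq, where="locate_primer")
    if GAP in seq:
        raise SequenceValidationError("locate_primer requires an ungapped sequence")
    if orientation not in ("fwd", "rev"):
        raise ValueError("orientation must be 'fwd' or 'rev'")
    query = primer.upper() if orientation == "fwd" else revcomp(primer)
    k = len(query)
    if k > len(seq):
        return []
    spans = []
    for i in range(len(seq) - k + 1):
        mm = 0
        for a, b in zip(seq[i:i + k], query):
            if not iupac_match(a, b):
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            spans.append((i, i + k))
    return spans


def predict_amplicon(seq: SeqRecord | str, primers: PrimerSet,
                     guide: GuideCandidate | None = None,
                     design_params: DesignParams | None = None,
                     max_amplicon: int = 1500) -> list[AmpliconHit]:
    """Predicted amplicons: every forward x reverse span pair in order.

    Pairs where the forward footprint ends after the reverse one starts, or
    whose total length exceeds ``max_amplicon``, are dropped.  When ``guide``
    is given, its PAM+spacer window (located by ``pam_start``/strand on this
    sequence's coordinates) must lie strictly inside the inter-primer region
    for ``contains_guide`` to be true — a guide overlapping a primer
    footprint does not count as contained.
    """
    if isinstance(seq, SeqRecord):
        sid, s = seq.id, seq.ungapped
    else:
        sid, s = "seq", _clean(seq, where="predict_amplicon").replace(GAP, "")
    fwd_spans = locate_primer(s, primers.fwd, "fwd", primers.max_mm)
    rev_spans = locate_primer(s, primers.rev, "rev", primers.max_mm)
    gspan: tuple[int, int] | None = None
    if guide is not None:
        p = design_params or DesignParams()
        sw = spacer_window(guide.strand, guide.pam_start, p)
        positions = list(range(guide.pam_start, guide.pam_start + p.pam_len))
        positions += list(sw)
        gspan = (min(positions), max(positions) + 1)
    hits: list[AmpliconHit] = []
    for fs, fe in fwd_spans:
        for rs, re_ in rev_spans:
            if fe > rs or re_ - fs > max_amplicon:
                continue
            contains = None
            if gspan is not None:
                contains = fe <= gspan[0] and gspan[1] <= rs
            hits.append(AmpliconHit(
                seq_id=sid, fwd_start=fs, fwd_end=fe,
                rev_start=rs, rev_end=re_, length=re_ - fs,
                contains_guide=contains,
            ))
    return hits
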