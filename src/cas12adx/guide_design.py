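"""PAM scanning, spacer extraction, and cross-species candidate assessment.

A Cas12a guide candidate is a PAM site (default pattern ``TTTV``; V = A, C or
G) on the target species together with the spacer window lying immediately 3'
of it on the same strand.  Spacer positions are numbered from the
PAM-proximal base, so spacer position 1 is seed position 1; the seed region
is positions 1-5 by default, where Cas12a tolerates mismatches poorly.

Assessment of a candidate against another species reads that species'
characters at the candidate's alignment columns and classifies the PAM
(canonical / variant / absent-on-gap) and counts seed vs distal spacer
mismatches under IUPAC set-intersection semantics; an alignment gap inside
the spacer counts as a mismatch at that position and is also tallied
separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from cas12adx.alignment import MsaResult, project
from cas12adx.sequence_core import (
    GAP,
    SequenceValidationError,
    iupac_match,
    iupac_union,
    revcomp,
    _clean,
)

__all__ = [
    "DesignParams", "GuideCandidate", "SpeciesAssessment",
    "T7_PROMOTER", "LB_DIRECT_REPEAT_DNA",
    "scan_pams", "enumerate_candidates", "assess_candidate", "build_construct",
]

#: Minimal T7 promoter used for in-vitro transcription templates (editable).
T7_PROMOTER = "TAATACGACTCACTATAG"
#: LbCas12a crRNA direct-repeat scaffold, DNA rendering (editable).
LB_DIRECT_REPEAT_DNA = "TAATTTCTACTAAGTGTAGAT"


@dataclass(frozen=True)
class DesignParams:
    """Guide-design settings.

    ``pam_pattern`` is an IUPAC string matched by set intersection (default
    ``TTTV``).  ``seed_window`` is an inclusive 1-based range of spacer
    positions counted from the PAM-proximal base.
    """

    pam_pattern: str = "TTTV"
    spacer_len: int = 21
    seed_window: tuple[int, int] = (1, 5)
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "pam_pattern",
                           _clean(self.pam_pattern, where="pam_pattern"))
        if GAP in self.pam_pattern:
            raise ValueError("pam_pattern may not contain gaps")
        if not 18 <= self.spacer_len <= 24:
            raise ValueError("spacer_len must be in 18..24")
        lo, hi = self.seed_window
        if not 1 <= lo <= hi:
            raise ValueError("seed_window must be an inclusive 1-based range")
        if self.spacer_len < hi:
            raise ValueError("spacer_len must cover the seed window")

    @property
    def pam_len(self) -> int:
        return len(self.pam_pattern)

    def is_seed(self, spacer_pos1: int) -> bool:
        """Is 1-based spacer position inside the seed window?"""
        return self.seed_window[0] <= spacer_pos1 <= self.seed_window[1]


@dataclass(frozen=True)
class GuideCandidate:
    """A PAM site plus spacer window on the target species.

    ``pam_start`` is the 0-based position of the PAM's first base in the
    *ungapped* target sequence, in plus-strand coordinates for both strands.
    ``spacer_seq`` is stored PAM-proximal base first (spacer position 1
    first), i.e. 5'->3' along the candidate strand.  ``pam_cols`` /
    ``spacer_cols`` are the alignment columns of those bases in the same
    order as the sequences.
    """

    target_species: str
    strand: str  # '+' or '-'
    pam_start: int
    pam_seq: str
    pam_cols: tuple[int, ...]
    spacer_seq: str
    spacer_cols: tuple[int, ...]
    guide_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.pam_seq) != len(self.pam_cols):
            raise ValueError("pam_seq / pam_cols length mismatch")
        if len(self.spacer_seq) != len(self.spacer_cols):
            raise ValueError("spacer_seq / spacer_cols length mismatch")

    @property
    def window_cols(self) -> tuple[int, ...]:
        return self.pam_cols + self.spacer_cols


@dataclass(frozen=True)
class SpeciesAssessment:
    """Per-species comparison of one candidate.

    ``pam_status``: ``canonical`` (matches the PAM pattern), ``variant``
    (ungapped but pattern-breaking), or ``absent`` (any gap in the PAM
    window).  ``gap_positions`` counts alignment gaps anywhere in the
    PAM+spacer window; spacer gaps are additionally counted as mismatches
    at their seed/distal position.
    """

    species: str
    pam_status: str
    pam_obs: str
    seed_mismatches: int
    distal_mismatches: int
    gap_positions: int
    spacer_identical: bool


def scan_pams(seq: str, p: DesignParams = DesignParams()) -> list[tuple[str, int, str]]:
    """All PAM sites in an ungapped sequence with room for a full spacer.

    Returns ``(strand, start, pam_sequence)`` triples; ``start`` is the
    0-based plus-strand position of the PAM window's leftmost base on both
    strands, and ``pam_sequence`` reads 5'->3' along the hit strand.  Plus
    hits need ``spacer_len`` bases 3' (rightward) of the PAM; minus hits need
    them leftward.  Sorted by (start, strand).
    """
    seq = _clean(seq, where="scan_pams")
    if GAP in seq:
        raise SequenceValidationError("scan_pams requires an ungapped sequence")
    k, L = p.pam_len, p.spacer_len
    if len(seq) < k + L:
        warnings.warn(
            f"sequence length {len(seq)} shorter than PAM+spacer ({k + L}): no scan"
        )
        return []
    hits: list[tuple[str, int, str]] = []

    def matches(window: str) -> bool:
        return all(iupac_match(c, q) for c, q in zip(window, p.pam_pattern))

    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if i + k + L <= len(seq) and matches(window):
            hits.append(("+", i, window))
        if p.scan_both_strands and i - L >= 0:
            rc = revcomp(window)
            if matches(rc):
                hits.append(("-", i, rc))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def spacer_window(strand: str, pam_start: int, p: DesignParams) -> range:
    """Plus-strand positions of the spacer for a PAM hit, left to right."""
    if strand == "+":
        return range(pam_start + p.pam_len, pam_start + p.pam_len + p.spacer_len)
    return range(pam_start - p.spacer_len, pam_start)


def enumerate_candidates(msa: MsaResult, p: DesignParams,
                         target: str) -> list[GuideCandidate]:
    """Candidate guides for the target species, one per usable PAM hit.

    The first target row is scanned; a PAM window interrupted by an alignment
    gap in that row is skipped.  When the target species has several rows,
    candidates whose PAM+spacer characters differ between target rows (or hit
    a gap in any of them) are disqualified.
    """
    target_rows = msa.rows_of_species(target)
    if not target_rows:
        raise KeyError(f"species {target!r} not in alignment")
    rid, _, gapped = target_rows[0]
    ungapped = gapped.replace(GAP, "")
    out: list[GuideCandidate] = []
    for n, (strand, start, pam_seq) in enumerate(scan_pams(ungapped, p)):
        pam_pos = range(start, start + p.pam_len)
        sp_pos = spacer_window(strand, start, p)
        pam_cols = tuple(project(msa, rid, i) for i in pam_pos)
        sp_cols = tuple(project(msa, rid, i) for i in sp_pos)
        if pam_cols[-1] - pam_cols[0] != p.pam_len - 1:
            # alignment gap interrupts the PAM window on the target row:
            # cross-species projection of the motif is unreliable
            continue
        spacer_plus = ungapped[sp_pos.start:sp_pos.stop]
        if strand == "-":
            # report PAM-proximal-first: reverse both sequence and columns
            spacer_seq = revcomp(spacer_plus)
            sp_cols = tuple(reversed(sp_cols))
            pam_cols = tuple(reversed(pam_cols))
        else:
            spacer_seq = spacer_plus
        cand = GuideCandidate(
            target_species=target, strand=strand, pam_start=start,
            pam_seq=pam_seq, pam_cols=pam_cols,
            spacer_seq=spacer_seq, spacer_cols=sp_cols,
            guide_id=f"{target}_g{n + 1}{strand}{start}",
        )
        if _consistent_across_rows(cand, msa, target_rows[1:]):
            out.append(cand)
    return out


def _consistent_across_rows(c: GuideCandidate, msa: MsaResult,
                            other_rows: list[tuple[str, str, str]]) -> bool:
    for _, _, gapped in other_rows:
        for col, ref in zip(c.window_cols, c.pam_seq + c.spacer_seq):
            obs = gapped[col]
            if c.strand == "-":
                obs = revcomp(obs)
            if obs == GAP or not iupac_match(obs, ref):
                return False
    return True


def _species_consensus(msa: MsaResult, species: str, cols: tuple[int, ...]) -> str:
    """Column-wise IUPAC consensus of a species' rows at given columns."""
    rows = msa.rows_of_species(species)
    return "".join(
        iupac_union(gapped[col] for _, _, gapped in rows) for col in cols
    )


def assess_candidate(c: GuideCandidate, msa: MsaResult,
                     p: DesignParams = DesignParams()) -> list[SpeciesAssessment]:
    """Assess a candidate against every non-target species in the alignment.

    Each species' rows are collapsed to a column-wise IUPAC consensus first,
    then read along the candidate strand and compared to the candidate's PAM
    pattern and spacer.
    """
    out = []
    for sp in msa.species:
        if sp == c.target_species:
            continue
        out.append(assess_species(c, msa, sp, p))
    if not out:
        raise ValueError("alignment holds no non-target species")
    return out


def assess_species(c: GuideCandidate, msa: MsaResult, species: str,
                   p: DesignParams = DesignParams()) -> SpeciesAssessment:
    """Assessment of one species (see :func:`assess_candidate`)."""
    if not msa.rows_of_species(species):
        raise KeyError(f"species {species!r} not in alignment")
    pam_obs = _species_consensus(msa, species, c.pam_cols)
    sp_obs = _species_consensus(msa, species, c.spacer_cols)
    if c.strand == "-":
        # columns are already stored PAM-proximal-first (reversed); complement
        # each base to read along the candidate strand
        pam_obs = "".join(revcomp(ch) for ch in pam_obs)
        sp_obs = "".join(revcomp(ch) for ch in sp_obs)
    if GAP in pam_obs:
        pam_status = "absent"
    elif all(iupac_match(o, q) for o, q in zip(pam_obs, p.pam_pattern)):
        pam_status = "canonical"
    else:
        pam_status = "variant"
    seed_mm = distal_mm = spacer_gaps = 0
    for idx, (obs, ref) in enumerate(zip(sp_obs, c.spacer_seq)):
        pos1 = idx + 1  # 1-based, PAM-proximal first
        if obs == GAP:
            spacer_gaps += 1
            mismatch = True
        else:
            mismatch = not iupac_match(obs, ref)
        if mismatch:
            if p.is_seed(pos1):
                seed_mm += 1
            else:
                distal_mm += 1
    gap_positions = pam_obs.count(GAP) + spacer_gaps
    return SpeciesAssessment(
        species=species,
        pam_status=pam_status,
        pam_obs=pam_obs,
        seed_mismatches=seed_mm,
        distal_mismatches=distal_mm,
        gap_positions=gap_positions,
        spacer_identical=(seed_mm == 0 and distal_mm == 0 and spacer_gaps == 0),
    )


def build_construct(c: GuideCandidate,
                    t7: str = T7_PROMOTER,
                    repeat: str = LB_DIRECT_REPEAT_DNA) -> tuple[str, str, str]:
    """In-vitro-transcription construct for a candidate.

    Returns ``(crRNA, dsDNA_top, dsDNA_bottom)``: the crRNA is the
    direct-repeat scaffold plus spacer rendered as RNA (T->U); the dsDNA
    template top strand is T7 promoter + scaffold + spacer in DNA, the bottom
    strand its reverse complement.
    """
    if not repeat:
        raise ValueError("empty scaffold/direct-repeat sequence")
    if not t7:
        raise ValueError("empty T7 promoter sequence")
    repeat_dna = _clean(repeat, where="repeat")
    t7_dna = _clean(t7, where="t7")
    crrna = (repeat_dna + c.spacer_seq).replace("T", "U")
    top = t7_dna + repeat_dna + c.spacer_seq
    return crrna, top, revcomp(top)
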