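"""Qualitative Cas12a signal prediction and candidate ranking.

Cas12a's collateral (trans) cleavage fires only when the guide binds its
double-stranded DNA target, which in turn needs a recognizable PAM and a
well-matched spacer, especially in the PAM-proximal seed region.  This module
turns a per-species assessment into a positive/negative fluorescence call
through a small additive penalty model, and ranks guide candidates by the
fraction of off-target species they predict negative.

No quantitative activity model is published for this assay, so the penalties
are a calibration exposed as two named presets:

``strict``
    any seed mismatch kills the signal (seed penalty 3 >= threshold 3) —
    the conservative reading under which the seed is mismatch-intolerant.
``permissive``
    a single seed mismatch with a canonical PAM survives (seed penalty 2 <
    threshold 4) — matching the empirical observation that one seed-position
    variant can still give a positive signal.

A perfectly identical spacer is called positive regardless of PAM status by
default (``identity_override``), reflecting the observed cross-reactivity of
an identical-spacer/variant-PAM species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from cas12adx.guide_design import (
    DesignParams,
    GuideCandidate,
    SpeciesAssessment,
    assess_candidate,
)
from cas12adx.alignment import MsaResult

__all__ = [
    "ActivityRules", "SignalPrediction", "RankScore", "RankedCandidate",
    "STRICT", "PERMISSIVE", "PRESETS",
    "predict_signal", "discrimination_score", "rank_candidates",
]


@dataclass(frozen=True)
class ActivityRules:
    """Penalty model turning an assessment into a positive/negative call.

    The call is negative when the PAM is absent (hard rule, unless the spacer
    is identical and ``identity_override`` is on) or when the summed penalty
    reaches ``threshold``.
    """

    seed_penalty: float = 3.0
    distal_penalty: float = 1.0
    pam_variant_penalty: float = 2.0
    pam_absent: bool = True
    identity_override: bool = True
    threshold: float = 3.0
    name: str = "strict"

    def __post_init__(self) -> None:
        if min(self.seed_penalty, self.distal_penalty, self.pam_variant_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


STRICT = ActivityRules()
PERMISSIVE = replace(STRICT, seed_penalty=2.0, threshold=4.0, name="permissive")
PRESETS: dict[str, ActivityRules] = {"strict": STRICT, "permissive": PERMISSIVE}


@dataclass(frozen=True)
class SignalPrediction:
    """Predicted fluorescence outcome for one species under one rule set."""

    species: str
    call: str  # 'positive' | 'negative'
    score: float
    rationale: tuple[str, ...]

    @property
    def positive(self) -> bool:
        return self.call == "positive"


def predict_signal(a: SpeciesAssessment, r: ActivityRules = STRICT) -> SignalPrediction:
    """Evaluate the activity rules on one species assessment.

    Rule order: (1) identical spacer forces positive when
    ``identity_override`` is set; (2) absent PAM forces negative when
    ``pam_absent`` is set; (3) otherwise the additive penalty decides —
    positive iff score < threshold.
    """
    rationale: list[str] = []
    score = (
        r.seed_penalty * a.seed_mismatches
        + r.distal_penalty * a.distal_mismatches
        + (r.pam_variant_penalty if a.pam_status == "variant" else 0.0)
    )
    if a.spacer_identical and r.identity_override:
        rationale.append("identity_override")
        return SignalPrediction(a.species, "positive", score, tuple(rationale))
    if a.pam_status == "absent" and r.pam_absent:
        rationale.append("pam_absent")
        return SignalPrediction(a.species, "negative", score, tuple(rationale))
    if a.seed_mismatches:
        rationale.append(f"seed_mismatches={a.seed_mismatches}")
    if a.distal_mismatches:
        rationale.append(f"distal_mismatches={a.distal_mismatches}")
    if a.pam_status == "variant":
        rationale.append("pam_variant")
    call = "positive" if score < r.threshold else "negative"
    rationale.append(f"score={score:g}<{r.threshold:g}" if call == "positive"
                     else f"score={score:g}>={r.threshold:g}")
    return SignalPrediction(a.species, call, score, tuple(rationale))


@dataclass(frozen=True, order=True)
class RankScore:
    """Sortable composite discrimination score; larger is better.

    ``fraction`` is the share of off-target species predicted negative
    (0..1); candidates whose own target call is not positive carry
    ``qualified=False`` and sort below every qualified one.  Ties break by
    larger total off-target penalty, then fewer off-target canonical PAMs,
    then leftmost candidate coordinate.
    """

    qualified: bool
    fraction: float
    total_offtarget_penalty: float
    neg_canonical_pams: int  # negated count, so fewer canonical sorts higher
    neg_start: int  # negated coordinate, so leftmost sorts higher


def discrimination_score(c: GuideCandidate,
                         preds: list[SignalPrediction],
                         target_pred: SignalPrediction,
                         assessments: list[SpeciesAssessment] | None = None,
                         ) -> RankScore:
    """Species-discrimination score of a candidate.

    ``preds`` holds one prediction per non-target species; ``target_pred``
    is the prediction from the target's own (identity) assessment.
    """
    if not preds:
        raise ValueError("empty prediction list")
    if not target_pred.positive:
        return RankScore(False, 0.0, 0.0, 0, -c.pam_start)
    fraction = sum(not p.positive for p in preds) / len(preds)
    total_penalty = sum(p.score for p in preds)
    n_canonical = (
        sum(a.pam_status == "canonical" for a in assessments)
        if assessments is not None else 0
    )
    return RankScore(True, fraction, total_penalty, -n_canonical, -c.pam_start)


@dataclass(frozen=True)
class RankedCandidate:
    candidate: GuideCandidate
    score: RankScore
    target_prediction: SignalPrediction
    assessments: tuple[SpeciesAssessment, ...]
    predictions: tuple[SignalPrediction, ...]


def _target_self_assessment(c: GuideCandidate) -> SpeciesAssessment:
    # the target compared to itself: canonical PAM, identical spacer
    return SpeciesAssessment(
        species=c.target_species, pam_status="canonical", pam_obs=c.pam_seq,
        seed_mismatches=0, distal_mismatches=0, gap_positions=0,
        spacer_identical=True,
    )


def rank_candidates(cands: list[GuideCandidate], msa: MsaResult,
                    p: DesignParams = DesignParams(),
                    r: ActivityRules = STRICT) -> list[RankedCandidate]:
    """Assess, predict and rank candidates by discrimination score.

    The sort is stable and descending in :class:`RankScore`, so fully tied
    candidates keep their input order.
    """
    if not cands:
        warnings.warn("no candidates to rank")
        return []
    report: list[RankedCandidate] = []
    for c in cands:
        assessments = assess_candidate(c, msa, p)
        preds = [predict_signal(a, r) for a in assessments]
        target_pred = predict_signal(_target_self_assessment(c), r)
        score = discrimination_score(c, preds, target_pred, assessments)
        report.append(RankedCandidate(c, score, target_pred,
                                      tuple(assessments), tuple(preds)))
    report.sort(key=lambda rc: rc.score, reverse=True)
    return report
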