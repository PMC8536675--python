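"""Confusion-matrix evaluation of an authentication panel.

A panel is a set of blinded samples with known true species; the assay calls
each sample positive (predicted target species) or negative.  Metrics follow
the assay-evaluation conventions:

    accuracy  = 100 * (TP + TN) / total     (correctly predicted / total)
    precision = 100 * TP / (TP + FP)        (true target among predicted target)
    recall    = 100 * TP / (TP + FN)        (target samples detected)

Percentages are rounded half-up to two decimals.  Precision is undefined
(``None``, reported as ``n/a``) when nothing was called positive — distinct
from 0.00.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

from cas12adx.alignment import AlnParams, MsaResult, nw_align, project
from cas12adx.guide_design import (
    DesignParams,
    GuideCandidate,
    assess_species,
    spacer_window,
)
from cas12adx.rpa_amplicon import PrimerSet, predict_amplicon
from cas12adx.sequence_core import SeqRecord
from cas12adx.specificity import ActivityRules, STRICT, SignalPrediction, predict_signal

__all__ = ["PanelManifest", "ConfusionMatrix", "confusion", "evaluate_panel",
           "species_breakdown"]


def _pct(numer: int, denom: int) -> float:
    return float(
        (Decimal(100 * numer) / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class PanelManifest:
    """Sample-to-true-species assignments plus the target species."""

    samples: tuple[tuple[str, str], ...]
    target_species: str

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("manifest needs >=1 sample")
        ids = [sid for sid, _ in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.samples]

    def true_species(self, sample_id: str) -> str:
        for sid, sp in self.samples:
            if sid == sample_id:
                return sp
        raise KeyError(sample_id)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with percentage metrics for one target species."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy_pct(self) -> float:
        return _pct(self.tp + self.tn, self.total)

    @property
    def precision_pct(self) -> float | None:
        called = self.tp + self.fp
        return _pct(self.tp, called) if called else None

    @property
    def recall_pct(self) -> float | None:
        actual = self.tp + self.fn
        return _pct(self.tp, actual) if actual else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy_pct": self.accuracy_pct,
            "precision_pct": self.precision_pct,
            "recall_pct": self.recall_pct,
        }


def confusion(manifest: PanelManifest,
              calls: Mapping[str, str]) -> ConfusionMatrix:
    """Tally calls against the manifest's true species.

    ``calls`` must cover every manifest sample exactly once with values
    ``positive`` or ``negative``.
    """
    missing = set(manifest.sample_ids) - set(calls)
    extra = set(calls) - set(manifest.sample_ids)
    if missing:
        raise ValueError(f"calls missing sample(s): {sorted(missing)}")
    if extra:
        raise ValueError(f"calls name unknown sample(s): {sorted(extra)}")
    tp = fp = tn = fn = 0
    for sid, true_sp in manifest.samples:
        call = calls[sid]
        if call not in ("positive", "negative"):
            raise ValueError(f"sample {sid!r}: call must be positive/negative, "
                             f"got {call!r}")
        is_target = true_sp == manifest.target_species
        if call == "positive":
            tp += is_target
            fp += not is_target
        else:
            fn += is_target
            tn += not is_target
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def species_breakdown(manifest: PanelManifest,
                      calls: Mapping[str, str]) -> dict[str, dict[str, int]]:
    """Actual-species x call table (the per-species view of the matrix)."""
    table: dict[str, dict[str, int]] = {}
    for sid, sp in manifest.samples:
        row = table.setdefault(sp, {"positive": 0, "negative": 0})
        row[calls[sid]] += 1
    return table


def _rebase(c: GuideCandidate, msa: MsaResult, row_id: str,
            p: DesignParams) -> GuideCandidate:
    """Recompute a candidate's alignment columns for a different alignment
    (same target sequence, identified by ``row_id``)."""
    pam_pos = range(c.pam_start, c.pam_start + p.pam_len)
    sp_pos = spacer_window(c.strand, c.pam_start, p)
    pam_cols = tuple(project(msa, row_id, i) for i in pam_pos)
    sp_cols = tuple(project(msa, row_id, i) for i in sp_pos)
    if c.strand == "-":
        pam_cols = tuple(reversed(pam_cols))
        sp_cols = tuple(reversed(sp_cols))
    return replace(c, pam_cols=pam_cols, spacer_cols=sp_cols)


def evaluate_panel(samples: list[SeqRecord],
                   manifest: PanelManifest,
                   target_ref: SeqRecord,
                   guide: GuideCandidate,
                   params: DesignParams = DesignParams(),
                   rules: ActivityRules = STRICT,
                   primers: PrimerSet | None = None,
                   aln_params: AlnParams = AlnParams(),
                   ) -> tuple[dict[str, SignalPrediction], ConfusionMatrix]:
    """Predict a call for every panel sample and tally the confusion matrix.

    Each sample is aligned pairwise against the target reference the guide
    was designed on; the guide window is projected into that alignment and
    the sample assessed and called like any off-target species.  When
    ``primers`` is supplied, a sample is additionally required to yield an
    amplicon containing the guide window — no amplicon, no signal.
    """
    if guide.target_species != manifest.target_species:
        raise ValueError("guide was designed for a different target species")
    by_id = {r.id: r for r in samples}
    missing = [sid for sid in manifest.sample_ids if sid not in by_id]
    if missing:
        raise ValueError(f"no sequence for sample(s): {missing}")
    preds: dict[str, SignalPrediction] = {}
    for sid in manifest.sample_ids:
        sample = by_id[sid]
        _, g_ref, g_smp = nw_align(target_ref.ungapped, sample.ungapped, aln_params)
        msa = MsaResult(rows=[
            (target_ref.id, guide.target_species, g_ref),
            (sid, sid, g_smp),
        ])
        cand = _rebase(guide, msa, target_ref.id, params)
        assessment = assess_species(cand, msa, sid, params)
        pred = predict_signal(assessment, rules)
        if pred.positive and primers is not None:
            if not _amplicon_contains(sample, primers, msa, sid, cand):
                pred = SignalPrediction(
                    species=sid, call="negative", score=pred.score,
                    rationale=pred.rationale + ("no_amplicon",),
                )
        preds[sid] = pred
    calls = {sid: p.call for sid, p in preds.items()}
    return preds, confusion(manifest, calls)


def _amplicon_contains(sample: SeqRecord, primers: PrimerSet, msa: MsaResult,
                       sample_row: str, cand: GuideCandidate) -> bool:
    mapped = [msa.res_of[sample_row][col] for col in cand.window_cols
              if col in msa.res_of[sample_row]]
    if not mapped:
        return False
    gstart, gend = min(mapped), max(mapped) + 1
    for hit in predict_amplicon(sample, primers):
        if hit.fwd_end <= gstart and gend <= hit.rev_start:
            return True
    return False
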