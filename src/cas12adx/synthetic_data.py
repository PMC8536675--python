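"""Deterministic generator of barcode panels with controlled variation.

Real chloroplast-barcode datasets for this assay are not deposited anywhere
machine-readable, so every other module is exercised on synthetic panels: a
random target locus with a planted PAM+spacer site, and off-target species
derived from the target by placing substitutions (or deletions) in chosen
zones of the guide window — PAM, seed, distal — or at neutral positions,
plus low-level background divergence outside the window.  Because each
off-target's edit list is known, the generator doubles as its own oracle:
the expected per-species assessment of the planted guide is computed from
the edit list alone and can be compared against the full
alignment-and-assessment pipeline.

Three named fixtures encode *described* variation configurations of the
Phyllanthus trnL model system (a target-exclusive guide, a conserved guide
with one seed-position-2 variant, and a 20-sample authentication panel).
They are synthetic stand-ins built to reproduce those described mismatch
patterns — not the real trnL sequences — and must not be used as biological
reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from cas12adx.assay_eval import PanelManifest
from cas12adx.guide_design import DesignParams, GuideCandidate
from cas12adx.sequence_core import GAP, BarcodePanel, SeqRecord, revcomp, iupac_match

__all__ = ["Edit", "PanelSpec", "PlantedGuide", "ExpectedAssessment",
           "GroundTruth", "Fixture", "generate_panel", "fixture",
           "FIXTURE_NAMES"]

_BASES = "ACGT"


@dataclass(frozen=True)
class Edit:
    """One planned difference of an off-target species from the target.

    ``zone`` is ``PAM`` (offset = 0-based position within the PAM, in
    guide-strand order), ``seed`` / ``distal`` (offset = 1-based spacer
    position counted from the PAM-proximal base), or ``neutral`` (offset =
    absolute plus-strand position outside the guide window).  ``new_base``
    is read on the guide strand; ``'-'`` deletes the base; ``None`` picks
    the next base in A->C->G->T cyclic order, guaranteeing a mismatch.
    """

    zone: str
    offset: int
    new_base: str | None = None

    def __post_init__(self) -> None:
        if self.zone not in ("PAM", "seed", "distal", "neutral"):
            raise ValueError(f"unknown edit zone {self.zone!r}")
        if self.new_base is not None and self.new_base not in set(_BASES) | {GAP}:
            raise ValueError(f"new_base must be A/C/G/T/'-', got {self.new_base!r}")


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for one synthetic panel.

    The target is ``species1``; off-targets are ``species2`` ..
    ``species<n>`` unless ``offtarget_edits`` uses custom names.  Background
    divergence applies per-site outside the guide window only, so planted
    assessments are unaffected by it.
    """

    seed: int
    n_species: int
    locus_len: int = 400
    guide_pos: int | None = None  # None: locus midpoint
    guide_strand: str = "+"
    pam_seq: str = "TTTA"
    spacer_bases: tuple[tuple[int, str], ...] = ()
    offtarget_edits: tuple[tuple[str, tuple[Edit, ...]], ...] = ()
    background_divergence: float = 0.02
    indels: bool = False
    design: DesignParams = field(default_factory=DesignParams)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need >=2 species")
        if self.guide_pos is None:
            object.__setattr__(self, "guide_pos", self.locus_len // 2)
        if self.guide_strand not in "+-":
            raise ValueError("guide_strand must be '+' or '-'")
        if not 0.0 <= self.background_divergence < 1.0:
            raise ValueError("background_divergence must be in [0, 1)")
        p = self.design
        if len(self.pam_seq) != p.pam_len or not all(
                iupac_match(a, b) for a, b in zip(self.pam_seq, p.pam_pattern)):
            raise ValueError(
                f"planted PAM {self.pam_seq!r} incompatible with pattern "
                f"{p.pam_pattern!r}")
        ws, we = self.window_span
        if ws < 1 or we > self.locus_len - 1:
            raise ValueError("guide window (plus one flank base each side) "
                             "must fit inside the locus")

    @property
    def window_span(self) -> tuple[int, int]:
        """Plus-strand half-open span of PAM+spacer."""
        g, k, L = self.guide_pos, self.design.pam_len, self.design.spacer_len
        if self.guide_strand == "+":
            return g, g + k + L
        return g - L, g + k

    @property
    def species_names(self) -> list[str]:
        custom = [name for name, _ in self.offtarget_edits]
        names = ["species1"]
        auto = (f"species{i}" for i in range(2, 2 + self.n_species))
        for name in custom:
            names.append(name)
        while len(names) < self.n_species:
            nxt = next(auto)
            if nxt not in names:
                names.append(nxt)
        if len(names) != self.n_species:
            raise ValueError("more edited species than n_species allows")
        return names


@dataclass(frozen=True)
class PlantedGuide:
    """Coordinates and sequence of the planted site on the target."""

    target_species: str
    strand: str
    pam_start: int
    pam_seq: str
    spacer_seq: str

    def as_candidate(self, p: DesignParams) -> GuideCandidate:
        """The planted site as a candidate with identity column mapping
        (valid whenever the target row of the alignment is gap-free)."""
        g, k, L = self.pam_start, p.pam_len, p.spacer_len
        if self.strand == "+":
            pam_cols = tuple(range(g, g + k))
            sp_cols = tuple(range(g + k, g + k + L))
        else:
            pam_cols = tuple(range(g + k - 1, g - 1, -1))
            sp_cols = tuple(range(g - 1, g - L - 1, -1))
        return GuideCandidate(
            target_species=self.target_species, strand=self.strand,
            pam_start=g, pam_seq=self.pam_seq, pam_cols=pam_cols,
            spacer_seq=self.spacer_seq, spacer_cols=sp_cols,
            guide_id=f"{self.target_species}_planted{self.strand}{g}",
        )


@dataclass(frozen=True)
class ExpectedAssessment:
    """Assessment the pipeline must reproduce for one off-target species."""

    species: str
    pam_status: str
    seed_mismatches: int
    distal_mismatches: int
    gap_positions: int
    spacer_gaps: int = 0

    @property
    def spacer_identical(self) -> bool:
        return (self.seed_mismatches == 0 and self.distal_mismatches == 0
                and self.spacer_gaps == 0)


@dataclass(frozen=True)
class GroundTruth:
    planted: PlantedGuide
    expected: tuple[ExpectedAssessment, ...]

    def expected_for(self, species: str) -> ExpectedAssessment:
        for e in self.expected:
            if e.species == species:
                return e
        raise KeyError(species)


def _abs_pos(e: Edit, spec: PanelSpec) -> int:
    """Plus-strand position of an edit."""
    g, strand = spec.guide_pos, spec.guide_strand
    k, L = spec.design.pam_len, spec.design.spacer_len
    if e.zone == "PAM":
        if not 0 <= e.offset < k:
            raise ValueError(f"PAM edit offset {e.offset} out of range 0..{k - 1}")
        return g + e.offset if strand == "+" else g + (k - 1) - e.offset
    if e.zone in ("seed", "distal"):
        if not 1 <= e.offset <= L:
            raise ValueError(f"spacer edit offset {e.offset} out of range 1..{L}")
        in_seed = spec.design.is_seed(e.offset)
        if (e.zone == "seed") != in_seed:
            raise ValueError(
                f"edit zone {e.zone!r} inconsistent with spacer position "
                f"{e.offset} (seed window {spec.design.seed_window})")
        return g + k + (e.offset - 1) if strand == "+" else g - e.offset
    ws, we = spec.window_span
    if ws <= e.offset < we:
        raise ValueError(f"neutral edit at {e.offset} falls inside the guide window")
    if not 0 <= e.offset < spec.locus_len:
        raise ValueError(f"neutral edit at {e.offset} outside the locus")
    return e.offset


def _next_base(b: str) -> str:
    return _BASES[(_BASES.index(b) + 1) % 4]


def _guide_strand_base(plus_base: str, strand: str) -> str:
    return plus_base if strand == "+" else revcomp(plus_base)


def generate_panel(spec: PanelSpec) -> tuple[BarcodePanel, GroundTruth]:
    """Build the panel and its ground truth; bit-reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    p = spec.design
    target = list(rng.choice(list(_BASES), size=spec.locus_len))
    g, k, strand = spec.guide_pos, p.pam_len, spec.guide_strand
    # plant the PAM (guide-strand sequence placed in plus orientation)
    plus_pam = spec.pam_seq if strand == "+" else revcomp(spec.pam_seq)
    target[g:g + k] = list(plus_pam)
    # forced spacer bases (guide-strand positions/bases)
    for pos1, base in spec.spacer_bases:
        e = Edit("seed" if p.is_seed(pos1) else "distal", pos1)  # reuse mapping
        ap = _abs_pos(e, spec)
        target[ap] = base if strand == "+" else revcomp(base)
    ws, we = spec.window_span
    # pin the window flanks so any in-window deletion keeps its alignment
    # gap inside the window (no homopolymer bleed across the boundary)
    for flank, inner in ((ws - 1, ws), (we, we - 1)):
        if target[flank] == target[inner]:
            target[flank] = "C" if target[inner] != "C" else "G"
    target_seq = "".join(target)

    edits_by_species = dict(spec.offtarget_edits)
    names = spec.species_names
    records = [SeqRecord(id="s1", species=names[0], seq=target_seq)]
    expected: list[ExpectedAssessment] = []
    for idx, name in enumerate(names[1:], start=2):
        edits = edits_by_species.get(name, ())
        seq, exp = _derive_offtarget(name, edits, target, spec, rng)
        records.append(SeqRecord(id=f"s{idx}", species=name, seq=seq))
        expected.append(exp)

    spacer_positions = (range(g + k, g + k + p.spacer_len) if strand == "+"
                        else range(g - 1, g - p.spacer_len - 1, -1))
    spacer_seq = "".join(
        _guide_strand_base(target_seq[i], strand) for i in spacer_positions)
    truth = GroundTruth(
        planted=PlantedGuide(
            target_species=names[0], strand=strand, pam_start=g,
            pam_seq=spec.pam_seq, spacer_seq=spacer_seq),
        expected=tuple(expected),
    )
    return BarcodePanel(records=records, target_species=names[0]), truth


def _derive_offtarget(name: str, edits: Iterable[Edit], target: list[str],
                      spec: PanelSpec, rng: np.random.Generator,
                      ) -> tuple[str, ExpectedAssessment]:
    p = spec.design
    seq = list(target)
    ws, we = spec.window_span
    seen: dict[int, Edit] = {}
    pam_obs = list(spec.pam_seq)
    seed_mm = distal_mm = pam_gaps = spacer_gaps = 0
    for e in edits:
        ap = _abs_pos(e, spec)
        if ap in seen:
            raise ValueError(f"{name}: position {ap} edited twice")
        seen[ap] = e
        current_guide = _guide_strand_base(seq[ap], spec.guide_strand)
        nb = e.new_base if e.new_base is not None else _next_base(current_guide)
        if nb == current_guide:
            raise ValueError(
                f"{name}: edit at {e.zone}/{e.offset} is a no-op ({nb})")
        if nb == GAP:
            if not spec.indels:
                raise ValueError(f"{name}: gap edit requires indels=True")
            seq[ap] = GAP  # marks deletion; stripped below
        else:
            seq[ap] = nb if spec.guide_strand == "+" else revcomp(nb)
        if e.zone == "PAM":
            pam_obs[e.offset] = nb
            pam_gaps += nb == GAP
        elif e.zone == "seed":
            seed_mm += 1
            spacer_gaps += nb == GAP
        elif e.zone == "distal":
            distal_mm += 1
            spacer_gaps += nb == GAP
    # background divergence strictly outside the window, skipping the pinned
    # flanks and already-edited positions
    bg = spec.background_divergence
    if bg > 0:
        for i in range(spec.locus_len):
            if ws - 1 <= i <= we or i in seen:
                continue
            if rng.random() < bg:
                seq[i] = _next_base(seq[i]) if seq[i] != GAP else seq[i]
    if GAP in pam_obs:
        pam_status = "absent"
    elif all(iupac_match(o, q) for o, q in zip(pam_obs, p.pam_pattern)):
        pam_status = "canonical"
    else:
        pam_status = "variant"
    exp = ExpectedAssessment(
        species=name, pam_status=pam_status, seed_mismatches=seed_mm,
        distal_mismatches=distal_mm, gap_positions=pam_gaps + spacer_gaps,
        spacer_gaps=spacer_gaps)
    return "".join(ch for ch in seq if ch != GAP), exp


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A named synthetic scenario with its panel, truth and expectations.

    ``expected_calls`` maps a rule-preset name to the species->call pattern
    the planted guide must produce, including the target species itself.
    ``manifest`` is set only for sample-level (authentication-panel)
    fixtures, where ``panel.records`` are per-sample and ``expected_matrix``
    gives the (tp, fp, tn, fn) counts under the named preset.
    """

    name: str
    panel: BarcodePanel
    truth: GroundTruth
    design: DesignParams
    expected_calls: dict[str, dict[str, str]]
    manifest: PanelManifest | None = None
    expected_matrix: dict[str, tuple[int, int, int, int]] | None = None

    @property
    def target_record(self) -> SeqRecord:
        for r in self.panel.records:
            if r.species == self.panel.target_species:
                return r
        raise AssertionError("panel lost its target record")

    def candidate(self) -> GuideCandidate:
        return self.truth.planted.as_candidate(self.design)


FIXTURE_NAMES = ("gRNA-A", "gRNA-B", "accuracy-panel")

_PAM_VARIANT = (Edit("PAM", 2, "G"),)          # TTTA -> TTGA: pattern-breaking
_PAM_VARIANT2 = (Edit("PAM", 1, "C"),)         # TTTA -> TCTA
# One PAM base deleted -> status absent.  The deletion is paired with a seed
# substitution: the identity override (identical spacer => positive) would
# otherwise outrank the absent-PAM rule, and the species this zone pattern
# emulates varies in the binding site as well as lacking the PAM.
_PAM_DELETION = (Edit("PAM", 1, GAP), Edit("seed", 3))


def _fixture_grna_a() -> Fixture:
    """Target-exclusive guide: every off-target loses PAM or seed matching."""
    spec = PanelSpec(
        seed=2301, n_species=4, indels=True,
        offtarget_edits=(
            ("species2", _PAM_VARIANT + (Edit("seed", 1),)),
            ("species3", _PAM_VARIANT2 + (Edit("distal", 8), Edit("distal", 12),
                                          Edit("distal", 16))),
            ("species4", _PAM_DELETION),
        ),
    )
    panel, truth = generate_panel(spec)
    neg = {"species2": "negative", "species3": "negative",
           "species4": "negative"}
    return Fixture(
        name="gRNA-A", panel=panel, truth=truth, design=spec.design,
        expected_calls={
            "strict": {"species1": "positive", **neg},
            "permissive": {"species1": "positive", **neg},
        },
    )


def _fixture_grna_b() -> Fixture:
    """Conserved guide on the opposite strand: canonical PAM everywhere, one
    seed-position-2 A>G variant; discriminates nothing under relaxed rules."""
    spec = PanelSpec(
        seed=2302, n_species=4, guide_pos=220, guide_strand="-",
        spacer_bases=((2, "A"),),
        offtarget_edits=(
            ("species2", (Edit("seed", 2, "G"),)),
            ("species3", (Edit("distal", 10),)),
            ("species4", ()),
        ),
    )
    panel, truth = generate_panel(spec)
    return Fixture(
        name="gRNA-B", panel=panel, truth=truth, design=spec.design,
        expected_calls={
            "strict": {"species1": "positive", "species2": "negative",
                       "species3": "positive", "species4": "positive"},
            "permissive": {"species1": "positive", "species2": "positive",
                           "species3": "positive", "species4": "positive"},
        },
    )


#: (species, n_samples, edits) for the 20-sample authentication panel.
_ACCURACY_PANEL = (
    ("Phyllanthus_amarus", 7, ()),                                   # target
    ("Phyllanthus_urinaria", 2, _PAM_VARIANT2 + (Edit("distal", 8),
                                                 Edit("distal", 12),
                                                 Edit("distal", 16))),
    ("Phyllanthus_debilis", 2, _PAM_VARIANT + (Edit("seed", 1),)),
    ("Phyllanthus_virgatus", 1, _PAM_DELETION),
    ("Phyllanthus_airy-shawii", 2, (Edit("seed", 1), Edit("seed", 3))),
    ("Phyllanthus_acidus", 1, (Edit("seed", 2), Edit("seed", 4))),
    ("Phyllanthus_emblica", 2, (Edit("seed", 1), Edit("seed", 2),
                                Edit("seed", 5))),
    ("Phyllanthus_reticulatus", 2, _PAM_VARIANT),  # variant PAM, identical spacer
    ("Phyllanthus_sp", 1, (Edit("seed", 4), Edit("distal", 9),
                           Edit("distal", 14))),
)


def _fixture_accuracy_panel() -> Fixture:
    """20-sample blinded authentication panel.

    Species composition 7/2/2/1/2/1/2/2/1; the two identical-spacer,
    variant-PAM samples cross-react (identity override), so under the strict
    preset the expected matrix is (tp, fp, tn, fn) = (7, 2, 11, 0):
    accuracy 90.00, precision 77.78, recall 100.00.
    """
    species_spec = PanelSpec(
        seed=2303, n_species=len(_ACCURACY_PANEL), indels=True,
        offtarget_edits=tuple((sp, ed) for sp, _, ed in _ACCURACY_PANEL[1:]),
    )
    species_panel, truth = generate_panel(species_spec)
    by_species = {r.species: r for r in species_panel.records}
    by_species[_ACCURACY_PANEL[0][0]] = replace(
        by_species.pop("species1"), species=_ACCURACY_PANEL[0][0])
    truth = replace(truth, planted=replace(
        truth.planted, target_species=_ACCURACY_PANEL[0][0]))
    samples: list[SeqRecord] = []
    manifest_rows: list[tuple[str, str]] = []
    n = 0
    for sp, count, _ in _ACCURACY_PANEL:
        for _ in range(count):
            n += 1
            sid = f"A{n:02d}"
            samples.append(replace(by_species[sp], id=sid))
            manifest_rows.append((sid, sp))
    manifest = PanelManifest(samples=tuple(manifest_rows),
                             target_species=_ACCURACY_PANEL[0][0])
    return Fixture(
        name="accuracy-panel",
        panel=BarcodePanel(records=samples,
                           target_species=manifest.target_species),
        truth=truth, design=species_spec.design,
        expected_calls={}, manifest=manifest,
        expected_matrix={"strict": (7, 2, 11, 0)},
    )


_FIXTURES = {
    "gRNA-A": _fixture_grna_a,
    "gRNA-B": _fixture_grna_b,
    "accuracy-panel": _fixture_accuracy_panel,
}


def fixture(name: str) -> Fixture:
    """Build a named fixture: ``gRNA-A``, ``gRNA-B`` or ``accuracy-panel``."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        ) from None
    return builder()
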