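import random

import pytest

from cas12adx.alignment import MsaResult, star_msa
from cas12adx.guide_design import (
    DesignParams,
    assess_candidate,
    assess_species,
    build_construct,
    enumerate_candidates,
    scan_pams,
)
from cas12adx.sequence_core import revcomp
from cas12adx.synthetic_data import Edit, PanelSpec, generate_panel

from conftest import bf_pam_hits, random_dna

P = DesignParams()


class TestScanPams:
    def test_single_planted_plus_strand_site(self):
        seq = "TTTA" + "C" * 25
        assert scan_pams(seq, P) == [("+", 0, "TTTA")]

    def test_all_t_sequence_has_no_sites(self):
        # V excludes T, so a poly-T stretch never matches TTTV
        assert scan_pams("T" * 40, P) == []

    def test_site_without_room_for_spacer_skipped(self):
        # PAM at the very end: no spacer space 3' of it on the plus strand
        seq = "G" * 30 + "TTTA"
        assert all(s != "+" for s, _, _ in scan_pams(seq, P))

    def test_minus_strand_hit_reported_in_plus_coordinates(self):
        # plant TAAA at 25: minus-strand PAM TTTA, spacer to its left
        seq = "C" * 25 + "TAAA" + "G" * 5
        hits = scan_pams(seq, P)
        assert ("-", 25, "TTTA") in hits

    def test_too_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert scan_pams("TTTACGT", P) == []

    def test_matches_sliding_window_oracle_on_random_sequences(self):
        rng = random.Random(3)
        for _ in range(100):
            seq = random_dna(rng, 60)
            got = set(scan_pams(seq, P))
            assert got == bf_pam_hits(seq, "TTTV", 21), seq

    def test_plus_only_mode_drops_minus_hits(self):
        rng = random.Random(13)
        p1 = DesignParams(scan_both_strands=False)
        for _ in range(20):
            seq = random_dna(rng, 60)
            assert set(scan_pams(seq, p1)) == bf_pam_hits(
                seq, "TTTV", 21, both_strands=False)


def _single_row_msa(seq: str, species: str = "sp1") -> MsaResult:
    return MsaResult(rows=[("r1", species, seq)])


class TestEnumerateCandidates:
    def test_planted_site_yields_one_plus_candidate(self):
        spec = PanelSpec(seed=21, n_species=2, locus_len=120,
                         background_divergence=0.0)
        panel, truth = generate_panel(spec)
        msa = star_msa(panel)
        cands = enumerate_candidates(msa, P, "species1")
        planted = [c for c in cands if c.pam_start == truth.planted.pam_start
                   and c.strand == truth.planted.strand]
        assert len(planted) == 1
        assert planted[0].spacer_seq == truth.planted.spacer_seq

    def test_minus_strand_spacer_is_revcomp_of_planted_window(self):
        spec = PanelSpec(seed=22, n_species=2, locus_len=120, guide_pos=60,
                         guide_strand="-", background_divergence=0.0)
        panel, truth = generate_panel(spec)
        msa = star_msa(panel)
        cands = enumerate_candidates(msa, P, "species1")
        hit = next(c for c in cands if c.strand == "-" and c.pam_start == 60)
        target = panel.records[0].seq
        assert hit.spacer_seq == revcomp(target[60 - 21:60])
        assert hit.spacer_seq == truth.planted.spacer_seq

    def test_gap_in_target_pam_window_excludes_candidate(self):
        gapped = "CC" + "TT-TA" + "A" * 25
        msa = MsaResult(rows=[("r1", "sp1", gapped),
                              ("r2", "sp2", gapped.replace("-", "G"))])
        assert enumerate_candidates(msa, P, "sp1") == []

    def test_strand_symmetry_under_panel_reverse_complement(self):
        spec = PanelSpec(seed=23, n_species=3, locus_len=140,
                         background_divergence=0.03)
        panel, _ = generate_panel(spec)
        msa_f = star_msa(panel)
        from dataclasses import replace
        rc_panel = type(panel)(
            records=[replace(r, seq=revcomp(r.seq)) for r in panel.records],
            target_species=panel.target_species)
        msa_r = star_msa(rc_panel)
        L = len(panel.records[0].seq)
        fwd = {(c.strand, c.pam_start, c.spacer_seq)
               for c in enumerate_candidates(msa_f, P, "species1")}
        rev = set()
        for c in enumerate_candidates(msa_r, P, "species1"):
            strand = "+" if c.strand == "-" else "-"
            start = L - c.pam_start - P.pam_len
            rev.add((strand, start, c.spacer_seq))
        assert fwd == rev

    def test_equals_bruteforce_on_short_panels(self):
        rng = random.Random(31)
        for _ in range(20):
            seq = random_dna(rng, 80)
            msa = MsaResult(rows=[("r1", "sp1", seq), ("r2", "sp2", seq)])
            got = {(c.strand, c.pam_start, c.pam_seq)
                   for c in enumerate_candidates(msa, P, "sp1")}
            assert got == bf_pam_hits(seq, "TTTV", 21)

    def test_discordant_second_target_row_disqualifies(self):
        seq = "CC" + "TTTA" + "G" * 25
        variant = "CC" + "TTTA" + "C" + "G" * 24  # differs at spacer pos 1
        msa = MsaResult(rows=[("r1", "sp1", seq), ("r1b", "sp1", variant),
                              ("r2", "sp2", seq)])
        assert enumerate_candidates(msa, P, "sp1") == []

    def test_unknown_target_species_rejected(self):
        with pytest.raises(KeyError):
            enumerate_candidates(_single_row_msa("A" * 30), P, "nope")


class TestAssessCandidate:
    def _setup(self, offtarget_edits, seed=41, **kw):
        spec = PanelSpec(seed=seed, n_species=2, locus_len=120,
                         offtarget_edits=(("species2", offtarget_edits),),
                         background_divergence=0.0, **kw)
        panel, truth = generate_panel(spec)
        msa = star_msa(panel)
        cands = enumerate_candidates(msa, P, "species1")
        cand = next(c for c in cands if c.pam_start == truth.planted.pam_start
                    and c.strand == truth.planted.strand)
        return cand, msa

    def test_identical_offtarget_is_fully_clean(self):
        cand, msa = self._setup(())
        (a,) = assess_candidate(cand, msa)
        assert (a.pam_status, a.seed_mismatches, a.distal_mismatches,
                a.gap_positions, a.spacer_identical) == ("canonical", 0, 0, 0, True)

    def test_single_seed_position2_mismatch_with_conserved_pam(self):
        cand, msa = self._setup((Edit("seed", 2, None),))
        (a,) = assess_candidate(cand, msa)
        assert a.pam_status == "canonical"
        assert (a.seed_mismatches, a.distal_mismatches) == (1, 0)
        assert not a.spacer_identical

    def test_pattern_breaking_pam_is_variant(self):
        cand, msa = self._setup((Edit("PAM", 2, "G"),))  # TTTA -> TTGA
        (a,) = assess_candidate(cand, msa)
        assert a.pam_status == "variant"
        assert a.pam_obs == "TTGA"
        assert a.spacer_identical  # spacer untouched

    def test_pam_gap_is_absent(self):
        cand, msa = self._setup((Edit("PAM", 1, "-"),), indels=True)
        (a,) = assess_candidate(cand, msa)
        assert a.pam_status == "absent"
        assert a.gap_positions == 1

    def test_pam_edit_within_pattern_stays_canonical(self):
        # V covers A/C/G: an A->G swap at the V position keeps the PAM canonical
        cand, msa = self._setup((Edit("PAM", 3, "G"),))
        (a,) = assess_candidate(cand, msa)
        assert a.pam_status == "canonical"

    def test_minus_strand_assessment_counts_guide_strand_positions(self):
        cand, msa = self._setup((Edit("seed", 1, None), Edit("distal", 7, None)),
                                guide_pos=60, guide_strand="-")
        (a,) = assess_candidate(cand, msa)
        assert (a.seed_mismatches, a.distal_mismatches) == (1, 1)

    def test_mismatch_counts_partition_the_spacer_mismatch_set(self):
        rng = random.Random(99)
        for seed in range(10):
            edits = []
            positions = rng.sample(range(1, 22), rng.randint(0, 5))
            for pos in positions:
                edits.append(Edit("seed" if pos <= 5 else "distal", pos, None))
            cand, msa = self._setup(tuple(edits), seed=500 + seed)
            (a,) = assess_candidate(cand, msa)
            assert a.seed_mismatches + a.distal_mismatches == len(positions)

    def test_species_consensus_with_ambiguity_still_matches(self):
        # two rows of one species differing at one spacer base collapse to an
        # IUPAC code that still intersects the target base => no mismatch
        base = "CC" + "TTTA" + "A" * 25
        v1 = "CC" + "TTTA" + "A" * 25
        v2 = "CC" + "TTTA" + "G" + "A" * 24
        msa = MsaResult(rows=[("t", "sp1", base), ("o1", "sp2", v1),
                              ("o2", "sp2", v2)])
        cand = enumerate_candidates(msa, P, "sp1")[0]
        (a,) = assess_candidate(cand, msa)
        assert a.seed_mismatches == 0  # consensus R intersects A

    def test_missing_species_is_an_error(self):
        cand, msa = self._setup(())
        with pytest.raises(KeyError):
            assess_species(cand, msa, "ghost")


class TestBuildConstruct:
    def _cand(self):
        spec = PanelSpec(seed=61, n_species=2, locus_len=120,
                         background_divergence=0.0)
        panel, truth = generate_panel(spec)
        return truth.planted.as_candidate(P)

    def test_crrna_is_rna_scaffold_plus_spacer(self):
        c = self._cand()
        crrna, top, bottom = build_construct(c)
        assert len(crrna) == 21 + 21  # LbCas12a repeat is 21 nt
        assert "T" not in crrna and "U" in crrna

    def test_bottom_strand_is_revcomp_of_top(self):
        c = self._cand()
        _, top, bottom = build_construct(c)
        assert bottom == revcomp(top)

    def test_spacer_recoverable_from_construct_3prime_end(self):
        c = self._cand()
        _, top, _ = build_construct(c)
        assert top.endswith(c.spacer_seq)
        assert top[-len(c.spacer_seq):] == c.spacer_seq

    def test_empty_scaffold_rejected(self):
        with pytest.raises(ValueError, match="scaffold"):
            build_construct(self._cand(), repeat="")


class TestDesignParams:
    def test_spacer_must_cover_seed_window(self):
        with pytest.raises(ValueError):
            DesignParams(spacer_len=18, seed_window=(1, 19))

    def test_spacer_length_bounds(self):
        with pytest.raises(ValueError):
            DesignParams(spacer_len=30)

    def test_tttn_variant_pattern_accepted(self):
        # N admits the TTTT site that TTTV rejects
        p = DesignParams(pam_pattern="TTTN", scan_both_strands=False)
        assert scan_pams("TTTT" + "C" * 21, p) == [("+", 0, "TTTT")]
        assert scan_pams("TTTT" + "C" * 21, DesignParams(
            scan_both_strands=False)) == []
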