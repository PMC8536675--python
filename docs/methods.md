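# Methods

This note documents the models, conventions and design choices behind
`cas12adx`, in the order data flows through the tool.

## Sequence model and coordinate conventions

All sequences are uppercase DNA over the IUPAC alphabet with `-` as gap;
`U` is converted to `T` on ingest so guide RNAs and DNA targets compare
directly. Ambiguity codes match by **set intersection**: two characters
match iff their concrete-base sets share a member (`R` matches `A`; the PAM
symbol `V` matches A/C/G). A gap matches nothing, including another gap —
gaps are absence of sequence, not uncertainty. Multiple records of one
species are collapsed column-by-column to the IUPAC union of their bases
(any gap ⇒ gap) before assessment, so assessments are per-species.

Coordinates are 0-based half-open internally; reports print 1-based
positions. Spacer positions are numbered 1..L from the PAM-proximal base,
so spacer position 1 is seed position 1; the seed window defaults to the
inclusive range 1–5.

## Alignment

Pairwise alignment is global Needleman–Wunsch with linear gap penalties
(defaults match +1, mismatch −1, gap −2), computed over anti-diagonal
wavefronts in numpy. Ties break deterministically: substitution over gap-in
second sequence over gap-in-first, applied both in the fill and the
traceback, so outputs are bit-stable across runs and platforms.

The multiple alignment is center-star: the center is the record maximising
the summed pairwise score against all others (ties go to the earliest
record), and the remaining rows merge under "once a gap, always a gap",
with insert runs left-aligned within their slot. Barcode loci are short
(~300–500 nt) and panels small, so the O(k²L²) cost is negligible, and the
construction guarantees that substitution-only panels align gap-free —
which is what isolates guide-design logic from alignment behaviour in the
tests. Center-star alignments are not claimed to match any external
aligner's output; users who prefer an external aligner such as MAFFT can
pass aligned FASTA and skip this step (`aln --aligned`).

## Guide design

PAM scanning slides the IUPAC pattern (default `TTTV`) over both strands,
keeping only hits with room for a full spacer 3′ of the PAM on the hit
strand; minus-strand hits are reported in plus-strand coordinates. The
spacer length default is 21 nt (typical LbCas12a; no canonical value is
universal), configurable 18–24. A `TTTN` pattern is selectable for the
relaxed-PAM reading of Cas12a specificity.

A candidate whose PAM window is interrupted by an alignment gap *in the
target row* is dropped: the cross-species projection of a split motif is
unreliable. When the target species has several rows, a candidate must be
exactly supported (IUPAC-compatible, ungapped) by every target row.

Per-species assessment reads the species consensus at the candidate's
alignment columns, oriented along the candidate strand:

- **PAM status** — `canonical` if every character matches the pattern,
  `absent` if any gap falls in the PAM window, else `variant`.
- **Mismatches** — counted per spacer position under intersection
  semantics; positions 1–5 tally as seed, the rest as distal. An alignment
  gap inside the spacer counts as a mismatch at its position and is also
  reported separately as a gap count.
- `spacer_identical` ⇔ zero seed, zero distal, zero spacer gaps.

## Activity rules

No quantitative Cas12a activity model exists for this assay, so the
positive/negative call is an explicit, inspectable penalty model:
score = seed_penalty·m_seed + distal_penalty·m_distal +
pam_variant_penalty·[variant], negative iff PAM absent or score ≥
threshold. Rule order matters and is fixed: (1) an identical spacer forces
positive (`identity_override`, default on — this is the observed
cross-reactivity mode of an identical-spacer species behind a variant PAM);
(2) absent PAM forces negative; (3) the score decides. Every prediction
carries the ordered list of rules that fired.

Two presets expose the genuine ambiguity in how harshly a single seed
mismatch should be judged: `strict` (3/1/2, threshold 3) makes any seed
mismatch lethal, matching the seed-intolerance reading that explains a
target-exclusive guide; `permissive` (2/1/2, threshold 4) lets one seed
mismatch behind a canonical PAM stay positive, matching the observed
behaviour of a conserved guide with a single seed-position-2 variant. The
presets expose, rather than resolve, that tension; `strict` is the default
because seed intolerance is the design advice the ranking should encode.

Candidates are ranked by the fraction of off-target species predicted
negative (target must be positive, else disqualified), with ties broken by
larger total off-target penalty, then fewer off-target canonical PAMs, then
leftmost coordinate; the sort is stable so fully tied candidates keep input
order.

## RPA amplicon check

Primers are located by a Hamming sliding window (no indels — a primer
anneals without looping out) under intersection semantics, with a default
tolerance of 2 mismatches per primer: RPA is mismatch-tolerant in practice
and no tolerance is standardised, so the default is deliberately
conservative and configurable. The shipped defaults are the universal
chloroplast *trnL* RPA pair (35 nt forward, 34 nt reverse). An amplicon is
any forward span paired with a downstream reverse span within a 1500 bp
cap; its length includes both primer footprints (gel convention), and all
pairs are reported rather than guessing the biological product. A guide
counts as contained only if its whole PAM+spacer window lies strictly
between the primer footprints.

## Panel evaluation

Each blinded sample is aligned pairwise to the target reference the guide
was designed on, the guide window is projected through that alignment, and
the sample is assessed and called exactly like an off-target species — the
target's own samples are *not* assumed positive, they must earn the call
from their own sequence. With primers supplied, a positive call
additionally requires an amplicon containing the guide window (no
amplification, no signal). Metrics are accuracy = 100(TP+TN)/N, precision
= 100·TP/(TP+FP), recall = 100·TP/(TP+FN), rounded half-up to two
decimals; precision with zero positive calls is reported as undefined
(`null`/`n/a`), which the output distinguishes from 0.00.

## Synthetic panels and fixtures

The generator plants a PAM+spacer site (default PAM `TTTA`) at a chosen
position and strand in a random target locus (default 400 nt, roughly a
plant-barcode amplicon), then derives each off-target species by applying a
declared edit list — substitutions or deletions addressed by zone (PAM
offset, seed/distal spacer position, or neutral absolute position) — plus
per-site background divergence (default 0.02, a realistic congeneric
barcode distance) strictly outside the guide window. Because the edit list
fully determines the planted window's cross-species differences, the
generator emits the expected per-species assessment alongside the panel and
serves as its own oracle. Everything is reproducible from the integer seed.

Deletions need care: a base deleted inside a homopolymer run lets the
aligner slide the gap along the run, so the generator pins both bases
flanking the guide window to differ from their window-edge neighbours,
keeping in-window gaps in-window. Indel edits are opt-in
(`indels=true`) and excluded from exact-expectation tests elsewhere; the
substitution-only default keeps alignments gap-free and assessments exact.

Three named fixtures encode described variation patterns of the
*Phyllanthus* *trnL* model system, **as synthetic stand-ins** (the real
sequences are not public; the fixtures reproduce the described mismatch
configurations, not the biology):

- **gRNA-A** — target-exclusive: off-targets carry variant PAM + 1 seed
  mismatch, variant PAM + 3 distal mismatches, and an absent (deleted) PAM
  + 1 seed mismatch. The seed mismatch accompanying the deleted PAM is
  deliberate: an absent-PAM species with a fully identical spacer would be
  called positive by the identity override, and the species this pattern
  models varies in the binding site as well as lacking the PAM.
- **gRNA-B** — conserved, on the opposite strand: canonical PAM everywhere,
  one species with a single seed-position-2 A→G variant, one with a single
  distal variant, one identical. All four species are positive under
  `permissive`; `strict` silences only the seed-variant species.
- **accuracy-panel** — 20 samples across nine species (7 target), with the
  two *P. reticulatus*-like samples sharing the target spacer behind a
  variant PAM. Under `strict` the in-silico evaluation yields
  (TP, FP, TN, FN) = (7, 2, 11, 0): accuracy 90.00, precision 77.78,
  recall 100.00.

## What the synthetic tests do and do not show

Passing fixtures shows the machinery — alignment, projection, assessment,
rules, metrics — behaves exactly as specified on panels whose ground truth
is known by construction. It does not validate the penalty values against
real fluorescence data, does not model amplification efficiency, reporter
kinetics, or detection limits, and the fixtures' background divergence is
uniform i.i.d. rather than phylogenetically structured. Predictions on real
barcode panels should be treated as a screening prior, not an assay result.

## Problem sizes and determinism

Default test and acceptance workloads use 100–400 nt loci, 2–10 species,
200 brute-force alignment pairs (length ≤ 6), 100 random sequences per
scanning oracle, and 100 planted panels for the ranking check — sizes at
which every oracle is exhaustive or near-exhaustive while the whole suite
stays fast. All randomness flows through explicit integer seeds
(`numpy.random.default_rng` in the generator, seeded `random.Random` in
tests); the CLI writes provenance (version, config hash, input checksums)
next to every output, and repeated runs are byte-identical.
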