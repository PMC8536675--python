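"""Sequence records, FASTA I/O, and elementary nucleotide operations.

All sequences are stored as uppercase DNA over the IUPAC nucleotide alphabet
(``ACGT`` plus ambiguity codes ``RYSWKMBDHVN``) with ``-`` as the gap
character.  ``U`` is converted to ``T`` on ingest: guide RNAs are conceptually
RNA but every comparison in this package happens on DNA.

Ambiguity codes are compared by *set intersection*: two characters match if
their base sets share at least one concrete base (so ``R`` matches ``A``, and
the PAM pattern symbol ``V`` matches any of ``A``, ``C``, ``G``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "IUPAC_SETS", "IUPAC_COMPLEMENT", "GAP",
    "SeqRecord", "BarcodePanel",
    "read_fasta", "write_fasta", "revcomp", "hamming_mismatches",
    "iupac_match",
]

GAP = "-"

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Complement table over the full ambiguity alphabet; the gap maps to itself.
IUPAC_COMPLEMENT: Mapping[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}

_BASE_TO_IUPAC: Mapping[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

ALPHABET = frozenset(IUPAC_SETS) | {GAP}


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the IUPAC alphabet."""


class SpeciesLabelError(ValueError):
    """Raised when no species label can be derived for a record."""


def _clean(seq: str, *, where: str = "sequence") -> str:
    """Uppercase, strip whitespace, convert U->T, and validate the alphabet."""
    s = "".join(seq.split()).upper().replace("U", "T")
    if not s:
        raise SequenceValidationError(f"{where}: empty sequence")
    for i, ch in enumerate(s):
        if ch not in ALPHABET:
            raise SequenceValidationError(
                f"{where}: invalid character {ch!r} at position {i}"
            )
    return s


@dataclass(frozen=True)
class SeqRecord:
    """A species-labelled nucleotide sequence.

    Parameters
    ----------
    id
        Record identifier (first FASTA header token).
    species
        Species label; non-empty.
    seq
        Nucleotide string over the IUPAC alphabet, gaps allowed.
    """

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.species:
            raise SpeciesLabelError(f"record {self.id!r}: empty species label")
        object.__setattr__(self, "seq", _clean(self.seq, where=f"record {self.id!r}"))

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class BarcodePanel:
    """Species-labelled barcode sequences plus the designated target species."""

    records: list[SeqRecord]
    target_species: str

    def __post_init__(self) -> None:
        species = {r.species for r in self.records}
        if len(species) < 2:
            raise ValueError("panel needs >=2 distinct species")
        if self.target_species not in species:
            raise ValueError(
                f"target species {self.target_species!r} not in panel "
                f"({sorted(species)})"
            )

    @property
    def species(self) -> list[str]:
        """Distinct species labels in input order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species)
        return list(seen)

    def records_of(self, species: str) -> list[SeqRecord]:
        return [r for r in self.records if r.species == species]


def _species_from_header(description: str, species_map: Mapping[str, str] | None,
                         rec_id: str) -> str:
    if species_map is not None and rec_id in species_map:
        return species_map[rec_id]
    tokens = description.split()
    if len(tokens) >= 2:
        return tokens[1]
    raise SpeciesLabelError(
        f"record {rec_id!r}: no species label (expected second header token "
        "or an entry in species_map)"
    )


def read_fasta(path: str | Path | io.TextIOBase,
               species_map: Mapping[str, str] | None = None) -> list[SeqRecord]:
    """Read a FASTA file into validated :class:`SeqRecord` objects.

    The species label is taken from the second whitespace-separated header
    token unless ``species_map`` supplies one keyed by record id.  Sequences
    are uppercased, ``U`` becomes ``T``, and any character outside the IUPAC
    alphabet raises :class:`SequenceValidationError` naming the record and
    position.  An empty file raises :class:`FastaParseError`.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        first = handle.read(1)
        if first == "":
            raise FastaParseError(f"{path}: empty FASTA file")
        if first != ">":
            raise FastaParseError(f"{path}: line 1: expected '>' header")
        handle.seek(0)
        out: list[SeqRecord] = []
        for bio in SeqIO.parse(handle, "fasta"):
            species = _species_from_header(bio.description, species_map, bio.id)
            out.append(SeqRecord(id=bio.id, species=species, seq=str(bio.seq)))
        if not out:
            raise FastaParseError(f"{path}: no FASTA records")
        return out
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def write_fasta(records: Sequence[SeqRecord], path: str | Path | io.TextIOBase) -> None:
    """Write records as 60-column-wrapped FASTA.

    Headers are ``>id species`` so that :func:`read_fasta` round-trips
    (id, species, seq) exactly.
    """
    bios = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.species)
        for r in records
    ]
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            SeqIO.write(bios, fh, "fasta")
    else:
        SeqIO.write(bios, path, "fasta")


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement; gaps map to gaps; involution."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as e:
        raise SequenceValidationError(f"invalid character {e.args[0]!r}") from None


def iupac_match(a: str, b: str) -> bool:
    """True if the base sets of two IUPAC characters intersect.

    A gap never matches anything (including another gap): gaps are absence
    of sequence, not an ambiguous base.
    """
    sa = IUPAC_SETS.get(a)
    sb = IUPAC_SETS.get(b)
    if sa is None or sb is None:
        if a not in ALPHABET or b not in ALPHABET:
            raise SequenceValidationError(f"invalid character in {a!r}/{b!r}")
        return False  # gap
    return not sa.isdisjoint(sb)


def hamming_mismatches(a: str, b: str) -> list[int]:
    """0-based positions where two equal-length ungapped strings mismatch.

    Ambiguity codes are compared by set intersection, so the relation is
    symmetric.  Gaps are rejected here; gapped comparison is the guide
    assessment's job.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    if GAP in a or GAP in b:
        raise ValueError("hamming_mismatches does not accept gapped input")
    return [i for i, (x, y) in enumerate(zip(a, b)) if not iupac_match(x, y)]


def iupac_union(bases: Iterable[str]) -> str:
    """IUPAC code for the union of concrete-base sets of the inputs.

    Used to collapse multiple records of one species into a per-column
    consensus.  Any gap in the column yields a gap.
    """
    acc: set[str] = set()
    for b in bases:
        if b == GAP:
            return GAP
        acc |= IUPAC_SETS[b]
    return _BASE_TO_IUPAC[frozenset(acc)]
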