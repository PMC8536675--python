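"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately reimplement alignment scoring, PAM matching
and primer search from first principles (own IUPAC tables, plain recursion,
sliding windows) so they stay independent of the package code paths they
check.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# --- independent IUPAC tables ---------------------------------------------

ORACLE_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
               "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
               "D": "H", "H": "D", "N": "N", "-": "-"}


def oracle_match(a: str, b: str) -> bool:
    return bool(ORACLE_SETS[a] & ORACLE_SETS[b])


def oracle_revcomp(s: str) -> str:
    return "".join(ORACLE_COMP[c] for c in reversed(s))


# --- brute-force global alignment score -----------------------------------

def bf_align_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Max global-alignment score by plain recursion over all alignments."""
    def rec(i: int, j: int) -> float:
        if i == len(a):
            return (len(b) - j) * gap
        if j == len(b):
            return (len(a) - i) * gap
        sub = match if oracle_match(a[i], b[j]) else mismatch
        return max(rec(i + 1, j + 1) + sub, rec(i + 1, j) + gap,
                   rec(i, j + 1) + gap)
    return rec(0, 0)


# --- sliding-window PAM and primer oracles --------------------------------

def bf_pam_hits(seq: str, pattern: str, spacer_len: int,
                both_strands: bool = True) -> set[tuple[str, int, str]]:
    k = len(pattern)
    hits = set()
    for i in range(len(seq) - k + 1):
        win = seq[i:i + k]
        if i + k + spacer_len <= len(seq) and all(
                oracle_match(c, q) for c, q in zip(win, pattern)):
            hits.add(("+", i, win))
        if both_strands and i - spacer_len >= 0:
            rc = oracle_revcomp(win)
            if all(oracle_match(c, q) for c, q in zip(rc, pattern)):
                hits.add(("-", i, rc))
    return hits


def bf_primer_spans(seq: str, primer: str, orientation: str,
                    max_mm: int) -> list[tuple[int, int]]:
    query = primer if orientation == "fwd" else oracle_revcomp(primer)
    k = len(query)
    return [
        (i, i + k) for i in range(len(seq) - k + 1)
        if sum(not oracle_match(a, b)
               for a, b in zip(seq[i:i + k], query)) <= max_mm
    ]


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def grna_a():
    from cas12adx import fixture
    return fixture("gRNA-A")


@pytest.fixture(scope="session")
def grna_b():
    from cas12adx import fixture
    return fixture("gRNA-B")


@pytest.fixture(scope="session")
def accuracy_panel():
    from cas12adx import fixture
    return fixture("accuracy-panel")
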