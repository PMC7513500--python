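"""Nucleotide-string utilities shared by all modules.

Sequences are uppercase strings over the IUPAC nucleotide alphabet.  Ambiguity
codes are first-class citizens: two characters *match* whenever the nucleotide
sets they denote intersect (R = {A,G} matches W = {A,T} because both may be A).
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMP_TABLE = str.maketrans(_COMPLEMENT)

_VALID = frozenset(IUPAC_SETS)


class SequenceError(ValueError):
    """Raised for characters outside the IUPAC nucleotide alphabet."""


def _check(s: str) -> None:
    bad = set(s) - _VALID
    if bad:
        raise SequenceError(f"non-IUPAC nucleotide character(s): {sorted(bad)!r}")


def reverse_complement(s: str) -> str:
    """Reverse complement of ``s``; IUPAC codes map to their complements."""
    s = s.upper()
    _check(s)
    return s.translate(_COMP_TABLE)[::-1]


def bases_match(a: str, b: str) -> bool:
    """True iff the nucleotide sets denoted by ``a`` and ``b`` intersect."""
    try:
        sa = IUPAC_SETS[a.upper()]
        sb = IUPAC_SETS[b.upper()]
    except KeyError as e:
        raise SequenceError(f"non-IUPAC nucleotide character: {e.args[0]!r}") from None
    return not sa.isdisjoint(sb)


def is_acgt(c: str) -> bool:
    return c in "ACGT"
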