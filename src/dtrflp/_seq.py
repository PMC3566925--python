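"""Small nucleotide-alphabet helpers shared across modules."""

from __future__ import annotations

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
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

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_nucleotides(seq: str, *, context: str = "sequence") -> None:
    """Raise ``ValueError`` if *seq* contains characters outside the IUPAC set."""
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(
            f"{context} contains non-IUPAC characters: {sorted(bad)!r}"
        )


def iupac_match(pattern_char: str, base: str) -> bool:
    """Whether a concrete read base satisfies an IUPAC pattern character.

    An ambiguous base in the *read* (anything other than A/C/G/T) never
    matches: ambiguity in the data must not create spurious hits.
    """
    if base not in ("A", "C", "G", "T"):
        return False
    return base in IUPAC_SETS.get(pattern_char, frozenset())
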