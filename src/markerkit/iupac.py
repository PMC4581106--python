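"""IUPAC degenerate nucleotide code machinery.

The IUPAC single-letter code maps each letter to a set of concrete bases
(R = A/G, Y = C/T, ..., N = A/C/G/T).  It is used in three places: degenerate
restriction-enzyme recognition sites (e.g. HincII GTYRAC), masking variant
positions before primer design, and validating sequence alphabets.
"""

from __future__ import annotations

#: Degeneracy sets of the 15 IUPAC nucleotide letters.
IUPAC_CODES: dict[str, frozenset[str]] = {
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

#: Inverse table: frozen base set -> IUPAC letter.
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_match(pattern_base: str, base: str) -> bool:
    """Return True iff ``base`` lies in the degeneracy set of ``pattern_base``.

    ``pattern_base`` may be any IUPAC letter; ``base`` must be a concrete
    nucleotide (A/C/G/T).  An ``N`` in the *subject* sequence matches only an
    ``N`` in the pattern, so masked regions never produce phantom enzyme
    sites; that case is handled by the caller (see :func:`matches_at`).
    """
    if pattern_base not in IUPAC_CODES:
        raise ValueError(f"invalid IUPAC letter {pattern_base!r}")
    if base not in "ACGT":
        raise ValueError(f"invalid nucleotide {base!r}")
    return base in IUPAC_CODES[pattern_base]


def code_for(bases) -> str:
    """IUPAC letter for a set of concrete bases (e.g. {A, G} -> R)."""
    key = frozenset(bases)
    if not key <= frozenset("ACGT") or not key:
        raise ValueError(f"not a set of concrete bases: {sorted(bases)!r}")
    return _SET_TO_CODE[key]


def matches_at(seq: str, pattern: str, i: int) -> bool:
    """Does the IUPAC ``pattern`` match ``seq`` starting at 0-based ``i``?

    An ``N`` in the subject sequence matches only a literal ``N`` in the
    pattern, never a degeneracy set.
    """
    if i < 0 or i + len(pattern) > len(seq):
        return False
    for p, b in zip(pattern, seq[i : i + len(pattern)]):
        if b == "N":
            if p != "N":
                return False
        elif b not in IUPAC_CODES[p]:
            return False
    return True


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid_iupac(seq: str) -> bool:
    return all(c in IUPAC_CODES for c in seq)
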