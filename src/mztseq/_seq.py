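"""Small sequence utilities shared across modules.

Everything operates in transcript-sense DNA space (U already exchanged
for T); RNA inputs are converted at the boundary.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of concrete bases they match.
#: An ``N`` in a *sequence* never matches any pattern symbol.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into an overlapping-match regex.

    Uses a lookahead so that every start position is reported even when
    matches overlap.
    """
    if not pattern:
        raise ValueError("empty pattern")
    parts = []
    for ch in pattern.upper():
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"unknown IUPAC symbol {ch!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?={''.join(parts)})")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))
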