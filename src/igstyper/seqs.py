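"""Small sequence utilities shared across the package.

Sequences are plain upper-case strings over the IUPAC nucleotide alphabet.
Each IUPAC code is encoded as a 4-bit mask over {A, C, G, T}; two codes are
compatible iff their masks intersect, which is the matching rule used by the
primer scanner.
"""
from __future__ import annotations

import numpy as np

IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

IUPAC_ALPHABET = frozenset(IUPAC_BITS)
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)

# byte value -> bitmask, 0 for invalid characters
_BITS_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in IUPAC_BITS.items():
    _BITS_LUT[ord(_c)] = _b
    _BITS_LUT[ord(_c.lower())] = _b


def reverse_complement(seq: str) -> str:
    """Reverse complement, degenerate codes included."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bits(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 bitmask array (0 marks invalid symbols)."""
    return _BITS_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def validate_alphabet(seq: str, allow_degenerate: bool = True) -> None:
    """Raise ValueError naming the first offending symbol, if any."""
    allowed = IUPAC_ALPHABET if allow_degenerate else UNAMBIGUOUS
    for i, c in enumerate(seq.upper()):
        if c not in allowed:
            raise ValueError(f"invalid nucleotide symbol {c!r} at position {i + 1}")


def gc_fraction_pct(seq: str) -> float:
    """GC content in percent; requires an unambiguous A/C/G/T sequence."""
    s = seq.upper()
    for c in s:
        if c not in UNAMBIGUOUS:
            raise ValueError(f"degenerate or invalid base {c!r}: GC% is undefined")
    if not s:
        raise ValueError("empty sequence")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)
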