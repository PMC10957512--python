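"""Nucleotide-level utilities shared across the package.

Coordinates everywhere in the library are 0-based half-open on the
working-sense sequence; conversion to 1-based inclusive input coordinates
happens only in the report writers (:mod:`vdjannot.io_model`).
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide classes. A sequence 'N' is an ambiguity code, not a base,
# so it is a member of no class and fails every consensus position.
IUPAC_CLASSES: dict[str, frozenset[str]] = {
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

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    # standard genetic code, built once
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


_CODON_TABLE = _build_codon_table()


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate frame 0; incomplete trailing codon dropped; codons with
    N or other ambiguity translate to 'X'."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(aas)


def has_stop(seq: str) -> bool:
    """True if any complete frame-0 codon of *seq* is a stop codon."""
    return any(
        seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0..4 in a uint8 array (N and anything else -> 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for i, base in enumerate(NUCLEOTIDES):
        out[arr == ord(base)] = i
    return out


def clean_nucleotides(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the IUPAC nucleotide set.

    Non-ACGT IUPAC ambiguity codes are collapsed to N (draft assemblies carry
    them); anything outside the IUPAC set raises ``ValueError`` naming
    *context*.
    """
    seq = raw.upper().replace("U", "T")
    cleaned = []
    for ch in seq:
        if ch in ALPHABET:
            cleaned.append(ch)
        elif ch in IUPAC_CLASSES:
            cleaned.append("N")
        else:
            raise ValueError(f"non-nucleotide character {ch!r} in {context}")
    return "".join(cleaned)
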