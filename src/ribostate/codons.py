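"""Standard genetic code tables (DNA alphabet).

All sequences in this package are DNA strings (A/C/G/T); codons printed with
U elsewhere correspond to the same codon with T here.
"""

from __future__ import annotations

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: aa
    for aa, (b1, b2, b3) in zip(
        _AMINO, ((a, b, c) for a in _BASES for b in _BASES for c in _BASES)
    )
}

STOP_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa == "*")
)

#: The 61 sense codons, sorted alphabetically; the row order of occupancy tables.
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)

START_CODON = "ATG"


def amino_acid(codon: str) -> str:
    """One-letter amino acid for a DNA codon ('*' for stop)."""
    return GENETIC_CODE[codon.upper().replace("U", "T")]
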