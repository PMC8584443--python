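"""Canonical residue alphabet, polarity classes and molecular weights.

The 20 one-letter codes are kept in alphabetical order everywhere
(composition vectors, dipeptide grids, integer sequence codes) so that
every feature layout is reproducible without an external convention.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues the pipeline refuses by default (ambiguity codes and rare
#: residues): B, J, O, U, X, Z.
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ")

# Four-way polarity classification used by the conical mapping:
# class 1 non-polar, class 2 polar, class 3 basic, class 4 acidic.
RESIDUE_CLASSES: dict[int, frozenset[str]] = {
    1: frozenset("AVLIPFWM"),
    2: frozenset("GSTCYNQ"),
    3: frozenset("KRH"),
    4: frozenset("DE"),
}
CLASS_NAMES: dict[int, str] = {
    1: "non-polar",
    2: "polar",
    3: "basic",
    4: "acidic",
}
CLASS_OF: dict[str, int] = {
    aa: idx for idx, members in RESIDUE_CLASSES.items() for aa in members
}

#: Average molecular weight (Da) of each free amino acid. These set the
#: radius of the conical surface each residue is mapped onto.
MOLECULAR_WEIGHT: dict[str, float] = {
    "A": 89.09,
    "C": 121.16,
    "D": 133.10,
    "E": 147.13,
    "F": 165.19,
    "G": 75.07,
    "H": 155.16,
    "I": 131.17,
    "K": 146.19,
    "L": 131.17,
    "M": 149.21,
    "N": 132.12,
    "P": 115.13,
    "Q": 146.15,
    "R": 174.20,
    "S": 105.09,
    "T": 119.12,
    "V": 117.15,
    "W": 204.23,
    "Y": 181.19,
}

#: Fixed length every sequence is truncated/padded to before encoding and
#: featurization.
MAX_PEPTIDE_LENGTH: int = 50
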