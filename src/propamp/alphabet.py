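"""Residue and codon alphabets shared across the package.

Internal convention: amino acids are encoded as integers 0..19 in the order
of :data:`AMINO_ACIDS`; index 20 is the unknown residue ``X`` (scores zero
against every profile column). DNA is kept as plain ``ACGT`` strings; all
translation uses the standard genetic code (translation table 1).
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
X_INDEX = 20  # unknown residue
N_AA = 20

# BLOSUM62 background residue frequencies (Henikoff & Henikoff marginals),
# normalised to sum to one.
_BG = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
BACKGROUND = np.array([_BG[aa] for aa in AMINO_ACIDS], dtype=np.float64)
BACKGROUND /= BACKGROUND.sum()

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))
CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: codons per amino acid, each list sorted for determinism
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: BLOSUM62 restricted to the 20-letter alphabet plus X, in half-bit units
#: (matrix rows/cols follow AMINO_ACIDS order; index 20 = X, scored 0).
BLOSUM62_21 = np.zeros((21, 21), dtype=np.float64)
for _i, _a in enumerate(AMINO_ACIDS):
    for _j, _b in enumerate(AMINO_ACIDS):
        BLOSUM62_21[_i, _j] = _BLOSUM62[_a, _b]


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string to integer indices (unknowns -> 20)."""
    return np.array([AA_INDEX.get(c, X_INDEX) for c in seq.upper()],
                    dtype=np.int64)


def decode_protein(idx: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] if i < N_AA else "X" for i in idx)


def translate(dna: str, to_x: bool = False) -> str:
    """Translate a DNA string codon-by-codon under the standard code.

    Trailing bases that do not complete a codon are ignored. Stop codons
    render as ``*`` or, with ``to_x=True``, as ``X`` (the convention used
    when scanning translated non-coding DNA).
    """
    dna = dna.upper()
    n = len(dna) - len(dna) % 3
    out = []
    for i in range(0, n, 3):
        aa = CODON_TO_AA.get(dna[i:i + 3], "X")
        if aa == "*" and to_x:
            aa = "X"
        out.append(aa)
    return "".join(out)


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS
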