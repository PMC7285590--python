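"""Numeric constants for the classical encoding schemes.

VHSE descriptors are the published 8-component principal-component scores
(hydrophobic, steric, electronic properties), used verbatim.

The row-stochastic BLOSUM62 representation is derived from the integer
half-bit BLOSUM62 score matrix ``s(a, b)`` and the BLOSUM62 background
frequencies ``p(b)``::

    q(a, b) ∝ p(a) * p(b) * 2 ** (s(a, b) / 2)
    p(b | a) = q(a, b) / sum_c q(a, c)

so each amino-acid row is the conditional substitution distribution given
that amino acid and sums to one.  The integer score matrix is read from
Biopython's bundled substitution matrices.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical amino acids, alphabetical one-letter order.  This fixed order
#: defines columns of every encoding matrix and rows 1..20 of the alphabet.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol stored at alphabet index 0.
PAD_TOKEN: str = "-"

# BLOSUM62 marginal (background) amino-acid frequencies, keyed by residue.
# These are the commonly quoted Henikoff & Henikoff marginals.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

# Published VHSE descriptors (8 principal-component scores per residue).
VHSE8_TABLE = {
    "A": (0.15, -1.11, -1.35, -0.92, 0.02, -0.91, 0.36, -0.48),
    "R": (-1.47, 1.45, 1.24, 1.27, 1.55, 1.47, 1.30, 0.83),
    "N": (-0.99, 0.00, -0.37, 0.69, -0.55, 0.85, 0.73, -0.80),
    "D": (-1.15, 0.67, -0.41, -0.01, -2.68, 1.31, 0.03, 0.56),
    "C": (0.18, -1.67, -0.46, -0.21, 0.00, 1.20, -1.61, -0.19),
    "Q": (-0.96, 0.12, 0.18, 0.16, 0.09, 0.42, -0.20, -0.41),
    "E": (-1.18, 0.40, 0.10, 0.36, -2.16, -0.17, 0.91, 0.02),
    "G": (-0.20, -1.53, -2.63, 2.28, -0.53, -1.18, 2.01, -1.34),
    "H": (-0.43, -0.25, 0.37, 0.19, 0.51, 1.28, 0.93, 0.65),
    "I": (1.27, -0.14, 0.30, -1.80, 0.30, -1.61, -0.16, -0.13),
    "L": (1.36, 0.07, 0.26, -0.80, 0.22, -1.37, 0.08, -0.62),
    "K": (-1.17, 0.70, 0.70, 0.80, 1.64, 0.67, 1.63, 0.13),
    "M": (1.01, -0.53, 0.43, 0.00, 0.23, 0.10, -0.86, -0.68),
    "F": (1.52, 0.61, 0.96, -0.16, 0.25, 0.28, -1.33, -0.20),
    "P": (0.22, -0.17, -0.50, 0.05, -0.01, -1.34, -0.19, 3.56),
    "S": (-0.67, -0.86, -1.07, -0.41, -0.32, 0.27, -0.64, 0.11),
    "T": (-0.34, -0.51, -0.55, -1.06, -0.06, -0.01, -0.79, 0.39),
    "W": (1.50, 2.06, 1.79, 0.75, 0.75, -0.13, -1.01, -0.85),
    "Y": (0.61, 1.60, 1.17, 0.73, 0.53, 0.25, -0.96, -0.52),
    "V": (0.76, -0.92, -0.17, -1.91, 0.22, -1.40, -0.24, -0.03),
}


def blosum62_scores() -> np.ndarray:
    """Integer BLOSUM62 score matrix over :data:`AMINO_ACIDS` (20 x 20)."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


def blosum62_conditional() -> np.ndarray:
    """Row-stochastic conditional substitution matrix p(b | a), 20 x 20."""
    scores = blosum62_scores()
    bg = np.array([BLOSUM62_BACKGROUND[a] for a in AMINO_ACIDS])
    bg = bg / bg.sum()
    joint = bg[:, None] * bg[None, :] * np.exp2(scores / 2.0)
    return joint / joint.sum(axis=1, keepdims=True)


def vhse8_values() -> np.ndarray:
    """Published VHSE descriptors over :data:`AMINO_ACIDS` (20 x 8)."""
    return np.array([VHSE8_TABLE[a] for a in AMINO_ACIDS], dtype=float)
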