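"""BLOSUM62 marginal amino-acid background frequencies.

These are the standard background probabilities of the 20 amino acids implied
by the BLOSUM62 substitution data (Henikoff & Henikoff block counts), shipped
as a constant so conservation weights are reproducible offline.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

# Marginal frequencies; they sum to 1.000 at the printed precision and are
# re-normalized defensively below.
_BLOSUM62_FREQ = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

BLOSUM62_BACKGROUND: np.ndarray = np.array(
    [_BLOSUM62_FREQ[a] for a in AMINO_ACIDS], dtype=float
)
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
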