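"""Shared residue alphabet, scoring matrices and background frequencies.

Everything downstream (search, alignment, simulation) indexes amino acids by
their position in :data:`AA20`; ``X`` is the 21st symbol and scores through the
BLOSUM62 ``X`` row.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"
GAP = "-"

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

# Robinson & Robinson style background amino-acid frequencies (order AA20).
BACKGROUND_FREQS = np.array(
    [
        0.0787, 0.0125, 0.0531, 0.0666, 0.0405, 0.0711, 0.0219, 0.0591,
        0.0595, 0.0964, 0.0242, 0.0415, 0.0484, 0.0394, 0.0539, 0.0683,
        0.0541, 0.0673, 0.0109, 0.0304,
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


def _blosum62_array() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a, b]
    return out


BLOSUM62 = _blosum62_array()


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scoring plus Karlin-Altschul statistics.

    ``gap_open``/``gap_extend`` are negative; a gap of length *k* costs
    ``gap_open + k * gap_extend``.  ``karlin_K``/``karlin_lambda`` parameterize
    the E-value E = K * m * n * exp(-lambda * S) for raw score S against a
    query of length m and a database of n residues.  The defaults are the
    standard gapped BLOSUM62 (11, 1) constants.
    """

    matrix: np.ndarray = field(default_factory=lambda: BLOSUM62.copy())
    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    karlin_K: float = 0.041
    karlin_lambda: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.karlin_K <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[AA_INDEX[a], AA_INDEX[b]])


def encode(residues: str) -> np.ndarray:
    """Map a residue string onto alphabet indices (uint8)."""
    try:
        return np.fromiter(
            (AA_INDEX[c] for c in residues), dtype=np.uint8, count=len(residues)
        )
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in indices)
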