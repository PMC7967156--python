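"""BLOSUM-scored substitution events.

A substitution event between sequences *k* and *l* at one alignment
column is scored with BLOSUM50; a residue aligned against a gap scores
the gap penalty (default −8) and a gap aligned against a gap scores 0.
The table below is pinned as a plain-text constant so results never
depend on a runtime download or a library's packaging of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ALPHABET, AMINO_ACIDS, GAP_INDEX, N_SYMBOLS, symbol_to_index

# BLOSUM50, half-bit units, rows/columns in ACDEFGHIKLMNPQRSTVWY order.
_BLOSUM50_TEXT = """
 5 -1 -2 -1 -3  0 -2 -1 -1 -2 -1 -1 -1 -1 -2  1  0  0 -3 -2
-1 13 -4 -3 -2 -3 -3 -2 -3 -2 -2 -2 -4 -3 -4 -1 -1 -1 -5 -3
-2 -4  8  2 -5 -1 -1 -4 -1 -4 -4  2 -1  0 -2  0 -1 -4 -5 -3
-1 -3  2  6 -3 -3  0 -4  1 -3 -2  0 -1  2  0 -1 -1 -3 -3 -2
-3 -2 -5 -3  8 -4 -1  0 -4  1  0 -4 -4 -4 -3 -3 -2 -1  1  4
 0 -3 -1 -3 -4  8 -2 -4 -2 -4 -3  0 -2 -2 -3  0 -2 -4 -3 -3
-2 -3 -1  0 -1 -2 10 -4  0 -3 -1  1 -2  1  0 -1 -2 -4 -3  2
-1 -2 -4 -4  0 -4 -4  5 -3  2  2 -3 -3 -3 -4 -3 -1  4 -3 -1
-1 -3 -1  1 -4 -2  0 -3  6 -3 -2  0 -1  2  3  0 -1 -3 -3 -2
-2 -2 -4 -3  1 -4 -3  2 -3  5  3 -4 -4 -2 -3 -3 -1  1 -2 -1
-1 -2 -4 -2  0 -3 -1  2 -2  3  7 -2 -3  0 -2 -2 -1  1 -1  0
-1 -2  2  0 -4  0  1 -3  0 -4 -2  7 -2  0 -1  1  0 -3 -4 -2
-1 -4 -1 -1 -4 -2 -2 -3 -1 -4 -3 -2 10 -1 -3 -1 -1 -3 -4 -3
-1 -3  0  2 -4 -2  1 -3  2 -2  0  0 -1  7  1  0 -1 -3 -1 -1
-2 -4 -2  0 -3 -3  0 -4  3 -3 -2 -1 -3  1  7 -1 -1 -3 -3 -1
 1 -1  0 -1 -3  0 -1 -3  0 -3 -2  1 -1  0 -1  5  2 -2 -4 -2
 0 -1 -1 -1 -2 -2 -2 -1 -1 -1 -1  0 -1 -1 -1  2  5  0 -3 -2
 0 -1 -4 -3 -1 -4 -4  4 -3  1  1 -3 -3 -3 -3 -2  0  5 -3 -1
-3 -5 -5 -3  1 -3 -3 -3 -3 -2 -1 -4 -4 -1 -3 -4 -3 -3 15  2
-2 -3 -3 -2  4 -3  2 -1 -2 -1  0 -2 -3 -1 -1 -2 -2 -1  2  8
"""


def blosum50_matrix() -> np.ndarray:
    """The pinned 20x20 BLOSUM50 matrix (int, ACDEFGHIKLMNPQRSTVWY order)."""
    rows = [ln.split() for ln in _BLOSUM50_TEXT.strip().splitlines()]
    m = np.array(rows, dtype=np.int64)
    assert m.shape == (20, 20)
    return m


@dataclass(frozen=True)
class SubstitutionModel:
    """Scoring rules for pairwise substitution events.

    Parameters
    ----------
    aa_scores
        Symmetric 20x20 integer matrix over the standard amino acids,
        BLOSUM50 by default.
    gap_vs_residue
        Score when exactly one of the two sequences has a gap.
    gap_vs_gap
        Score when both sequences have a gap.
    """

    aa_scores: np.ndarray = field(default_factory=blosum50_matrix)
    gap_vs_residue: int = -8
    gap_vs_gap: int = 0

    def __post_init__(self) -> None:
        scores = np.asarray(self.aa_scores)
        if scores.shape != (20, 20):
            raise ValueError("aa_scores must be 20x20")
        if not np.array_equal(scores, scores.T):
            raise ValueError("aa_scores must be symmetric")
        object.__setattr__(self, "aa_scores", scores.astype(np.int64))

    def full_matrix(self) -> np.ndarray:
        """21x21 score matrix over the full alphabet (gap row/column included)."""
        full = np.full((N_SYMBOLS, N_SYMBOLS), self.gap_vs_residue, dtype=np.float64)
        full[:20, :20] = self.aa_scores
        full[GAP_INDEX, GAP_INDEX] = self.gap_vs_gap
        return full


def substitution_score(a: str, b: str, model: SubstitutionModel | None = None) -> int:
    """Score the substitution event between symbols ``a`` and ``b``.

    Exactly one gap scores ``gap_vs_residue``; two gaps score
    ``gap_vs_gap``; otherwise the amino-acid matrix entry is returned.
    Symbols outside the 21-letter alphabet raise ``ValueError``.
    """
    if model is None:
        model = SubstitutionModel()
    ia, ib = symbol_to_index(a), symbol_to_index(b)
    return int(model.full_matrix()[ia, ib])


__all__ = [
    "ALPHABET",
    "AMINO_ACIDS",
    "SubstitutionModel",
    "blosum50_matrix",
    "substitution_score",
]
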