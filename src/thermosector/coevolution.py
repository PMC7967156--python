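"""Residue correlation analysis (RCA) and its eigen-decomposition.

For an alignment of M sequences, every unordered sequence pair (k, l)
defines a *substitution event* at each position i: the BLOSUM50 score of
the two residues found there (with the gap rules of
:mod:`~thermosector.substitution`).  The coevolution of positions i and
j is the Pearson correlation, across all M(M-1)/2 pairs, between the
substitution events at i and at j.  Coevolving position groups show up
as blocks in this correlation matrix and as localized eigenvectors; the
leading mode reflects shared ancestry (phylogenetic signal) and is
excluded from sector analysis, which by default uses modes 2-4.

Two routes compute the matrix:

* :func:`rca_matrix_bruteforce` enumerates sequence pairs directly —
  quadratic in M, used as the independent oracle in tests;
* :func:`rca_matrix` collapses the pair sums onto joint 21x21
  symbol-pair counts per position pair, which is exact and reduces the
  cost from O(N^2 M^2) to O(N^2 A^4 + N M) with A = 21 symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import Alignment, symbol_count_matrix
from .alphabet import N_SYMBOLS
from .substitution import SubstitutionModel

_VAR_TINY = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric N x N matrix of pairwise substitution-event correlations.

    Positions whose substitution events have zero variance (e.g. a
    strictly constant column) are *degenerate*: their correlation is
    undefined, so their whole row and column — diagonal included — are
    set to 0 and flagged in ``degenerate``.
    """

    r: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or self.degenerate.shape != (n,):
            raise ValueError("inconsistent matrix / mask shapes")
        if not np.allclose(self.r, self.r.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(self.r).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_positions(self) -> int:
        return self.r.shape[0]


@dataclass
class EigenSystem:
    """Descending eigenvalues and sign-fixed eigenvectors of an RCA matrix.

    ``eigenvectors[:, k]`` pairs with ``eigenvalues[k]``; each vector's
    sign is fixed so its largest-magnitude component is positive, which
    makes downstream boundary tests and clustering reproducible.  Mode
    indices are 1-based throughout (mode 1 = largest eigenvalue).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    selected_modes: list[int] = field(default_factory=lambda: [2, 3, 4])

    def mode_vector(self, mode: int) -> np.ndarray:
        if not 1 <= mode <= len(self.eigenvalues):
            raise ValueError(f"mode {mode} out of range")
        return self.eigenvectors[:, mode - 1]

    def mode_coordinates(self, modes: list[int] | None = None) -> np.ndarray:
        """N x len(modes) matrix of eigenvector components (columns = modes)."""
        modes = modes or self.selected_modes
        return np.column_stack([self.mode_vector(m) for m in modes])


def _pair_score_vector(codes_col: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Substitution scores for all unordered sequence pairs at one column."""
    m = codes_col.shape[0]
    out = []
    for k in range(m - 1):
        for l in range(k + 1, m):
            out.append(score[codes_col[k], codes_col[l]])
    return np.array(out, dtype=float)


def rca_matrix_bruteforce(aln: Alignment,
                          model: SubstitutionModel | None = None
                          ) -> CorrelationMatrix:
    """Direct pair-enumeration RCA — the oracle route.

    Pearson correlation with population normalization over the
    M(M-1)/2 pair population; self pairs (k = l) are excluded.
    """
    model = model or SubstitutionModel()
    m, n = aln.codes.shape
    if m < 3:
        raise ValueError(f"need at least 3 sequences, got {m}")
    score = model.full_matrix()
    x = np.vstack([_pair_score_vector(aln.codes[:, j], score)
                   for j in range(n)])
    mean = x.mean(axis=1)
    centered = x - mean[:, None]
    var = (centered ** 2).mean(axis=1)
    degenerate = var <= _VAR_TINY
    sd = np.sqrt(np.where(degenerate, 1.0, var))
    r = (centered @ centered.T) / x.shape[1] / np.outer(sd, sd)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(r, degenerate)


def rca_matrix(aln: Alignment, model: SubstitutionModel | None = None,
               row_chunk: int = 16) -> CorrelationMatrix:
    """Count-collapsed RCA, numerically identical to the brute force.

    For positions i, j let T[a, c] count sequences showing symbol a at i
    and c at j.  Sums of products of substitution scores over sequence
    pairs then reduce to quadratic forms in T and the 21x21 score matrix
    S, with the k = l self-pairs subtracted:

        sum_{k<l} X_i X_j = ( sum(T*(S T S^T... )) - diag term ) / 2
    """
    model = model or SubstitutionModel()
    m, n = aln.codes.shape
    if m < 3:
        raise ValueError(f"need at least 3 sequences, got {m}")
    s = model.full_matrix()
    d = np.diag(s)
    n_pairs = m * (m - 1) / 2.0

    counts = symbol_count_matrix(aln).astype(float)  # N x 21
    # sum over pairs of X_i, per position
    sum_x = (np.einsum("ia,ab,ib->i", counts, s, counts) - counts @ d) / 2.0
    mean = sum_x / n_pairs

    # one-hot encoding: F[(i, a), k] = 1 iff sequence k has symbol a at i
    f = np.zeros((n * N_SYMBOLS, m))
    rows = (np.arange(n)[:, None] * N_SYMBOLS + aln.codes.T).ravel()
    cols = np.repeat(np.arange(m)[None, :], n, axis=0).ravel()
    f[rows, cols] = 1.0

    cross = np.empty((n, n))
    gram = f @ f.T  # (N*21) x (N*21); block (i, j) is T_ij
    t4 = gram.reshape(n, N_SYMBOLS, n, N_SYMBOLS)
    for start in range(0, n, row_chunk):
        stop = min(start + row_chunk, n)
        block = np.ascontiguousarray(
            t4[start:stop].transpose(0, 2, 1, 3))  # chunk x N x 21 x 21
        sts = np.matmul(np.matmul(s, block), s)
        quad = np.einsum("xjab,xjab->xj", block, sts)
        self_term = np.einsum("xjab,a,b->xj", block, d, d)
        cross[start:stop] = (quad - self_term) / 2.0

    cov = cross / n_pairs - np.outer(mean, mean)
    var = np.diag(cov).copy()
    degenerate = var <= _VAR_TINY
    sd = np.sqrt(np.where(degenerate, 1.0, var))
    r = cov / np.outer(sd, sd)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(r, degenerate)


def eigendecompose(corr: CorrelationMatrix,
                   selected_modes: list[int] | None = None) -> EigenSystem:
    """Eigen-decompose the RCA matrix (descending, sign-fixed)."""
    r = corr.r
    if not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("matrix is not symmetric within 1e-8")
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    order = np.argsort(w, kind="stable")[::-1]
    w, v = w[order], v[:, order]
    for k in range(v.shape[1]):
        top = np.argmax(np.abs(v[:, k]))
        if v[top, k] < 0:
            v[:, k] = -v[:, k]
    modes = selected_modes or [2, 3, 4]
    n = len(w)
    modes = [m for m in modes if m <= n]
    return EigenSystem(w, v, modes)


def mode_approximation(eig: EigenSystem, modes: list[int]) -> np.ndarray:
    """Low-rank reconstruction  sum_{k in modes} lambda_k v_k v_k^T."""
    if not modes:
        raise ValueError("modes list must not be empty")
    n = len(eig.eigenvalues)
    if any(not 1 <= m <= n for m in modes):
        raise ValueError(f"modes must lie in 1..{n}")
    approx = np.zeros((n, n))
    for m in modes:
        v = eig.mode_vector(m)
        approx += eig.eigenvalues[m - 1] * np.outer(v, v)
    return approx


def write_correlation_tsv(corr: CorrelationMatrix, positions: list[int],
                          path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(corr.r, index=positions, columns=positions).to_csv(
        path, sep="\t", float_format="%.10g", index_label="ref_position")


def write_eigen_tsv(eig: EigenSystem, positions: list[int],
                    values_path: str | Path, vectors_path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame({"mode": np.arange(1, len(eig.eigenvalues) + 1),
                  "eigenvalue": eig.eigenvalues}).to_csv(
        values_path, sep="\t", index=False, float_format="%.10g")
    vec = pd.DataFrame(eig.eigenvectors, index=positions,
                       columns=[f"v{k}" for k in
                                range(1, eig.eigenvectors.shape[1] + 1)])
    vec.to_csv(vectors_path, sep="\t", float_format="%.10g",
               index_label="ref_position")


__all__ = [
    "CorrelationMatrix", "EigenSystem",
    "rca_matrix", "rca_matrix_bruteforce",
    "eigendecompose", "mode_approximation",
    "write_correlation_tsv", "write_eigen_tsv",
]
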