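"""Sector identification: shuffling null, boundary fit, k-means clustering.

Signal positions are separated from noise by comparing eigenvector
components of the real alignment against those obtained after
independently permuting every column (which destroys inter-position
correlation but preserves per-column composition exactly).  A Gaussian
fit to the pooled null components of each selected mode yields a
positional-weight boundary; positions within the boundary in *all*
selected modes carry no significant correlation and are dropped.  The
remaining positions are clustered in eigenvector space (modes 2-4 by
default) with k-means into protein sectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .alignment_io import Alignment
from .coevolution import (CorrelationMatrix, EigenSystem, eigendecompose,
                          rca_matrix)
from .substitution import SubstitutionModel

BACKGROUND = "background"


@dataclass
class NullBoundaries:
    """Per-mode Gaussian boundaries fitted on the shuffling null."""

    per_mode: dict[int, tuple[float, float, float]]  # mode -> (mu, sigma, cutoff)
    n_trials: int = 10
    n_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for mode, (mu, sigma, cutoff) in self.per_mode.items():
            if sigma <= 0:
                raise ValueError(f"mode {mode}: sigma must be positive")
            if abs(cutoff - self.n_sigma * sigma) > 1e-9:
                raise ValueError(f"mode {mode}: cutoff != n_sigma * sigma")


@dataclass
class SectorAssignment:
    """Sector membership of retained positions; everything else is background."""

    sector_of: dict[int, int | str]       # ref position -> sector id or background
    k: int
    coordinates: dict[int, np.ndarray]    # ref position -> mode-space coords
    mean_theta_by_sector: dict[int, float] = field(default_factory=dict)
    contiguity_by_sector: dict[int, float | None] = field(default_factory=dict)

    def members(self, sector: int) -> list[int]:
        return sorted(p for p, s in self.sector_of.items() if s == sector)

    @property
    def sectors(self) -> list[int]:
        return sorted({s for s in self.sector_of.values() if s != BACKGROUND})


def shuffle_columns(aln: Alignment, seed: int) -> Alignment:
    """Independently permute each column; preserves every column multiset."""
    rng = np.random.default_rng(seed)
    codes = aln.codes.copy()
    for j in range(codes.shape[1]):
        rng.shuffle(codes[:, j])
    return Alignment(list(aln.sequence_ids), codes, list(aln.source_columns))


def null_component_distribution(aln: Alignment,
                                model: SubstitutionModel | None = None,
                                modes: list[int] | None = None,
                                n_trials: int = 10,
                                seed: int = 0) -> dict[int, np.ndarray]:
    """Pooled eigenvector components of the selected modes under the null.

    Each trial shuffles every column, recomputes the RCA matrix and its
    eigen-decomposition, and collects the selected-mode components; the
    samples of all trials are pooled per mode (N x n_trials values).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    modes = modes or [2, 3, 4]
    model = model or SubstitutionModel()
    pooled: dict[int, list[np.ndarray]] = {m: [] for m in modes}
    # distinct, deterministic per-trial seeds derived from the base seed
    trial_seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
    for t in range(n_trials):
        shuffled = shuffle_columns(aln, int(trial_seeds[t]))
        eig = eigendecompose(rca_matrix(shuffled, model), modes)
        for m in modes:
            pooled[m].append(eig.mode_vector(m))
    return {m: np.concatenate(v) for m, v in pooled.items()}


def fit_gaussian_boundary(samples: np.ndarray, n_sigma: float
                          ) -> tuple[float, float, float]:
    """Maximum-likelihood normal fit; boundary = n_sigma * sigma around mu."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 20:
        raise ValueError(f"need >= 20 samples, got {samples.size}")
    mu = float(samples.mean())
    sigma = float(samples.std(ddof=0))
    if sigma <= 0:
        raise ValueError("degenerate null: all samples identical")
    return mu, sigma, n_sigma * sigma


def null_boundaries(aln: Alignment, model: SubstitutionModel | None = None,
                    modes: list[int] | None = None, n_trials: int = 10,
                    n_sigma: float = 2.0, seed: int = 0) -> NullBoundaries:
    """Convenience: pooled null distribution + per-mode Gaussian boundary."""
    modes = modes or [2, 3, 4]
    pooled = null_component_distribution(aln, model, modes, n_trials, seed)
    per_mode = {m: fit_gaussian_boundary(pooled[m], n_sigma) for m in modes}
    return NullBoundaries(per_mode, n_trials=n_trials, n_sigma=n_sigma,
                          seed=seed)


def select_significant_positions(eig: EigenSystem,
                                 boundaries: NullBoundaries,
                                 corr: CorrelationMatrix,
                                 positions: list[int] | None = None
                                 ) -> list[int]:
    """Positions whose weight exceeds the boundary in at least one mode.

    This is the complement of the removal rule "all selected-mode
    weights smaller than the boundaries"; degenerate positions are
    always excluded.  ``positions`` supplies the reference numbering
    (defaults to 1..N).
    """
    n = corr.n_positions
    positions = positions or list(range(1, n + 1))
    missing = [m for m in eig.selected_modes if m not in boundaries.per_mode]
    if missing:
        raise ValueError(f"boundaries missing for modes {missing}")
    keep = np.zeros(n, dtype=bool)
    for m in eig.selected_modes:
        mu, _sigma, cutoff = boundaries.per_mode[m]
        keep |= np.abs(eig.mode_vector(m) - mu) > cutoff
    keep &= ~corr.degenerate
    return [positions[i] for i in np.flatnonzero(keep)]


def cluster_sectors(eig: EigenSystem, positions: list[int], k: int,
                    seed: int = 0, n_restarts: int = 100,
                    all_positions: list[int] | None = None,
                    weight_modes: bool = False) -> SectorAssignment:
    """K-means the retained positions in selected-mode eigenvector space.

    Sector ids are relabeled deterministically: 1..k by descending
    cluster size, ties broken by the smallest member position.  With
    ``weight_modes`` the coordinates are scaled by sqrt(lambda_k).
    """
    n = len(eig.eigenvalues)
    all_positions = all_positions or list(range(1, n + 1))
    pos_sorted = sorted(positions)
    if len(pos_sorted) < k:
        raise ValueError(
            f"{len(pos_sorted)} retained positions < k={k}; use a smaller k")
    index_of = {p: i for i, p in enumerate(all_positions)}
    coords_all = eig.mode_coordinates()
    if weight_modes:
        scale = np.sqrt(np.maximum(
            [eig.eigenvalues[m - 1] for m in eig.selected_modes], 0.0))
        coords_all = coords_all * scale
    x = np.vstack([coords_all[index_of[p]] for p in pos_sorted])
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    raw = km.fit_predict(x)
    # deterministic relabeling: size desc, then smallest member position
    order = sorted(range(k), key=lambda c: (-(raw == c).sum(),
                                            min(p for p, lab in
                                                zip(pos_sorted, raw)
                                                if lab == c)))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    sector_of: dict[int, int | str] = {p: BACKGROUND for p in all_positions}
    for p, lab in zip(pos_sorted, raw):
        sector_of[p] = relabel[lab]
    coordinates = {p: coords_all[index_of[p]].copy() for p in all_positions}
    return SectorAssignment(sector_of, k, coordinates)


def sector_contiguity(assignment: SectorAssignment
                      ) -> dict[int, float | None]:
    """Median gap between consecutive member positions, per sector.

    1.0 means a perfectly contiguous run in the primary sequence;
    singleton sectors have no defined gap and report None.  Advisory
    only — never used to exclude a sector automatically.
    """
    scores: dict[int, float | None] = {}
    for s in assignment.sectors:
        members = assignment.members(s)
        if len(members) < 2:
            scores[s] = None
        else:
            gaps = np.diff(members)
            scores[s] = float(np.median(gaps))
    assignment.contiguity_by_sector = scores
    return scores


def write_boundaries_tsv(boundaries: NullBoundaries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mode\tmu\tsigma\tcutoff\tn_trials\tn_sigma\n")
        for m in sorted(boundaries.per_mode):
            mu, sigma, cutoff = boundaries.per_mode[m]
            fh.write(f"{m}\t{mu:.10g}\t{sigma:.10g}\t{cutoff:.10g}\t"
                     f"{boundaries.n_trials}\t{boundaries.n_sigma:g}\n")


def write_sectors_tsv(assignment: SectorAssignment, path: str | Path,
                      ref_residues: dict[int, str] | None = None) -> None:
    modes_header = "\t".join(f"coord{i + 1}" for i in
                             range(len(next(iter(assignment.coordinates.values())))))
    with open(path, "w") as fh:
        fh.write(f"ref_position\tref_residue\tsector\t{modes_header}\n")
        for p in sorted(assignment.sector_of):
            res = (ref_residues or {}).get(p, "?")
            coords = "\t".join(f"{c:.10g}" for c in assignment.coordinates[p])
            fh.write(f"{p}\t{res}\t{assignment.sector_of[p]}\t{coords}\n")


__all__ = [
    "BACKGROUND", "NullBoundaries", "SectorAssignment",
    "shuffle_columns", "null_component_distribution",
    "fit_gaussian_boundary", "null_boundaries",
    "select_significant_positions", "cluster_sectors", "sector_contiguity",
    "write_boundaries_tsv", "write_sectors_tsv",
]
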