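"""Thermophile/mesophile sequence-profile divergence via relative entropy.

Each reference position gets two 21-component relative-entropy vectors —
one from the thermophilic sub-alignment, one from the mesophilic — whose
component for symbol *a* is the binary Kullback–Leibler divergence
between the observed frequency f of *a* at that position and its
background frequency q:

    D_a = f ln(f / q) + (1 - f) ln((1 - f) / (1 - q))

(the large-M approximation of the log-binomial enrichment probability;
being sample-size-free, it compares sub-alignments of very different
depth on an equal footing).  The *relative entropy angle*

    theta = arccos( D_thermo . D_meso / (|D_thermo| |D_meso|) )

measures how divergent the amino-acid usage of the two thermal classes
is at the position: theta near 0 means the classes deviate from
background in the same way, theta near pi/2 means they diverge in
unrelated directions.  High-theta positions are the thermostability
design candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_io import (Alignment, FrequencyProfile, LabelTable,
                           MESOPHILIC, MIN_SUBSET_SIZE, ReferenceMap,
                           THERMOPHILIC, column_frequencies, subset_by_label,
                           symbol_count_matrix)
from .alphabet import ALPHABET, GAP_INDEX, N_SYMBOLS

DEFAULT_Q_FLOOR = 1e-4


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background symbol frequencies q (20 aa + gap), floored and normalized."""

    q: np.ndarray
    q_floor: float = DEFAULT_Q_FLOOR

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (N_SYMBOLS,):
            raise ValueError("q must have 21 components")
        # renormalization after flooring may pull entries marginally
        # below the floor (factor >= 1/(1 + 21*q_floor))
        if (q < self.q_floor * (1 - 25 * self.q_floor) - 1e-15).any():
            raise ValueError("q entries must be >= q_floor")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("q must sum to 1")
        object.__setattr__(self, "q", q)


@dataclass
class EntropyProfiles:
    """Per-position D vectors and angle for the two thermal classes."""

    positions: list[int]
    d_thermo: np.ndarray        # N x 21
    d_meso: np.ndarray          # N x 21
    theta: np.ndarray           # N
    support_thermo: int
    support_meso: int
    freqs_thermo: np.ndarray | None = None   # N x 21 raw frequencies
    freqs_meso: np.ndarray | None = None

    def theta_of(self, position: int) -> float:
        return float(self.theta[self.positions.index(position)])


def background_frequencies(aln: Alignment,
                           q_floor: float = DEFAULT_Q_FLOOR
                           ) -> BackgroundFrequencies:
    """Background composition of the full (projected) alignment.

    q_gap is the overall gap fraction; the 20 amino-acid frequencies are
    taken over non-gap cells and scaled by (1 - q_gap), i.e. the overall
    cell fractions.  Entries are then floored at ``q_floor`` and the
    vector renormalized, so no symbol has zero background mass.
    """
    counts = symbol_count_matrix(aln).sum(axis=0).astype(float)
    total = counts.sum()
    if total == 0 or counts[GAP_INDEX] == total:
        raise ValueError("alignment is entirely gaps")
    q = counts / total
    q = np.maximum(q, q_floor)
    q = q / q.sum()
    return BackgroundFrequencies(q, q_floor)


def relative_entropy_vector(freqs: FrequencyProfile,
                            background: BackgroundFrequencies) -> np.ndarray:
    """21-component binary KL divergence of f against the background q.

    Natural logarithm; the 0 ln 0 = 0 convention makes the f = 0 and
    f = 1 endpoints exact.  Every component is >= 0.
    """
    f = freqs.freqs
    q = background.q
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(f > 0, f * np.log(f / q), 0.0)
        term2 = np.where(f < 1, (1 - f) * np.log((1 - f) / (1 - q)), 0.0)
    d = term1 + term2
    # binary KL is non-negative; clip away -0.0 and rounding dust
    return np.maximum(d, 0.0)


def exact_relative_entropy_vector(freqs: FrequencyProfile,
                                  background: BackgroundFrequencies
                                  ) -> np.ndarray:
    """Exact log-binomial form, -(1/M) ln P(count | q), for comparison only.

    Unlike the binary-KL approximation this depends on the sub-alignment
    depth M, so it is not used for the angle by default.
    """
    from scipy.stats import binom

    m = freqs.support
    f = freqs.freqs
    q = background.q
    k = np.rint(f * m).astype(int)
    logp = binom.logpmf(k, m, q)
    return -logp / m


def entropy_angle(d_thermo: np.ndarray, d_meso: np.ndarray) -> float:
    """Angle in [0, pi/2] between two non-negative D vectors.

    A zero-norm vector means the profile sits exactly at background, i.e.
    no divergence evidence: the angle is defined as 0 so such positions
    never rank as design candidates.
    """
    a = np.asarray(d_thermo, dtype=float)
    b = np.asarray(d_meso, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    if np.array_equal(a, b):
        return 0.0  # identical profiles are exactly parallel
    cos = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return float(np.arccos(cos))


def theta_profile(aln: Alignment, labels: LabelTable, refmap: ReferenceMap,
                  q_floor: float = DEFAULT_Q_FLOOR,
                  min_subset_size: int = MIN_SUBSET_SIZE,
                  exclude_ids: set[str] | None = None,
                  background: BackgroundFrequencies | None = None
                  ) -> EntropyProfiles:
    """Relative-entropy vectors and angle for every reference position.

    The background q is shared by both profiles and computed from the
    full projected alignment (unknown-label sequences included) unless
    an explicit ``background`` table is supplied.  The reference/target
    sequence can be excluded from the labeled subsets via
    ``exclude_ids``.
    """
    exclude = set(exclude_ids or ())
    if background is None:
        background = background_frequencies(aln, q_floor)
    thermo = subset_by_label(aln, labels, THERMOPHILIC, min_subset_size,
                             exclude_ids=exclude)
    meso = subset_by_label(aln, labels, MESOPHILIC, min_subset_size,
                           exclude_ids=exclude)
    positions = list(refmap.ref_positions)
    n = len(positions)
    d_t = np.zeros((n, N_SYMBOLS))
    d_m = np.zeros((n, N_SYMBOLS))
    f_t = np.zeros((n, N_SYMBOLS))
    f_m = np.zeros((n, N_SYMBOLS))
    theta = np.zeros(n)
    for i, p in enumerate(positions):
        ft = column_frequencies(thermo, p, refmap)
        fm = column_frequencies(meso, p, refmap)
        d_t[i] = relative_entropy_vector(ft, background)
        d_m[i] = relative_entropy_vector(fm, background)
        f_t[i], f_m[i] = ft.freqs, fm.freqs
        theta[i] = entropy_angle(d_t[i], d_m[i])
    return EntropyProfiles(positions, d_t, d_m, theta,
                           thermo.n_sequences, meso.n_sequences,
                           freqs_thermo=f_t, freqs_meso=f_m)


def mean_theta(profiles: EntropyProfiles, positions: list[int]) -> float:
    """Arithmetic mean of theta over a position subset."""
    if not positions:
        raise ValueError("position subset is empty")
    index_of = {p: i for i, p in enumerate(profiles.positions)}
    missing = [p for p in positions if p not in index_of]
    if missing:
        raise ValueError(f"positions not in profile: {missing}")
    return float(np.mean([profiles.theta[index_of[p]] for p in positions]))


def write_theta_tsv(profiles: EntropyProfiles, path: str | Path,
                    ref_residues: dict[int, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("ref_position\tref_residue\ttheta\tsupport_thermo\t"
                 "support_meso\ttop_thermo_aa\ttop_meso_aa\n")
        for i, p in enumerate(profiles.positions):
            res = (ref_residues or {}).get(p, "?")
            top_t = ALPHABET[int(np.argmax(profiles.freqs_thermo[i]))]
            top_m = ALPHABET[int(np.argmax(profiles.freqs_meso[i]))]
            fh.write(f"{p}\t{res}\t{profiles.theta[i]:.10g}\t"
                     f"{profiles.support_thermo}\t{profiles.support_meso}\t"
                     f"{top_t}\t{top_m}\n")


__all__ = [
    "BackgroundFrequencies", "EntropyProfiles", "DEFAULT_Q_FLOOR",
    "background_frequencies", "relative_entropy_vector",
    "exact_relative_entropy_vector", "entropy_angle", "theta_profile",
    "mean_theta", "write_theta_tsv",
]
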