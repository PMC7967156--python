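from __future__ import annotations

import numpy as np
import pytest

from thermosector.alignment_io import Alignment
from thermosector.alphabet import SYMBOL_INDEX


def alignment_from_rows(rows: list[str], ids: list[str] | None = None) -> Alignment:
    """Build an Alignment from literal row strings (test helper)."""
    ids = ids or [f"s{i + 1}" for i in range(len(rows))]
    codes = np.array([[SYMBOL_INDEX[ch] for ch in row] for row in rows],
                     dtype=np.uint8)
    return Alignment(ids, codes)


def random_alignment(rng: np.random.Generator, m: int, n: int,
                     gap_fraction: float = 0.0) -> Alignment:
    codes = rng.integers(0, 20, size=(m, n)).astype(np.uint8)
    if gap_fraction > 0:
        mask = rng.random((m, n)) < gap_fraction
        codes[mask] = SYMBOL_INDEX["-"]
    return Alignment([f"s{i}" for i in range(m)], codes)


@pytest.fixture(scope="session")
def default_family():
    """One default synthetic family (seed 0) shared across tests."""
    from thermosector.synthetic_msa import generate_family

    return generate_family(seed=0)


@pytest.fixture(scope="session")
def ten_seed_runs():
    """Fitted results + planted truth on the default family, seeds 0..9."""
    from thermosector.model import ThermostabilityDesign
    from thermosector.synthetic_msa import generate_family

    runs = []
    for seed in range(10):
        aln, labels, refmap, truth = generate_family(seed=seed)
        res = ThermostabilityDesign(aln, labels, "REF", k=3).fit(seed=seed)
        runs.append((res, truth))
    return runs


@pytest.fixture(scope="session")
def fitted_default(default_family):
    """Design results on the default family, k matched to planted sectors."""
    from thermosector.model import ThermostabilityDesign

    aln, labels, refmap, truth = default_family
    res = ThermostabilityDesign(aln, labels, "REF", k=3).fit(seed=0)
    return res, truth
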