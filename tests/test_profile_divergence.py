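from __future__ import annotations

import numpy as np
import pytest

from thermosector.alignment_io import (FrequencyProfile, LabelTable,
                                       project_to_reference)
from thermosector.alphabet import GAP_INDEX, N_SYMBOLS, SYMBOL_INDEX
from thermosector.profile_divergence import (BackgroundFrequencies,
                                             background_frequencies,
                                             entropy_angle,
                                             exact_relative_entropy_vector,
                                             mean_theta,
                                             relative_entropy_vector,
                                             theta_profile)

from conftest import alignment_from_rows


def _profile(freq_of: dict[str, float], support: int = 100,
             position: int = 1) -> FrequencyProfile:
    f = np.zeros(N_SYMBOLS)
    for sym, frac in freq_of.items():
        f[SYMBOL_INDEX[sym]] = frac
    return FrequencyProfile(position, f, support)


def _background(q_of: dict[str, float],
                floor: float = 1e-4) -> BackgroundFrequencies:
    q = np.full(N_SYMBOLS, floor)
    for sym, frac in q_of.items():
        q[SYMBOL_INDEX[sym]] = frac
    q = q / q.sum()
    return BackgroundFrequencies(q, floor)


class TestBackgroundFrequencies:
    def test_two_symbol_alignment(self):
        aln = alignment_from_rows(["AC", "CA", "AC", "CA"])
        bg = background_frequencies(aln)
        a, c = bg.q[SYMBOL_INDEX["A"]], bg.q[SYMBOL_INDEX["C"]]
        assert a == pytest.approx(c)
        assert a == pytest.approx(0.5, abs=0.01)  # minus flooring mass
        assert bg.q[GAP_INDEX] == pytest.approx(bg.q_floor, rel=0.05)
        assert bg.q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_gap_fraction_is_q_gap(self):
        # 4 rows x 2 cols, 2 of 8 cells are gaps -> q_gap = 0.25
        aln = alignment_from_rows(["A-", "AC", "-C", "AC"])
        bg = background_frequencies(aln)
        assert bg.q[GAP_INDEX] == pytest.approx(0.25, abs=0.01)
        assert bg.q[:20].sum() == pytest.approx(0.75, abs=0.01)

    def test_hand_counted_composition(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKL", "MNPQRSTVWY",
                "AAAAAAAAAA", "CCCCC-----", "WWWWWWWWW-",
                "ACACACACAC", "DDDDDDDDDD"]
        aln = alignment_from_rows(rows)
        counts = np.zeros(N_SYMBOLS)
        for row in rows:
            for ch in row:
                counts[SYMBOL_INDEX[ch]] += 1
        expected = counts / counts.sum()
        bg = background_frequencies(aln, q_floor=0.0)
        np.testing.assert_allclose(bg.q, expected, atol=1e-12)

    def test_all_gap_alignment_rejected(self):
        aln = alignment_from_rows(["--", "--"])
        with pytest.raises(ValueError, match="gaps"):
            background_frequencies(aln)


class TestRelativeEntropyVector:
    def test_zero_at_background(self):
        bg = _background({"A": 0.5, "C": 0.5})
        prof = FrequencyProfile(1, bg.q.copy(), 10)
        np.testing.assert_allclose(relative_entropy_vector(prof, bg), 0.0,
                                   atol=1e-12)

    def test_fixed_frequency_endpoints(self):
        q = np.full(N_SYMBOLS, 0.05)
        q[GAP_INDEX] = 1e-6
        bg = BackgroundFrequencies(q / q.sum(), 1e-6)
        # f = 1 against q = 0.05: D = ln(1/0.05) = ln 20
        prof = _profile({"A": 1.0})
        d = relative_entropy_vector(prof, bg)
        qa = bg.q[SYMBOL_INDEX["A"]]
        assert d[SYMBOL_INDEX["A"]] == pytest.approx(np.log(1 / qa), abs=1e-12)
        assert d[SYMBOL_INDEX["A"]] == pytest.approx(np.log(20), abs=1e-6)
        # f = 0 against q = 0.05: D = ln(1 / 0.95)
        qc = bg.q[SYMBOL_INDEX["C"]]
        assert d[SYMBOL_INDEX["C"]] == pytest.approx(np.log(1 / (1 - qc)),
                                                     abs=1e-12)
        assert d[SYMBOL_INDEX["C"]] == pytest.approx(np.log(1 / 0.95),
                                                     abs=1e-6)

    def test_nonnegative_over_random_profiles(self):
        rng = np.random.default_rng(51)
        for _ in range(50):
            f = rng.dirichlet(np.ones(N_SYMBOLS))
            q = rng.dirichlet(np.full(N_SYMBOLS, 2.0))
            q = np.maximum(q, 1e-4); q /= q.sum()
            prof = FrequencyProfile(1, f, 10)
            d = relative_entropy_vector(prof, BackgroundFrequencies(q))
            assert (d >= 0).all()

    def test_exact_form_tracks_approximation(self):
        # the log-binomial form divided by M approaches the binary KL
        bg = _background({"A": 0.3, "C": 0.3, "D": 0.4})
        prof = _profile({"A": 0.6, "C": 0.2, "D": 0.2}, support=5000)
        approx = relative_entropy_vector(prof, bg)
        exact = exact_relative_entropy_vector(prof, bg)
        ia = SYMBOL_INDEX["A"]
        assert exact[ia] == pytest.approx(approx[ia], rel=0.05)


class TestEntropyAngle:
    def test_parallel_vectors(self):
        v = np.linspace(0.1, 2.0, N_SYMBOLS)
        assert entropy_angle(v, v) == 0.0
        assert entropy_angle(v, 3.7 * v) == pytest.approx(0.0, abs=1e-7)

    def test_disjoint_support_orthogonal(self):
        a = np.zeros(N_SYMBOLS); a[SYMBOL_INDEX["K"]] = 1.2
        b = np.zeros(N_SYMBOLS); b[SYMBOL_INDEX["S"]] = 0.4
        assert entropy_angle(a, b) == pytest.approx(np.pi / 2)

    def test_direct_arithmetic_oracle(self):
        a = np.full(N_SYMBOLS, 0.05); a[0] = 3.0
        b = np.full(N_SYMBOLS, 0.05); b[1] = 3.0
        expected = np.arccos(float(a @ b) /
                             (np.linalg.norm(a) * np.linalg.norm(b)))
        assert entropy_angle(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(52)
        for _ in range(100):
            a = rng.random(N_SYMBOLS)
            b = rng.random(N_SYMBOLS)
            t1, t2 = entropy_angle(a, b), entropy_angle(b, a)
            assert t1 == t2
            assert 0.0 <= t1 <= np.pi / 2 + 1e-12

    def test_zero_norm_defined_as_zero(self):
        assert entropy_angle(np.zeros(N_SYMBOLS), np.ones(N_SYMBOLS)) == 0.0


class TestThetaProfile:
    def _family(self, thermo_rows, meso_rows):
        rows = ["A" * len(thermo_rows[0])] + thermo_rows + meso_rows
        ids = (["REF"] + [f"t{i}" for i in range(len(thermo_rows))]
               + [f"m{i}" for i in range(len(meso_rows))])
        aln = alignment_from_rows(rows, ids)
        labels = LabelTable({
            "REF": "unknown",
            **{f"t{i}": "thermophilic" for i in range(len(thermo_rows))},
            **{f"m{i}": "mesophilic" for i in range(len(meso_rows))},
        })
        proj, refmap = project_to_reference(aln, "REF")
        return proj, labels, refmap

    def test_identical_subsets_give_zero_theta(self):
        block = ["ACDEF", "GHIKL", "MNPQR", "STVWY", "ACDEF"]
        proj, labels, refmap = self._family(block, list(block))
        prof = theta_profile(proj, labels, refmap, exclude_ids={"REF"})
        np.testing.assert_allclose(prof.theta, 0.0, atol=1e-12)

    def test_log_base_invariance(self):
        """Scaling both D vectors by a common factor (= changing the log
        base) leaves every angle unchanged."""
        rng = np.random.default_rng(53)
        from conftest import random_alignment
        aln = random_alignment(rng, 30, 6)
        labels = LabelTable({f"s{i}": ("thermophilic" if i < 15
                                       else "mesophilic")
                             for i in range(30)})
        proj, refmap = project_to_reference(aln, "s0")
        prof = theta_profile(proj, labels, refmap)
        scale = 1.0 / np.log(2.0)  # nat -> bit conversion
        from thermosector.profile_divergence import entropy_angle
        for i in range(len(prof.positions)):
            t = entropy_angle(scale * prof.d_thermo[i],
                              scale * prof.d_meso[i])
            assert t == pytest.approx(prof.theta[i], abs=1e-12)

    def test_planted_sites_rank_top(self, fitted_default):
        res, truth = fitted_default
        order = np.argsort(-res.profiles.theta)
        top = {res.profiles.positions[i]
               for i in order[:len(truth.divergent_sites) + 2]}
        assert set(truth.divergent_sites) <= top

    def test_small_subset_rejected(self):
        proj, labels, refmap = self._family(["ACDEF"] * 3, ["GHIKL"] * 8)
        with pytest.raises(ValueError, match="at least"):
            theta_profile(proj, labels, refmap, exclude_ids={"REF"})


class TestMeanTheta:
    def _profiles(self, thetas):
        n = len(thetas)
        from thermosector.profile_divergence import EntropyProfiles
        return EntropyProfiles(list(range(1, n + 1)),
                               np.zeros((n, N_SYMBOLS)),
                               np.zeros((n, N_SYMBOLS)),
                               np.asarray(thetas, dtype=float), 10, 10)

    def test_singleton_and_pair(self):
        prof = self._profiles([0.6, 0.2, 0.9])
        assert mean_theta(prof, [3]) == pytest.approx(0.9)
        assert mean_theta(prof, [1, 2]) == pytest.approx(0.4)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            mean_theta(self._profiles([0.1]), [])

    def test_planted_sector_mean_exceeds_background(self, ten_seed_runs):
        wins = 0
        for res, truth in ten_seed_runs:
            div = sorted(truth.divergent_sites)
            rest = [p for p in res.profiles.positions if p not in div]
            wins += (mean_theta(res.profiles, div)
                     > mean_theta(res.profiles, rest))
        assert wins == 10
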