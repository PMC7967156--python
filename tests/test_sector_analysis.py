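from __future__ import annotations

import numpy as np
import pytest

from thermosector.coevolution import eigendecompose, rca_matrix
from thermosector.sector_analysis import (cluster_sectors,
                                          fit_gaussian_boundary,
                                          null_boundaries,
                                          null_component_distribution,
                                          sector_contiguity,
                                          select_significant_positions,
                                          shuffle_columns, NullBoundaries,
                                          SectorAssignment)
from thermosector.alignment_io import symbol_count_matrix

from conftest import alignment_from_rows, random_alignment


class TestShuffleColumns:
    def test_uniform_column_unchanged(self):
        aln = alignment_from_rows(["AC", "AD", "AE"])
        out = shuffle_columns(aln, seed=0)
        assert all(out.codes[i, 0] == aln.codes[i, 0] for i in range(3))

    def test_column_multisets_preserved(self):
        rng = np.random.default_rng(31)
        aln = random_alignment(rng, 20, 10, gap_fraction=0.2)
        out = shuffle_columns(aln, seed=5)
        np.testing.assert_array_equal(symbol_count_matrix(aln),
                                      symbol_count_matrix(out))

    def test_seed_determinism(self):
        rng = np.random.default_rng(32)
        aln = random_alignment(rng, 20, 10)
        a = shuffle_columns(aln, seed=9)
        b = shuffle_columns(aln, seed=9)
        c = shuffle_columns(aln, seed=10)
        np.testing.assert_array_equal(a.codes, b.codes)
        assert not np.array_equal(a.codes, c.codes)


class TestNullDistribution:
    def test_sample_counts(self):
        rng = np.random.default_rng(33)
        aln = random_alignment(rng, 10, 8)
        pooled = null_component_distribution(aln, n_trials=1, seed=0)
        assert set(pooled) == {2, 3, 4}
        assert all(len(v) == 8 for v in pooled.values())
        pooled3 = null_component_distribution(aln, n_trials=3, seed=0)
        assert all(len(v) == 24 for v in pooled3.values())

    def test_pooled_mean_near_zero(self, default_family):
        aln = default_family[0]
        pooled = null_component_distribution(aln, n_trials=10, seed=0)
        for mode, samples in pooled.items():
            tol = 3 * samples.std() / np.sqrt(samples.size)
            assert abs(samples.mean()) < tol, mode

    def test_bitwise_determinism(self):
        rng = np.random.default_rng(34)
        aln = random_alignment(rng, 12, 6)
        a = null_component_distribution(aln, n_trials=2, seed=7)
        b = null_component_distribution(aln, n_trials=2, seed=7)
        for mode in a:
            np.testing.assert_array_equal(a[mode], b[mode])


class TestGaussianBoundary:
    def test_standard_normal_monte_carlo(self):
        rng = np.random.default_rng(35)
        samples = rng.normal(0.0, 1.0, size=10000)
        mu, sigma, cutoff = fit_gaussian_boundary(samples, n_sigma=2.0)
        assert sigma == pytest.approx(1.0, abs=0.05)
        assert cutoff == pytest.approx(2.0, abs=0.1)

    def test_zero_sigma_multiplier(self):
        rng = np.random.default_rng(36)
        _, _, cutoff = fit_gaussian_boundary(rng.normal(size=100), n_sigma=0.0)
        assert cutoff == 0.0

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gaussian_boundary(np.ones(50), n_sigma=2.0)
        with pytest.raises(ValueError, match=">= 20"):
            fit_gaussian_boundary(np.arange(5.0), n_sigma=2.0)


class TestSelection:
    def _eig_corr(self, seed=41):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 15, 8)
        corr = rca_matrix(aln)
        return eigendecompose(corr), corr

    def test_zero_cutoff_retains_all(self):
        eig, corr = self._eig_corr()
        bounds = NullBoundaries({m: (0.5, 1e-9, 0.0) for m in (2, 3, 4)},
                                n_sigma=0.0)
        kept = select_significant_positions(eig, bounds, corr)
        expected = [p for p in range(1, 9) if not corr.degenerate[p - 1]]
        assert kept == expected

    def test_infinite_cutoff_retains_none(self):
        eig, corr = self._eig_corr()
        bounds = NullBoundaries({m: (0.0, 1.0, 1e9) for m in (2, 3, 4)},
                                n_sigma=1e9)
        assert select_significant_positions(eig, bounds, corr) == []

    def test_planted_positions_retained(self, ten_seed_runs):
        """Planted sector positions pass the boundary, background mostly
        does not (10 seeds)."""
        ok_planted = ok_background = 0
        for res, truth in ten_seed_runs:
            planted = set().union(*map(set, truth.sector_members.values()))
            background = set(range(1, 61)) - planted
            retained = set(res.retained_positions)
            ok_planted += len(planted & retained) / len(planted) >= 0.8
            ok_background += len(background & retained) / len(background) <= 0.2
        assert ok_planted >= 9
        assert ok_background >= 9


class TestClustering:
    def test_separable_clouds_recovered_exactly(self):
        rng = np.random.default_rng(42)
        centers = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 10], [-10, 0, 0]])
        coords = np.vstack([c + 0.1 * rng.normal(size=(5, 3))
                            for c in centers])
        # wrap the coordinates in a synthetic eigen system
        from thermosector.coevolution import EigenSystem
        n = 20
        vecs = np.zeros((n, n))
        vecs[:, 1:4] = coords  # modes 2..4
        eig = EigenSystem(np.arange(n, 0, -1, dtype=float), vecs)
        assignment = cluster_sectors(eig, list(range(1, 21)), k=4, seed=0)
        groups = [frozenset(assignment.members(s)) for s in assignment.sectors]
        truth = [frozenset(range(5 * i + 1, 5 * i + 6)) for i in range(4)]
        assert set(groups) == set(truth)

    def test_k_one_puts_all_in_one_sector(self):
        eig = eigendecompose(rca_matrix(
            random_alignment(np.random.default_rng(43), 12, 6)))
        assignment = cluster_sectors(eig, [1, 3, 5], k=1, seed=0)
        assert assignment.members(1) == [1, 3, 5]

    def test_too_few_positions_rejected(self):
        eig = eigendecompose(rca_matrix(
            random_alignment(np.random.default_rng(44), 12, 6)))
        with pytest.raises(ValueError, match="smaller k"):
            cluster_sectors(eig, [1, 2], k=3, seed=0)

    def test_input_order_invariance_and_reproducibility(self, fitted_default):
        res, _truth = fitted_default
        a = cluster_sectors(res.eig, res.retained_positions, k=3, seed=0)
        b = cluster_sectors(res.eig, res.retained_positions[::-1], k=3, seed=0)
        assert a.sector_of == b.sector_of
        c = cluster_sectors(res.eig, res.retained_positions, k=3, seed=0)
        assert a.sector_of == c.sector_of

    def test_two_planted_sectors_ari(self):
        """k=2 on a two-sector family recovers the planted split."""
        from sklearn.metrics import adjusted_rand_score
        from thermosector.model import ThermostabilityDesign
        from thermosector.synthetic_msa import (GeneratorConfig, SectorSpec,
                                                generate_family)

        specs = (SectorSpec((6, 7, 8, 9, 10, 11, 13, 14, 15, 16)),
                 SectorSpec((41, 42, 43, 44, 45, 46, 48, 49)))
        cfg = GeneratorConfig(sector_specs=specs, divergent_sites=())
        good = 0
        for seed in range(10):
            aln, labels, refmap, truth = generate_family(cfg, seed=seed)
            stats = aln.take_rows(range(1, aln.n_sequences),
                                  aln.sequence_ids[1:])
            corr = rca_matrix(stats)
            # two planted sectors -> two signal modes beyond the lineage mode
            eig = eigendecompose(corr, [2, 3])
            bounds = null_boundaries(stats, modes=[2, 3], n_trials=3,
                                     seed=seed)
            kept = select_significant_positions(eig, bounds, corr)
            if len(kept) < 2:
                continue
            assignment = cluster_sectors(eig, kept, k=2, seed=seed)
            planted = {p: g for g, mem in truth.sector_members.items()
                       for p in mem}
            pred, true = [], []
            for p in range(1, 61):
                true.append(planted.get(p, 0))
                s = assignment.sector_of[p]
                pred.append(0 if s == "background" else int(s))
            good += adjusted_rand_score(true, pred) >= 0.8
        assert good >= 9


class TestContiguity:
    @pytest.mark.parametrize("members,expected", [
        ([10, 11, 12, 13], 1.0),
        ([10, 50, 90], 40.0),
        # gaps {35, 24, 1, 38, 1, 1, 65} -> median 24
        ([41, 76, 100, 101, 139, 140, 141, 206], 24.0),
    ])
    def test_median_gap(self, members, expected):
        assignment = SectorAssignment(
            {p: 1 for p in members}, 1,
            {p: np.zeros(3) for p in members})
        assert sector_contiguity(assignment)[1] == expected

    def test_singleton_undefined(self):
        assignment = SectorAssignment({7: 1}, 1, {7: np.zeros(3)})
        assert sector_contiguity(assignment)[1] is None
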