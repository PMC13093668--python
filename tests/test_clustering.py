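"""Free-energy curves, barrier cutting, PCA and density clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metastable import (DensityClustering, assign_by_thresholds,
                        find_minima_and_barriers, free_energy_1d, pca_reduce)
from metastable.clustering import FreeEnergyCurve


def minima_barriers_oracle(dG, min_depth):
    """Exhaustive O(n^2) reference for barrier-cut state counting.

    Works directly on candidate cut sets: start from the full
    alternating minima/maxima decomposition (found by pairwise value
    comparison of de-duplicated runs) and repeatedly delete, by a full
    rescan, the leftmost lowest barrier below the depth floor together
    with its shallower minimum (right one on ties).
    """
    d = [float(v) for v in dG]
    # de-duplicate consecutive equal values
    runs = [0] + [i for i in range(1, len(d)) if d[i] != d[i - 1]]
    mins, maxs = [], []
    for k, i in enumerate(runs):
        prev = d[runs[k - 1]] if k > 0 else np.inf
        nxt = d[runs[k + 1]] if k + 1 < len(runs) else np.inf
        if d[i] < prev and d[i] < nxt:
            mins.append(i)
        elif d[i] > prev and d[i] > nxt:
            maxs.append(i)
    if len(runs) == 1:
        mins = [runs[0]]
    while maxs:
        heights = [d[b] - max(d[mins[k]], d[mins[k + 1]])
                   for k, b in enumerate(maxs)]
        k = int(np.argmin(heights))
        if heights[k] >= min_depth:
            break
        hi = k + 1 if d[mins[k + 1]] >= d[mins[k]] else k
        del maxs[k], mins[hi]
    return len(mins), [d[b] - max(d[mins[k]], d[mins[k + 1]])
                       for k, b in enumerate(maxs)]


class TestFreeEnergy:
    def test_uniform_samples_give_flat_curve(self):
        rng = np.random.default_rng(0)
        curve = free_energy_1d(rng.uniform(0, 1, 200_000), 20)
        assert np.nanmax(curve.dG) < 0.1

    def test_gaussian_samples_give_quadratic_curve(self):
        rng = np.random.default_rng(1)
        curve = free_energy_1d(rng.standard_normal(500_000), 41)
        sel = np.abs(curve.bin_centers) < 1.5
        np.testing.assert_allclose(curve.dG[sel],
                                   curve.bin_centers[sel] ** 2 / 2,
                                   atol=0.15)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10_000)
        c1 = free_energy_1d(x, 25)
        c2 = free_energy_1d(x + 100.0, 25)
        np.testing.assert_allclose(c2.bin_centers - 100.0, c1.bin_centers,
                                   atol=1e-9)
        np.testing.assert_allclose(c2.dG, c1.dG, equal_nan=True)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            free_energy_1d(np.array([]), 10)

    def test_low_count_bins_undefined_not_zero(self):
        x = np.concatenate([np.zeros(100), [10.0]])
        curve = free_energy_1d(x, 11, min_count=2)
        assert np.isnan(curve.dG[-1]) and curve.counts[-1] == 1


class TestMinimaBarriers:
    def test_monotone_curve_single_minimum(self):
        curve = FreeEnergyCurve(np.arange(5.), np.arange(5.), np.ones(5))
        mb = find_minima_and_barriers(curve)
        assert mb.n_states == 1 and len(mb.barriers) == 0

    def test_w_shaped_curve(self):
        curve = FreeEnergyCurve(np.arange(5.),
                                np.array([0., 2., 0., 2., 0.]), np.ones(5))
        mb = find_minima_and_barriers(curve, min_depth=1.0)
        assert mb.n_states == 3
        np.testing.assert_allclose(mb.barrier_heights, [2.0, 2.0])

    def test_shallow_features_merged(self):
        # barrier heights (saddle minus higher adjacent minimum) before
        # merging: 0.2, 0.2 and 2.5; after the 0.2-features merge the
        # middle barrier becomes 2 - max(0, 0.5) = 1.5
        dG = np.array([0., 2., 1.8, 2., 0.5, 3., 0.])
        curve = FreeEnergyCurve(np.arange(7.), dG, np.ones(7))
        assert find_minima_and_barriers(curve, min_depth=0.1).n_states == 4
        mb = find_minima_and_barriers(curve, min_depth=0.5)
        assert mb.n_states == 3
        np.testing.assert_allclose(mb.barrier_heights, [1.5, 2.5])
        assert find_minima_and_barriers(curve, min_depth=1.6).n_states == 2
        assert find_minima_and_barriers(curve, min_depth=3.5).n_states == 1

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=60),
           st.sampled_from([0.0, 0.5, 1.0, 1.5]))
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_oracle(self, values, min_depth):
        dG = np.array(values, dtype=float)
        curve = FreeEnergyCurve(np.arange(len(dG), dtype=float), dG,
                                np.ones(len(dG)))
        mb = find_minima_and_barriers(curve, min_depth=min_depth)
        n_ref, h_ref = minima_barriers_oracle(dG, min_depth)
        assert mb.n_states == n_ref
        np.testing.assert_allclose(mb.barrier_heights, h_ref)


class TestAssign:
    def test_simple_cut(self):
        np.testing.assert_array_equal(
            assign_by_thresholds([0.1, 0.9], [0.5]), [0, 1])

    def test_no_cuts_single_state(self):
        assert set(assign_by_thresholds(np.random.default_rng(0)
                                        .standard_normal(50), [])) == {0}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 500)
        cuts = np.sort(rng.uniform(-1.5, 1.5, 4))
        labels = assign_by_thresholds(x, cuts)
        brute = np.array([sum(v > c for c in cuts) for v in x])
        np.testing.assert_array_equal(labels, brute)

    def test_non_ascending_cuts_rejected(self):
        with pytest.raises(ValueError):
            assign_by_thresholds([0.0], [1.0, 0.5])


class TestPCA:
    def test_line_explains_all_variance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(1000)
        res = pca_reduce(np.c_[x, 2 * x], 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_noise_splits_evenly(self):
        rng = np.random.default_rng(5)
        res = pca_reduce(rng.standard_normal((200_000, 4)), 4)
        np.testing.assert_allclose(res.explained_variance_ratio, 0.25,
                                   atol=0.01)

    def test_components_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((500, 5)) @ rng.standard_normal((5, 5))
        res = pca_reduce(X, 5)
        np.testing.assert_allclose(res.components @ res.components.T,
                                   np.eye(5), atol=1e-10)
        recon = res.scores @ res.components + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((300, 3))
        r1, r2 = pca_reduce(X, 3), pca_reduce(X.copy(), 3)
        np.testing.assert_array_equal(r1.components, r2.components)
        for comp in r1.components:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestDensityClustering:
    def make_clouds(self, seed=0, n=300, spread=0.05):
        rng = np.random.default_rng(seed)
        centers = [(0, 0), (3, 0), (0, 3)]
        return np.vstack([rng.normal(c, spread, size=(n, 2))
                          for c in centers])

    def test_three_separated_clouds(self):
        X = self.make_clouds()
        dc = DensityClustering(radius=0.2, p_min=0.05).fit(X)
        assert dc.n_clusters_ == 3
        for k in range(3):
            block = dc.labels_[k * 300:(k + 1) * 300]
            assert len(np.unique(block)) == 1

    def test_single_cloud(self):
        X = self.make_clouds()[:300]
        assert DensityClustering(radius=0.2, p_min=0.05).fit(X).n_clusters_ == 1

    def test_labels_partition_and_population_floor(self):
        X = self.make_clouds(seed=1)
        dc = DensityClustering(radius=0.2, p_min=0.05).fit(X)
        assert np.all(dc.labels_ >= 0)
        for k in range(dc.n_clusters_):
            assert np.sum(dc.labels_ == k) >= 0.05 * len(X)

    def test_isolated_points_error_suggests_larger_radius(self):
        X = np.arange(20, dtype=float)[:, None] * 100
        with pytest.raises(ValueError, match="radius"):
            DensityClustering(radius=1.0, p_min=0.1).fit(X)

    def test_small_sample_warns(self):
        X = self.make_clouds(n=30)
        with pytest.warns(UserWarning, match="p_min"):
            DensityClustering(radius=0.2, p_min=1e-4).fit(X)

    def test_deterministic(self):
        X = self.make_clouds(seed=2)
        l1 = DensityClustering(radius=0.2, p_min=0.05).fit_predict(X)
        l2 = DensityClustering(radius=0.2, p_min=0.05).fit_predict(X)
        np.testing.assert_array_equal(l1, l2)

    def test_filtered_toy_data_recovers_three_wells(self, toy_traj_short,
                                                    default_potential):
        from metastable import gaussian_filter
        sub = gaussian_filter(toy_traj_short, window=10)[::5][:8000]
        dc = DensityClustering(p_min=0.02).fit(sub)
        assert dc.n_clusters_ == 3
        # labels constant in the neighbourhood of each well centre
        for c in default_potential.centers:
            near = np.linalg.norm(sub - np.asarray(c), axis=1) < 0.3
            vals, cnts = np.unique(dc.labels_[near], return_counts=True)
            assert cnts.max() / cnts.sum() > 0.95
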