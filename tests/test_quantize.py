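"""Clustering quantizers against exhaustive and fixed-point oracles."""

import itertools

import numpy as np
import pytest

from relcolors import infotheory as it
from relcolors import quantize as qz
from relcolors.synthetic import generate_image, true_information


def toy_sample(colors, weights=None):
    colors = np.asarray(colors, dtype=float)
    weights = np.ones(len(colors)) if weights is None else np.asarray(weights, float)
    return qz.PixelSample(colors=colors, weights=weights)


class TestKmeansPlusPlus:
    def test_single_center_comes_from_sample(self):
        sample = toy_sample([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        center = qz.kmeanspp_init(sample, 1, seed=4)
        assert any(np.array_equal(center[0], c) for c in sample.colors)

    def test_n_equals_distinct_colors_selects_all(self):
        colors = [[0, 0, 0], [50, 0, 0], [0, 50, 0], [0, 0, 50]]
        centers = qz.kmeanspp_init(toy_sample(colors), 4, seed=0)
        assert {tuple(c) for c in centers} == {tuple(map(float, c)) for c in colors}

    def test_too_few_distinct_colors_rejected(self):
        with pytest.raises(ValueError):
            qz.kmeanspp_init(toy_sample([[0, 0, 0], [1, 1, 1]]), 3, seed=0)

    def test_selection_frequencies_match_d2_distribution(self):
        """Empirical pair-selection frequencies over many seeds match the
        exactly enumerated D^2 seeding distribution on a fixed sample."""
        colors = np.array(
            [[0, 0, 0], [4, 0, 0], [20, 0, 0], [21, 0, 0]], dtype=float
        )
        sample = toy_sample(colors)
        m = len(colors)

        # enumerate P(first = i) * P(second = j | first = i) exactly
        expected = np.zeros((m, m))
        for i in range(m):
            d2 = ((colors - colors[i]) ** 2).sum(axis=1)
            expected[i] = (1.0 / m) * d2 / d2.sum()

        counts = np.zeros((m, m))
        trials = 4000
        for seed in range(trials):
            centers = qz.kmeanspp_init(sample, 2, seed=seed)
            i = int(np.where((colors == centers[0]).all(axis=1))[0][0])
            j = int(np.where((colors == centers[1]).all(axis=1))[0][0])
            counts[i, j] += 1
        freq = counts / trials
        # 4 sigma binomial tolerance per cell
        tol = 4.0 * np.sqrt(expected * (1 - expected) / trials) + 1e-9
        assert np.all(np.abs(freq - expected) <= tol)


class TestKmeans:
    def test_separated_colors_recovered_exactly(self, four_mode_image):
        img, _ = four_mode_image
        q = qz.kmeans_quantize(img, 4, seed=0)
        got = {tuple(np.round(c).astype(int)) for c in q.palette}
        assert got == {(200, 40, 40), (40, 170, 60), (50, 60, 200), (220, 200, 50)}

    def test_single_cluster_is_global_mean(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        q = qz.kmeans_quantize(img, 1, seed=0)
        np.testing.assert_allclose(
            q.palette[0], img.reshape(-1, 3).mean(axis=0), atol=1e-9
        )

    def test_matches_exhaustive_partition_oracle(self):
        """8 points, n = 2: Lloyd's objective equals the global optimum
        found by enumerating every 2-partition."""
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 100, size=(8, 3))
        img = pts.reshape(1, 8, 3)

        best = np.inf
        for assign in itertools.product([0, 1], repeat=8):
            assign = np.array(assign)
            if len(set(assign)) < 2:
                continue
            obj = 0.0
            for k in (0, 1):
                grp = pts[assign == k]
                obj += ((grp - grp.mean(axis=0)) ** 2).sum()
            best = min(best, obj)

        # several seeds: the best Lloyd run attains the oracle optimum
        objs = []
        for seed in range(10):
            q = qz.kmeans_quantize(img.astype(np.float64), 2, seed=seed)
            labels = q.labels.reshape(-1)
            obj = sum(
                ((pts[labels == k] - pts[labels == k].mean(axis=0)) ** 2).sum()
                for k in np.unique(labels)
            )
            objs.append(obj)
        assert min(objs) == pytest.approx(best, rel=1e-9)

    def test_deterministic_given_seed(self, noisy_image):
        img, _ = noisy_image
        a = qz.kmeans_quantize(img, 5, seed=9)
        b = qz.kmeans_quantize(img, 5, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.palette, b.palette)


class TestMec:
    def test_zero_temperature_limit_matches_kmeans(self, four_mode_image):
        img, _ = four_mode_image
        a = qz.mec_quantize(img, 4, seed=1, temperature=0.0)
        b = qz.kmeans_quantize(img, 4, seed=1)
        assert {tuple(np.round(c, 6)) for c in a.palette} == {
            tuple(np.round(c, 6)) for c in b.palette
        }

    def test_objective_non_increasing(self, noisy_image):
        img, _ = noisy_image
        q = qz.mec_quantize(img, 4, seed=2)
        diffs = np.diff(q.objective_trace)
        assert np.all(diffs <= 1e-6 * np.maximum(np.abs(q.objective_trace[:-1]), 1.0))

    def test_converged_memberships_satisfy_fixed_point(self):
        """At convergence the Gibbs membership and weighted-mean center
        equations hold simultaneously (residuals ~ 0)."""
        rng = np.random.default_rng(0)
        pts = np.concatenate(
            [rng.normal(20, 2, (40, 3)), rng.normal(120, 2, (40, 3))]
        )
        img = pts.reshape(8, 10, 3)
        T = 25.0
        q = qz.mec_quantize(img, 2, seed=0, temperature=T, max_iter=2000, tol=1e-14)
        centers = q.palette
        flat = img.reshape(-1, 3)
        d = ((flat[:, None] - centers[None]) ** 2).sum(-1)
        u = np.exp(-d / T)
        u /= u.sum(axis=1, keepdims=True)
        implied = (u.T @ flat) / u.sum(axis=0)[:, None]
        np.testing.assert_allclose(implied, centers, atol=1e-4)


class TestGmm:
    def test_recovers_separated_gaussian_means(self):
        rng = np.random.default_rng(8)
        means = np.array([[40, 40, 40], [160, 60, 60], [80, 200, 120]], dtype=float)
        pts = np.concatenate([rng.normal(m, 3.0, size=(400, 3)) for m in means])
        img = np.clip(pts, 0, 255).reshape(30, 40, 3)
        q = qz.gmm_quantize(img, 3, seed=0)
        se = 3.0 / np.sqrt(400)
        for m in means:
            nearest = q.palette[np.argmin(((q.palette - m) ** 2).sum(axis=1))]
            assert np.all(np.abs(nearest - m) < 3 * se + 0.5)

    def test_loglikelihood_non_decreasing(self, noisy_image):
        img, _ = noisy_image
        q = qz.gmm_quantize(img, 3, seed=1)
        assert np.all(np.diff(q.objective_trace) >= -1e-8)

    def test_single_component_matches_sample_moments(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
        q = qz.gmm_quantize(img, 1, seed=0)
        np.testing.assert_allclose(
            q.palette[0], img.reshape(-1, 3).mean(axis=0), atol=1e-6
        )


class TestMinCEntropy:
    def test_identity_clustering_on_n_distinct_colors(self, four_mode_image):
        img, _ = four_mode_image
        q = qz.mincentropy_quantize(img, 4, seed=0, bin_side=1)
        res = it.image_quantization_mi(img, q, bin_side=1)
        assert res.I == pytest.approx(res.H_original, abs=1e-12)

    def test_objective_trace_non_decreasing(self, noisy_image):
        img, _ = noisy_image
        q = qz.mincentropy_quantize(img, 5, seed=3, bin_side=4)
        assert q.objective_trace[-1] >= q.objective_trace[0] - 1e-12

    def test_final_mi_matches_exhaustive_assignment_oracle(self):
        """6 occupied bins, n = 2: hill climbing attains the maximum label
        entropy over all 2^6 assignments (I = H(label) for deterministic
        bin-to-label maps)."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            counts = rng.integers(1, 12, size=6)
            colors = rng.uniform(0, 255, size=(6, 3))
            img = np.repeat(colors, counts, axis=0).reshape(1, -1, 3)
            img = np.round(img).astype(np.uint8)
            # rounding may merge colors; recompute the actual bins
            ubins, ucounts = np.unique(img.reshape(-1, 3), axis=0, return_counts=True)
            if len(ubins) < 3:
                continue
            total = ucounts.sum()
            best = 0.0
            for assign in itertools.product([0, 1], repeat=len(ubins)):
                if len(set(assign)) < 2:
                    continue
                s0 = ucounts[np.array(assign) == 0].sum()
                p = np.array([s0, total - s0]) / total
                best = max(best, float(-(p[p > 0] * np.log2(p[p > 0])).sum()))
            q = qz.mincentropy_quantize(img, 2, seed=trial, bin_side=1)
            got = it.image_quantization_mi(img, q, bin_side=1).I
            assert got == pytest.approx(best, abs=1e-9)

    def test_improves_on_its_initialization(self, noisy_image):
        img, _ = noisy_image
        q = qz.mincentropy_quantize(img, 6, seed=5, bin_side=1)
        assert q.objective_trace[-1] >= q.objective_trace[0] - 1e-12

    def test_too_many_clusters_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            qz.mincentropy_quantize(img, 3, bin_side=1)


class TestGraphCut:
    def test_zero_smoothness_is_nearest_center_assignment(self, noisy_image):
        img, _ = noisy_image
        q = qz.graphcut_quantize(img, 4, seed=0, smoothness_weight=0.0, grid_max=32)
        km = qz.kmeans_quantize(img, 4, seed=0)
        d = (
            (img.reshape(-1, 3)[:, None].astype(float) - q.palette[None]) ** 2
        ).sum(-1)
        np.testing.assert_array_equal(q.labels.reshape(-1), d.argmin(1))
        np.testing.assert_allclose(q.palette, km.palette)

    def test_energy_non_increasing(self, noisy_image):
        img, _ = noisy_image
        q = qz.graphcut_quantize(img, 3, seed=1, grid_max=16)
        assert np.all(np.diff(q.objective_trace) <= 1e-9)

    def test_binary_cut_matches_exhaustive_labeling_oracle(self):
        """4x4 image, n = 2: the expansion's energy equals the minimum over
        all 2^16 labelings of the same Potts energy."""
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        lam, sigma = 0.5, 30.0
        q = qz.graphcut_quantize(
            img, 2, seed=0, smoothness_weight=lam, grid_max=4, sigma_affinity=sigma
        )
        flat = img.reshape(-1, 3).astype(float)
        centers = q.palette
        edges = qz._grid_edges(4, 4)
        aff = np.exp(-((flat[edges[:, 0]] - flat[edges[:, 1]]) ** 2).sum(1) / (2 * sigma**2))

        def energy(lab):
            un = ((flat - centers[lab]) ** 2).sum(1).sum() / sigma**2
            cut = lab[edges[:, 0]] != lab[edges[:, 1]]
            return un + lam * aff[cut].sum()

        best = min(
            energy(np.array(assign))
            for assign in itertools.product([0, 1], repeat=16)
        )
        # the optimized subgrid labeling (= full grid here) attains the optimum
        got = energy(q.labels.reshape(-1))
        assert got == pytest.approx(best, rel=1e-9)


class TestApplyPalette:
    def test_single_cluster_constant_output(self, noisy_image):
        img, _ = noisy_image
        q = qz.kmeans_quantize(img, 1, seed=0)
        out = qz.apply_palette(img, q)
        assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1

    def test_lossless_case_identity(self, four_mode_image):
        img, _ = four_mode_image
        q = qz.kmeans_quantize(img, 4, seed=0)
        assert np.array_equal(qz.apply_palette(img, q), img)

    def test_unique_color_count_bounded_by_n(self, noisy_image):
        img, _ = noisy_image
        for method in qz.CLUSTER_METHODS:
            kwargs = {"grid_max": 16} if method == "graphcut" else {}
            q = qz.quantize(img, method, 3, seed=0, **kwargs)
            out = qz.apply_palette(img, q)
            assert len(np.unique(out.reshape(-1, 3), axis=0)) <= 3
            assert q.n == 3 and q.palette.shape == (3, 3)

    def test_out_of_range_label_rejected(self, four_mode_image):
        img, _ = four_mode_image
        q = qz.kmeans_quantize(img, 2, seed=0)
        q.labels = q.labels.copy()
        q.labels[0, 0] = 7
        with pytest.raises(ValueError):
            qz.apply_palette(img, q)


def test_all_methods_recover_mode_information(four_mode_spec):
    """On well-separated noise-free modes every quantizer at n = n_true
    captures the full mode-label information."""
    img, _ = generate_image(four_mode_spec)
    truth = true_information(four_mode_spec)
    for method in qz.CLUSTER_METHODS:
        kwargs = {"grid_max": 32} if method == "graphcut" else {}
        q = qz.quantize(img, method, 4, seed=1, **kwargs)
        got = it.image_quantization_mi(img, q, bin_side=1).I
        assert got == pytest.approx(truth, abs=1e-9), method


def test_full_determinism_contract(noisy_image):
    """Fixed seed implies bit-identical quantization for every method."""
    img, _ = noisy_image
    for method in qz.CLUSTER_METHODS:
        kwargs = {"grid_max": 16} if method == "graphcut" else {}
        a = qz.quantize(img, method, 4, seed=12, **kwargs)
        b = qz.quantize(img, method, 4, seed=12, **kwargs)
        np.testing.assert_array_equal(a.labels, b.labels, err_msg=method)
        np.testing.assert_array_equal(a.palette, b.palette, err_msg=method)
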