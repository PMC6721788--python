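import itertools

import numpy as np
import pytest

from threshcheck.glm import StatMap, one_sample_t
from threshcheck.image_io import BrainMask, VolumeGrid
from threshcheck.synthetic_data import ClusterSpec, SimulationConfig, simulate_dataset
from threshcheck.thresholding import (
    METHOD_NAMES,
    ThresholdConfig,
    clustsim_threshold,
    label_clusters,
    mc_cluster_threshold,
    run_all_methods,
    sign_flip_matrix,
    sign_flip_null,
    snpm_clusterwise,
    snpm_voxelwise,
    tfce_fwe,
    tfce_transform,
)
from threshcheck.acf_noise import ACFParams
from tests.conftest import make_dataset


class TestLabelClusters:
    def test_corner_touching_voxels_by_connectivity(self):
        binary = np.zeros((3, 3, 3), dtype=bool)
        binary[0, 0, 0] = binary[1, 1, 1] = True  # share only a corner
        assert label_clusters(binary, 6).n_clusters == 2
        assert label_clusters(binary, 26).n_clusters == 1

    def test_edge_touching_voxels(self):
        binary = np.zeros((3, 3, 3), dtype=bool)
        binary[0, 0, 0] = binary[0, 1, 1] = True  # share an edge
        assert label_clusters(binary, 6).n_clusters == 2
        assert label_clusters(binary, 18).n_clusters == 1

    def test_empty_map(self):
        lab = label_clusters(np.zeros((4, 4, 4), dtype=bool), 18)
        assert lab.n_clusters == 0 and lab.sizes == []

    def test_solid_block_single_cluster(self):
        binary = np.zeros((4, 4, 4), dtype=bool)
        binary[1:3, 1:3, 1:3] = True
        for conn in (6, 18, 26):
            lab = label_clusters(binary, conn)
            assert lab.sizes == [8]


class TestSignFlips:
    def test_full_enumeration_for_small_n(self):
        flips = sign_flip_matrix(3, 100, seed=0)
        assert flips.shape == (8, 3)
        assert {tuple(r) for r in flips} == {
            tuple(p) for p in itertools.product((1.0, -1.0), repeat=3)
        }
        np.testing.assert_array_equal(flips[0], 1.0)

    def test_sampled_flips_include_identity(self):
        flips = sign_flip_matrix(20, 50, seed=1)
        assert flips.shape == (50, 20)
        np.testing.assert_array_equal(flips[0], 1.0)

    def test_abs_t_null_is_pairwise_degenerate_under_enumeration(self):
        # |t| is invariant to flipping all signs, so under full enumeration
        # every null value appears an even number of times
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.standard_normal((4, 3, 3, 3)))

        def abs_t(d):
            tmap, _ = one_sample_t(d)
            return np.abs(tmap.values)

        null = sign_flip_null(ds, 16, seed=0, statistic=abs_t)
        vals, counts = np.unique(np.round(null, 10), return_counts=True)
        assert np.all(counts % 2 == 0)

    def test_observed_never_exceeds_null_maximum(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.standard_normal((5, 3, 3, 3)))

        def max_t(d):
            tmap, _ = one_sample_t(d)
            return tmap.values

        null = sign_flip_null(ds, 32, seed=0, statistic=max_t)
        assert null[0] <= max(null)


def brute_force_voxel_p(data: np.ndarray) -> np.ndarray:
    """Independent enumeration oracle for corrected voxel p values.

    For every sign assignment, compute the t map by the textbook formula and
    take the max; corrected p of a voxel = fraction of assignments whose max
    reaches its observed t.
    """
    n = data.shape[0]
    flat = data.reshape(n, -1)
    maxima = []
    for signs in itertools.product((1.0, -1.0), repeat=n):
        flipped = flat * np.array(signs)[:, None]
        m = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        t = m / (sd / np.sqrt(n))
        maxima.append(t.max())
    maxima = np.array(maxima)
    obs = flat.mean(axis=0) / (flat.std(axis=0, ddof=1) / np.sqrt(n))
    return np.array([(maxima >= o).sum() / len(maxima) for o in obs])


class TestPermutationExactness:
    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_corrected_p_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        data = rng.standard_normal((n, 3, 3, 3)) + 0.4
        ds = make_dataset(data)
        cfg = ThresholdConfig(n_permutations=5000, var_smooth_fwhm_mm=0.0, seed=0)
        res = snpm_voxelwise(ds, cfg)
        expected = brute_force_voxel_p(data)
        np.testing.assert_allclose(res.corrected_p.ravel(), expected)
        # exact enumeration: p values are multiples of 2^-n
        assert np.allclose(res.corrected_p * 2**n, np.round(res.corrected_p * 2**n))

    def test_n3_smallest_p_is_eighth_so_nothing_survives(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.standard_normal((3, 3, 3, 3)) + 5.0)
        cfg = ThresholdConfig(n_permutations=5000, seed=0)
        res = snpm_voxelwise(ds, cfg)
        assert res.corrected_p.min() >= 1 / 8
        assert res.n_survivors == 0


class TestSnpmOnSignal:
    def test_voxelwise_catches_core_and_clusterwise_keeps_cluster(self, signal_dataset):
        cfg = ThresholdConfig(n_permutations=300, seed=3)
        vox = snpm_voxelwise(signal_dataset, cfg)
        clu = snpm_clusterwise(signal_dataset, cfg)
        core = signal_dataset.data().mean(axis=0) > 1.8
        assert (vox.survivors & core).sum() >= 0.5 * core.sum()
        assert (clu.survivors & core).sum() == core.sum()

    def test_clusterwise_empty_map_still_reports_extent(self, null_dataset):
        cfg = ThresholdConfig(n_permutations=100, cluster_forming_p=1e-6, seed=0)
        res = snpm_clusterwise(null_dataset, cfg)
        assert res.n_survivors == 0
        assert res.thresholds["critical_extent"] >= 1


class TestMonteCarloClusterThreshold:
    def _mask(self, dims=(20, 20, 20)):
        return BrainMask(VolumeGrid(dims, (2, 2, 2)), np.ones(dims, dtype=bool))

    def test_alpha_one_gives_k_of_one(self):
        cfg = ThresholdConfig(corrected_alpha=1.0, n_mc_iterations=50, seed=0)
        assert mc_cluster_threshold(self._mask((10, 10, 10)), {"fwhm_mm": 0.0}, cfg) == 1

    def test_white_noise_self_consistency(self):
        # two independent Monte-Carlo runs agree within +-1 on k*
        mask = self._mask()
        k1 = mc_cluster_threshold(
            mask, {"fwhm_mm": 0.0},
            ThresholdConfig(n_mc_iterations=4000, seed=1))
        k2 = mc_cluster_threshold(
            mask, {"fwhm_mm": 0.0},
            ThresholdConfig(n_mc_iterations=4000, seed=2))
        assert abs(k1 - k2) <= 1

    def test_smoother_noise_needs_larger_clusters(self):
        mask = self._mask()
        ks4 = [mc_cluster_threshold(mask, {"fwhm_mm": 4.0},
                                    ThresholdConfig(n_mc_iterations=1500, seed=s))
               for s in range(3)]
        ks8 = [mc_cluster_threshold(mask, {"fwhm_mm": 8.0},
                                    ThresholdConfig(n_mc_iterations=1500, seed=s))
               for s in range(3)]
        assert np.mean(ks8) >= np.mean(ks4)

    def test_gaussian_and_acf_variants_agree_on_gaussian_truth(self, signal_dataset):
        # data noise is Gaussian-smoothed, so the constrained (a=1) fit and
        # the mixed-ACF fit describe the same process; the cube tiling makes
        # the ACF variant slightly rougher, so require agreement within 30%
        cfg = ThresholdConfig(n_mc_iterations=1500, seed=5,
                              acf_cube_dims=(10, 10, 10))
        g = clustsim_threshold(signal_dataset, cfg, use_acf=False)
        a = clustsim_threshold(signal_dataset, cfg, use_acf=True)
        k_g, k_a = g.thresholds["k_star"], a.thresholds["k_star"]
        assert abs(k_g - k_a) <= max(3, 0.3 * max(k_g, k_a))

    def test_clustsim_strong_signal_keeps_template_cluster(self, signal_dataset):
        cfg = ThresholdConfig(n_mc_iterations=1000, seed=1)
        for use_acf in (False, True):
            res = clustsim_threshold(signal_dataset, cfg, use_acf=use_acf)
            core = signal_dataset.data().mean(axis=0) > 1.8
            assert (res.survivors & core).sum() == core.sum()


class TestTFCE:
    def _stat(self, values, df=10):
        grid = VolumeGrid(values.shape, (2, 2, 2))
        return StatMap(grid, values, df=df)

    def test_all_zero_map_transforms_to_zero(self):
        cfg = ThresholdConfig()
        out = tfce_transform(self._stat(np.zeros((5, 5, 5))), cfg)
        assert not out.any()

    def test_single_voxel_matches_closed_form(self):
        # isolated voxel of height h: TFCE -> h^3 / 3 (E=0.5, H=2)
        h0 = 2.5
        values = np.zeros((7, 7, 7))
        values[3, 3, 3] = h0
        out = tfce_transform(self._stat(values), ThresholdConfig(tfce_n_steps=100))
        assert out[3, 3, 3] == pytest.approx(h0**3 / 3, rel=0.02)

    def test_two_voxel_plateau_matches_closed_form(self):
        # connected pair of equal height: e = 2, TFCE -> sqrt(2) h^3 / 3
        h0 = 1.8
        values = np.zeros((7, 7, 7))
        values[3, 3, 3] = values[3, 3, 4] = h0
        out = tfce_transform(self._stat(values), ThresholdConfig(tfce_n_steps=100))
        for idx in [(3, 3, 3), (3, 3, 4)]:
            assert out[idx] == pytest.approx(np.sqrt(2) * h0**3 / 3, rel=0.02)

    def test_scaling_law(self):
        # TFCE(lam * map) = lam^(H+1) * TFCE(map) in the continuous limit
        rng = np.random.default_rng(6)
        values = np.maximum(rng.standard_normal((8, 8, 8)), 0)
        cfg = ThresholdConfig(tfce_n_steps=200)
        base = tfce_transform(self._stat(values), cfg)
        scaled = tfce_transform(self._stat(3.0 * values), cfg)
        np.testing.assert_allclose(scaled, 3.0**3 * base, rtol=0.02, atol=1e-9)

    def test_alpha_one_keeps_every_positive_tfce_voxel(self, signal_dataset):
        cfg = ThresholdConfig(n_permutations=50, corrected_alpha=1.0, seed=0)
        res = tfce_fwe(signal_dataset, cfg)
        tmap, _ = one_sample_t(signal_dataset)
        tf = tfce_transform(tmap, cfg)
        np.testing.assert_array_equal(
            res.survivors, (tf > 0) & signal_dataset.mask.inside
        )

    def test_signal_sensitivity_at_least_voxelwise(self, signal_dataset):
        cfg = ThresholdConfig(n_permutations=300, seed=2)
        tf = tfce_fwe(signal_dataset, cfg)
        vox = snpm_voxelwise(signal_dataset, cfg)
        assert tf.n_survivors >= vox.n_survivors


class TestRunAllMethods:
    def test_five_distinct_methods_within_mask(self, signal_dataset):
        cfg = ThresholdConfig(n_permutations=64, n_mc_iterations=300, tfce_n_steps=30,
                              seed=0)
        results, table = run_all_methods(signal_dataset, cfg)
        assert [r.method for r in results] == list(METHOD_NAMES)
        for r in results:
            assert not (r.survivors & ~signal_dataset.mask.inside).any()
            assert r.n_survivors == int(r.survivors.sum())
        assert set(table["method"]) == set(METHOD_NAMES)

    def test_effect_shift_never_reduces_survivors(self, signal_dataset):
        cfg = ThresholdConfig(n_permutations=80, n_mc_iterations=300, seed=1)
        res_base, _ = run_all_methods(signal_dataset, cfg)
        shifted = signal_dataset.with_images(signal_dataset.data() + 0.5)
        res_up, _ = run_all_methods(shifted, cfg)
        for a, b in zip(res_base, res_up):
            assert b.n_survivors >= a.n_survivors
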