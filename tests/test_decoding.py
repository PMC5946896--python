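"""Searchlight geometry, k-NN behaviour, schemes, smoothing."""

import numpy as np
import pytest

import semdecode as sd
from semdecode.decoding import Searchlight, _sphere_sums
from _oracle import brute_sphere_offsets

from scipy import ndimage


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(0, 1), (1, 7), (2, 33), (3, 123)])
    def test_counts_match_brute_force(self, radius, count):
        offs = sd.sphere_offsets(radius)
        assert len(offs) == len(brute_sphere_offsets(radius)) == count

    def test_symmetric_under_negation_and_contains_centre(self):
        offs = {tuple(o) for o in sd.sphere_offsets(3)}
        assert (0, 0, 0) in offs
        assert all((-a, -b, -c) in offs for a, b, c in offs)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            sd.sphere_offsets(-1)


def test_sphere_sums_equal_explicit_convolution():
    rng = np.random.default_rng(0)
    vols = rng.standard_normal((3, 7, 6, 9))
    for r in (1, 2, 3):
        kernel = Searchlight(radius_vox=r).kernel()
        got = _sphere_sums(vols, r)
        for i in range(3):
            ref = ndimage.correlate(vols[i], kernel, mode="constant")
            np.testing.assert_allclose(got[i], ref, atol=1e-9)


class TestKNN:
    def test_identical_pattern_returns_its_label(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 10))
        y = np.array([1, 2, 3, 1, 2, 3])
        pred = sd.knn_classify(X, y, X[[4]], k=1)
        assert pred[0] == 2

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            sd.knn_classify(np.empty((0, 3)), np.array([]), np.zeros((1, 3)))

    def test_feature_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sd.knn_classify(np.zeros((2, 3)), np.array([1, 2]), np.zeros((1, 4)))

    def test_distance_ties_resolve_by_training_order(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])  # equidistant from origin
        assert sd.knn_classify(X, np.array([5, 7]), np.zeros((1, 2)))[0] == 5
        assert sd.knn_classify(X[::-1], np.array([7, 5]), np.zeros((1, 2)))[0] == 7

    def test_vote_ties_resolve_to_smallest_label(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([9, 9, 2, 2])
        # k=4: two votes each; smallest label wins
        assert sd.knn_classify(X, y, np.array([[5.0]]), k=4)[0] == 2

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(2)
        accs = []
        for _ in range(300):
            X = rng.standard_normal((20, 8))
            y = np.tile(np.arange(10), 2)
            Xte = rng.standard_normal((10, 8))
            pred = sd.knn_classify(X, rng.permutation(y), Xte, k=1)
            accs.append(np.mean(pred == np.arange(10)))
        assert abs(np.mean(accs) - 0.1) < 0.01


class TestSchemes:
    def test_cross_language_fold_structure(self, cross_language_reading):
        s = cross_language_reading
        assert len(s.folds) == 5
        for r, (train_runs, test_runs) in enumerate(s.folds):
            assert test_runs == (r,)
            assert set(train_runs) == set(range(5)) - {r}
        assert s.train_language == "L1" and s.test_language == "L2"
        mirror = s.direction_pair
        assert mirror.train_language == "L2" and mirror.test_language == "L1"
        assert mirror.direction_pair is None

    def test_cross_modality_cells_disjoint(self):
        s = sd.make_cross_modality_scheme("naming", "reading")
        for direction in s.directions():
            assert direction.train_task != direction.test_task
            assert direction.train_language != direction.test_language

    def test_cross_modality_same_task_rejected(self):
        with pytest.raises(ValueError, match="different tasks"):
            sd.make_cross_modality_scheme("naming", "naming")

    def test_same_cell_overlapping_runs_rejected(self):
        with pytest.raises(ValueError, match="share"):
            sd.DecodingScheme(
                train_task="reading", train_language="L1",
                test_task="reading", test_language="L1",
                folds=(((0, 1, 2), (2,)),),
            )

    def test_within_language_flagged_confounded(self):
        s = sd.make_within_language_scheme("reading")
        assert s.lexically_confounded
        # leave-one-run-out keeps runs disjoint, so it constructs fine
        assert all(set(tr).isdisjoint(te) for tr, te in s.folds)


class TestSearchlight:
    def test_noise_free_shared_region_decodes_perfectly(
        self, noise_free_dataset, shared_region
    ):
        scheme = sd.make_cross_language_scheme("reading", n_runs=3)
        amap = sd.run_searchlight(
            noise_free_dataset, 0, scheme, sd.Searchlight(radius_vox=1, min_voxels=1)
        )
        # centres whose whole sphere lies inside the signal region
        interior = ndimage.binary_erosion(shared_region.mask, ndimage.generate_binary_structure(3, 3))
        assert np.all(amap.data[interior] == 1.0)

    def test_accuracy_map_provenance_and_range(self, signal_free_dataset, cross_language_reading):
        amap = sd.run_searchlight(signal_free_dataset, 0, cross_language_reading)
        vals = amap.data[np.isfinite(amap.data)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert amap.provenance["scheme"] == "cross_language:reading"
        assert amap.provenance["radius_vox"] == 3

    def test_signal_free_map_mean_near_chance(self, signal_free_dataset, cross_language_reading):
        """Binomial pooling: mean over the map within 3 SE of 1/n_concepts."""
        means = [
            sd.run_searchlight(signal_free_dataset, s, cross_language_reading).mean()
            for s in range(signal_free_dataset.n_subjects)
        ]
        # 100 pooled predictions per centre; centres are correlated, so use
        # the single-centre binomial SE as a conservative scale
        se = np.sqrt(0.1 * 0.9 / 100)
        assert abs(np.mean(means) - 0.1) < 3 * se

    def test_language_specific_region_does_not_transfer(self, small_geometry):
        region = sd.cuboid_region(
            small_geometry, (2, 2, 2), (8, 8, 8), "language_specific", amplitude=3.0
        )
        cfg = sd.SimulationConfig(
            n_subjects=2, tasks=("reading",), effect_regions=(region,),
            noise_sd=0.5, seed=31,
        )
        ds = sd.generate_beta_dataset(cfg, small_geometry)
        scheme = sd.make_cross_language_scheme("reading")
        means = []
        for s in range(2):
            amap = sd.run_searchlight(ds, s, scheme)
            means.append(float(np.nanmean(amap.data[region.mask])))
        assert abs(np.mean(means) - 0.1) < 0.05

    def test_min_voxels_marks_centres_undefined_not_zero(self, signal_free_dataset):
        sl = sd.Searchlight(radius_vox=1, min_voxels=7)
        amap = sd.run_searchlight(
            signal_free_dataset, 0, sd.make_cross_language_scheme("reading"), sl
        )
        corner = amap.data[0, 0, 0]  # sphere truncated to 4 voxels at the corner
        assert np.isnan(corner)
        assert np.isfinite(amap.data[5, 5, 5])

    def test_relabeling_equivariance(self, small_geometry):
        """Consistently permuting concept identities leaves accuracy unchanged."""
        region = sd.cuboid_region(small_geometry, (2, 2, 2), (8, 8, 8), "shared_semantic")
        cfg = sd.SimulationConfig(
            n_subjects=1, tasks=("reading",), n_runs=3, n_concepts=4,
            presentations_per_run=2, effect_regions=(region,), noise_sd=1.0, seed=13,
        )
        ds = sd.generate_beta_dataset(cfg, small_geometry)
        perm = np.array([2, 0, 3, 1])
        permuted = sd.BetaPatternDataset(
            geometry=ds.geometry, mask=ds.mask,
            betas=ds.betas[:, :, :, :, perm], tasks=ds.tasks,
        )
        scheme = sd.make_cross_language_scheme("reading", n_runs=3)
        a0 = sd.run_searchlight(ds, 0, scheme)
        a1 = sd.run_searchlight(permuted, 0, scheme)
        np.testing.assert_array_equal(
            np.nan_to_num(a0.data, nan=-1), np.nan_to_num(a1.data, nan=-1)
        )

    def test_generic_metric_path_matches_euclidean_fast_path(self, small_geometry):
        region = sd.cuboid_region(small_geometry, (3, 3, 3), (7, 7, 7), "shared_semantic")
        cfg = sd.SimulationConfig(
            n_subjects=1, tasks=("reading",), n_runs=2, n_concepts=3,
            presentations_per_run=2, effect_regions=(region,), noise_sd=1.0, seed=17,
        )
        ds = sd.generate_beta_dataset(cfg, small_geometry)
        scheme = sd.make_cross_language_scheme("reading", n_runs=2)
        sl = sd.Searchlight(radius_vox=2, min_voxels=1)
        fast = sd.run_searchlight(ds, 0, scheme, sl, sd.KNNSettings(metric="euclidean"))
        slow = sd.run_searchlight(ds, 0, scheme, sl, sd.KNNSettings(metric="sqeuclidean"))
        np.testing.assert_array_equal(
            np.nan_to_num(fast.data, nan=-1), np.nan_to_num(slow.data, nan=-1)
        )


class TestSmoothing:
    def _flat_map(self, geometry, data):
        return sd.AccuracyMap(
            geometry=geometry, mask=np.ones(geometry.shape, bool), data=data
        )

    def test_zero_fwhm_is_identity(self, small_geometry):
        rng = np.random.default_rng(3)
        amap = self._flat_map(small_geometry, rng.random(small_geometry.shape))
        assert sd.smooth_map(amap, 0.0) is amap

    def test_impulse_follows_gaussian_and_preserves_sum(self):
        geom = sd.VolumeGeometry.isotropic((41, 41, 41), 3.0)
        data = np.zeros(geom.shape)
        data[20, 20, 20] = 1.0
        sm = sd.smooth_map(self._flat_map(geom, data), fwhm_mm=8.0)
        sigma_mm = 8.0 / (2 * np.sqrt(2 * np.log(2)))
        sigma_vox = sigma_mm / 3.0
        ijk = np.indices(geom.shape)
        d2 = sum((ijk[a] - 20.0) ** 2 for a in range(3))
        expected = np.exp(-d2 / (2 * sigma_vox**2))
        expected /= expected.sum()
        np.testing.assert_allclose(sm.data, expected, atol=1e-4)
        assert sm.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_map_unchanged_by_mask_aware_normalization(self, small_geometry):
        amap = self._flat_map(small_geometry, np.full(small_geometry.shape, 0.37))
        sm = sd.smooth_map(amap, 8.0)
        np.testing.assert_allclose(sm.data, 0.37, atol=1e-12)

    def test_negative_fwhm_rejected(self, small_geometry):
        amap = self._flat_map(small_geometry, np.zeros(small_geometry.shape))
        with pytest.raises(ValueError):
            sd.smooth_map(amap, -1.0)


def test_accuracy_map_nifti_round_trip(tmp_path, signal_free_dataset, cross_language_reading):
    amap = sd.run_searchlight(signal_free_dataset, 0, cross_language_reading)
    path = tmp_path / "acc.nii.gz"
    amap.to_nifti(path)
    back = sd.AccuracyMap.from_nifti(path)
    np.testing.assert_allclose(
        np.nan_to_num(back.data, nan=-1), np.nan_to_num(amap.data, nan=-1), atol=1e-6
    )


@pytest.mark.parametrize("per_run_4d", [False, True])
def test_beta_dataset_nifti_round_trip(tmp_path, noise_free_dataset, per_run_4d):
    noise_free_dataset.to_dir(tmp_path / "betas", per_run_4d=per_run_4d)
    back = sd.BetaPatternDataset.from_dir(tmp_path / "betas")
    assert back.tasks == noise_free_dataset.tasks
    np.testing.assert_allclose(back.betas, noise_free_dataset.betas, atol=1e-6)
    np.testing.assert_array_equal(back.mask, noise_free_dataset.mask)
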