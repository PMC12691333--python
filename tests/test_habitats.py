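"""Entropy maps, pooled standardization, k-means, CH index and habitat maps."""

import numpy as np
import pytest

import habikit as hk
from conftest import ch_bruteforce, entropy_bruteforce


def _volume_pair(values, spacing=(1.0, 1.0, 1.0), mask=None):
    img = hk.VolumeImage(np.asarray(values, float), spacing)
    if mask is None:
        mask = np.ones(img.shape)
    return img, hk.TumorMask(mask, spacing)


class TestEntropyMap:
    def test_constant_region_has_zero_entropy(self):
        img, msk = _volume_pair(np.full((6, 6, 6), 40.0))
        fmap = hk.entropy_map(img, msk, window=1, n_bins=32)
        assert np.all(np.abs(fmap.entropy) < 1e-6)

    def test_two_equal_masses_give_one_bit(self):
        # a 1x1x4 tumor split 0/0/100/100: the window-2 neighbourhood of the
        # two middle voxels holds both levels in equal mass -> exactly 1 bit
        vals = np.array([[[0.0, 0.0, 100.0, 100.0]]])
        img, msk = _volume_pair(vals)
        fmap = hk.entropy_map(img, msk, window=2, n_bins=2)
        assert fmap.entropy[1] == pytest.approx(1.0, abs=1e-9)
        assert fmap.entropy[2] == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_loop_oracle(self, rng):
        vals = rng.normal(50, 20, size=(7, 7, 7))
        mask = (rng.uniform(size=vals.shape) < 0.8).astype(np.uint8)
        mask[3, 3, 3] = 1
        img, msk = _volume_pair(vals, mask=mask)
        fmap = hk.entropy_map(img, msk, window=2, n_bins=16, eps=1e-12)
        oracle = entropy_bruteforce(vals, mask, window=2, n_bins=16, eps=1e-12)
        for i, (z, y, x) in enumerate(zip(*fmap.indices)):
            assert fmap.entropy[i] == pytest.approx(
                max(oracle[(z, y, x)], 0.0), abs=1e-8
            )

    def test_entropy_bounded_by_log_bins(self, small_cohort):
        _, volumes, _, _ = small_cohort
        img, msk = volumes[0]
        for n_bins in (8, 32):
            fmap = hk.entropy_map(img, msk, n_bins=n_bins)
            assert fmap.entropy.min() >= 0.0
            assert fmap.entropy.max() <= np.log2(n_bins) + 1e-6

    def test_parameter_validation(self, small_cohort):
        _, volumes, _, _ = small_cohort
        img, msk = volumes[0]
        for kwargs in ({"window": 0}, {"n_bins": 1}, {"eps": 0.0}):
            with pytest.raises(ValueError):
                hk.entropy_map(img, msk, **kwargs)


class TestPooling:
    def test_standardized_columns_have_zero_mean_unit_sd(self, small_cohort):
        _, volumes, _, _ = small_cohort
        fmaps = [hk.entropy_map(i, m) for i, m in volumes]
        pooled = hk.pool_cohort_features(fmaps)
        np.testing.assert_allclose(pooled.matrix.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(pooled.matrix.std(axis=0), 1.0, atol=1e-9)

    def test_row_count_conservation(self, small_cohort):
        _, volumes, _, _ = small_cohort
        fmaps = [hk.entropy_map(i, m) for i, m in volumes]
        pooled = hk.pool_cohort_features(fmaps)
        assert len(pooled.matrix) == sum(m.n_voxels for _, m in volumes)
        counts = np.bincount(pooled.patient_index)
        assert list(counts) == [len(f) for f in fmaps]

    def test_heldout_standardized_with_training_parameters(self, small_cohort):
        _, volumes, _, _ = small_cohort
        fmaps = [hk.entropy_map(i, m) for i, m in volumes]
        pooled_train = hk.pool_cohort_features(fmaps[:4])
        heldout = pooled_train.transform(fmaps[5])
        own = (fmaps[5].features - fmaps[5].features.mean(0)) / \
            fmaps[5].features.std(0)
        expected = (fmaps[5].features - pooled_train.mean) / pooled_train.std
        np.testing.assert_allclose(heldout, expected)
        assert not np.allclose(heldout, own)

    def test_zero_variance_column_named_in_error(self):
        img, msk = hk.VolumeImage(np.full((4, 4, 4), 9.0)), hk.TumorMask(
            np.ones((4, 4, 4)))
        fmap = hk.entropy_map(img, msk)
        with pytest.raises(ValueError, match="intensity"):
            hk.pool_cohort_features([fmap])


class TestKMeans:
    def test_degenerate_identical_rows(self):
        x = np.tile([2.0, -1.0], (30, 1))
        res = hk.kmeans_cluster(x, k=2, seed=0)
        np.testing.assert_allclose(res.centroids, [[2.0, -1.0]] * 2)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_recovers_well_separated_gaussians(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = np.array([[0, 0], [10, 0], [0, 10]])
        truth = np.repeat([0, 1, 2], 150)
        x = centers[truth] + rng.normal(0, 0.3, size=(450, 2))
        res = hk.kmeans_cluster(x, k=3, seed=1)
        assert adjusted_rand_score(truth, res.assignment) > 0.99

    def test_inertia_equals_bruteforce_sum(self, rng):
        x = rng.normal(size=(200, 2))
        res = hk.kmeans_cluster(x, k=4, seed=3)
        brute = sum(
            ((x[i] - res.centroids[res.assignment[i] - 1]) ** 2).sum()
            for i in range(len(x))
        )
        assert res.inertia == pytest.approx(brute, rel=1e-10)

    def test_inertia_non_increasing_in_k(self, rng):
        x = rng.normal(size=(300, 2))
        inertias = [hk.kmeans_cluster(x, k, seed=0).inertia
                    for k in range(2, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))


class TestCalinskiHarabasz:
    def test_two_tight_triplets_match_bruteforce_to_1e10(self):
        x = np.array([[0, 0], [0.1, 0], [0, 0.1],
                      [10, 10], [10.1, 10], [10, 10.1]])
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert hk.calinski_harabasz(x, labels) == pytest.approx(
            ch_bruteforce(x, labels), abs=1e-10
        )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        x = rng.normal(size=(80, 2))
        labels = rng.integers(1, 4, size=80)
        assert hk.calinski_harabasz(x, labels) == pytest.approx(
            calinski_harabasz_score(x, labels), rel=1e-10
        )

    def test_each_point_own_cluster_returns_inf_sentinel(self):
        x = np.array([[0.0, 0], [1, 0], [2, 0]])
        assert hk.calinski_harabasz(x, np.array([1, 2, 3])) == np.inf

    def test_planted_three_clusters_beat_k2_and_k4(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        x = centers[np.repeat([0, 1, 2], 100)] + rng.normal(0, 0.4, (300, 2))
        ch = {k: hk.kmeans_cluster(x, k, seed=0).ch for k in (2, 3, 4)}
        assert ch[3] > ch[2] and ch[3] > ch[4]


class TestSelectK:
    def test_two_planted_habitats_give_k2(self):
        from habikit.synthetic import HabitatParams

        spec = hk.PhantomSpec(
            n_patients=5, k_true=2,
            habitat_params=(HabitatParams(20, 10, 0.05),
                            HabitatParams(90, 6, 2.5)),
            outcome_beta=(3.0, -3.0, 1.0),
            seed=21, tumor_radius_range=(7.0, 10.0),
        )
        volumes, _, _ = hk.generate_cohort(spec)
        fmaps = [hk.entropy_map(i, m) for i, m in volumes]
        pooled = hk.pool_cohort_features(fmaps)
        assert hk.select_k(pooled.matrix, k_range=range(2, 6),
                           seed=21).k_star == 2

    def test_ties_break_toward_smaller_k(self):
        # two exactly repeated distinct points: CH is the +inf sentinel for
        # every k that isolates them, so the tie must resolve to k=2
        x = np.array([[0.0, 0.0]] * 10 + [[5.0, 5.0]] * 10
                     + [[9.0, 0.0]] * 10)
        ks = hk.select_k(x, k_range=range(2, 5), seed=0)
        assert ks.ch_by_k[3] == np.inf
        assert ks.k_star == min(
            k for k, v in ks.ch_by_k.items() if v == np.inf
        )

    def test_k_range_bounds_validated(self, rng):
        x = rng.normal(size=(50, 2))
        with pytest.raises(ValueError):
            hk.select_k(x, k_range=range(1, 4))


@pytest.fixture(scope="module")
def clustered(small_cohort):
    _, volumes, _, truth = small_cohort
    masks = [m for _, m in volumes]
    fmaps = [hk.entropy_map(i, m) for i, m in volumes]
    pooled = hk.pool_cohort_features(fmaps)
    res = hk.kmeans_cluster(pooled.matrix, k=3, seed=4)
    maps = hk.label_habitats(res, pooled.patient_index, fmaps, masks)
    return volumes, truth, fmaps, pooled, res, maps


class TestHabitatMaps:
    def test_foreground_matches_mask_every_patient(self, clustered):
        volumes, _, _, _, _, maps = clustered
        for (_, msk), hmap in zip(volumes, maps):
            assert int((hmap.labels > 0).sum()) == msk.n_voxels
            np.testing.assert_array_equal(hmap.labels > 0, msk.labels > 0)

    def test_relabeling_invariance(self, clustered):
        volumes, _, fmaps, pooled, res, maps = clustered
        masks = [m for _, m in volumes]
        perm = np.array([2, 0, 1])
        permuted = hk.ClusteringResult(
            centroids=res.centroids[perm],
            assignment=np.argsort(perm)[res.assignment - 1] + 1,
            inertia=res.inertia, k=res.k,
        )
        maps2 = hk.label_habitats(permuted, pooled.patient_index, fmaps, masks)
        for a, b in zip(maps, maps2):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_majority_vote_accuracy_above_090(self, clustered):
        _, truth, fmaps, _, _, maps = clustered
        correct = total = 0
        for hmap, labels, fmap in zip(maps, truth.label_volumes, fmaps):
            pred = hmap.labels[fmap.indices]
            true = labels[fmap.indices]
            for j in np.unique(pred):
                sel = pred == j
                majority = np.bincount(true[sel]).argmax()
                correct += int((true[sel] == majority).sum())
                total += int(sel.sum())
        assert correct / total > 0.9

    def test_heldout_assignment_uses_frozen_centroids(self, clustered):
        volumes, _, fmaps, pooled, res, maps = clustered
        hmap = hk.assign_to_centroids(pooled, res, fmaps[0], volumes[0][1])
        # training patient re-assigned by nearest centroid agrees with the
        # canonical training labels except possibly boundary-of-cluster ties
        agree = (hmap.labels == maps[0].labels)[fmaps[0].indices].mean()
        assert agree > 0.99
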