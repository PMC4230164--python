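"""Sphere geometry, fold structure, pairwise CV classification, and the map."""

import numpy as np
import pytest
from sklearn.svm import SVC

from roamlight import (BetaImages, SearchlightConfig, classify_pair_cv,
                       leave_one_run_out_folds, searchlight_map, sphere_offsets)

VOX = (1.4, 1.4, 2.0)


class TestSphereOffsets:
    def test_radius_zero_is_center_only(self):
        offs = sphere_offsets(0.0, VOX)
        assert offs.shape == (1, 3) and (offs == 0).all()

    def test_anisotropic_voxels_exclude_far_z_neighbors(self):
        offs = {tuple(o) for o in sphere_offsets(1.4, VOX)}
        # z-neighbors sit 2.0 mm away and fall outside the 1.4-mm sphere
        assert offs == {(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)}

    def test_matches_exhaustive_enumeration_at_study_radius(self):
        offs = sphere_offsets(10.0, VOX)
        count = 0
        for i in range(-7, 8):          # floor(10 / 1.4) = 7
            for j in range(-7, 8):
                for k in range(-5, 6):  # floor(10 / 2.0) = 5
                    if (1.4 * i) ** 2 + (1.4 * j) ** 2 + (2.0 * k) ** 2 <= 100.0:
                        count += 1
        assert len(offs) == count

    def test_symmetric_under_negation(self):
        offs = {tuple(o) for o in sphere_offsets(5.0, VOX)}
        assert offs == {(-i, -j, -k) for i, j, k in offs}


class TestFolds:
    def test_eight_runs_give_eight_train_test_combinations(self):
        folds = leave_one_run_out_folds(range(8))
        assert len(folds) == 8
        for train, test in folds.folds:
            assert len(train) == 7 and test not in train

    def test_two_runs(self):
        folds = leave_one_run_out_folds([0, 1])
        assert folds.folds == (((1,), 0), ((0,), 1))

    def test_every_run_is_test_exactly_once(self):
        folds = leave_one_run_out_folds([3, 1, 4, 1 + 4])
        assert sorted(t for _, t in folds.folds) == [1, 3, 4, 5]

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ValueError):
            leave_one_run_out_folds([0])


def _vectors(rng, n_runs=8, dim=12, separation=0.0):
    out = {}
    for r in range(n_runs):
        out[(r, "face")] = rng.standard_normal(dim) + separation
        out[(r, "object")] = rng.standard_normal(dim) - separation
    return out


class TestClassifyPairCv:
    def test_separable_vectors_decode_perfectly(self, rng):
        vecs = _vectors(rng, separation=10.0)
        folds = leave_one_run_out_folds(range(8))
        assert classify_pair_cv(vecs, folds) == 1.0

    def test_fold_accuracies_are_discrete(self, rng):
        folds = leave_one_run_out_folds(range(4))
        for _ in range(25):
            acc = classify_pair_cv(_vectors(rng, n_runs=4, dim=3), folds)
            # mean of 4 fold accuracies, each in {0, 0.5, 1}
            assert (acc * 8) == pytest.approx(round(acc * 8), abs=1e-12)

    def test_exchangeable_vectors_decode_at_chance(self, rng):
        """Class labels carry no information -> accuracy approaches 50%."""
        folds = leave_one_run_out_folds(range(8))
        accs = [classify_pair_cv(_vectors(rng, dim=10), folds)
                for _ in range(200)]
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert np.mean(accs) == pytest.approx(0.5, abs=max(4 * se, 0.02))

    def test_label_swap_symmetry(self, rng):
        vecs = _vectors(rng, dim=6)
        swapped = {(r, {"face": "object", "object": "face"}[c]): v
                   for (r, c), v in vecs.items()}
        folds = leave_one_run_out_folds(range(8))
        assert classify_pair_cv(vecs, folds) == classify_pair_cv(swapped, folds)

    def test_nan_features_rejected(self, rng):
        vecs = _vectors(rng)
        vecs[(0, "face")] = np.full_like(vecs[(0, "face")], np.nan)
        with pytest.raises(ValueError, match="finite"):
            classify_pair_cv(vecs, leave_one_run_out_folds(range(8)))

    def test_dimension_mismatch_rejected(self, rng):
        vecs = _vectors(rng)
        vecs[(0, "face")] = np.zeros(3)
        with pytest.raises(ValueError, match="dimension"):
            classify_pair_cv(vecs, leave_one_run_out_folds(range(8)))


def _random_betas(rng, dims=(6, 6, 4), n_runs=4, signal=0.0, mask=None):
    mask = np.ones(dims, bool) if mask is None else mask
    data = rng.standard_normal((2, n_runs) + dims)
    if signal:
        bump = rng.standard_normal(dims)
        data[0] += signal * bump
        data[1] -= signal * bump
    return BetaImages(data=data, categories=("face", "object"), mask=mask,
                      voxel_size_mm=VOX)


def _naive_searchlight(betas, mask, radius_mm, C=1.0, min_vox=2):
    """Independent oracle: per-voxel loop + sklearn SVC over sphere features."""
    dims = mask.shape
    offs = sphere_offsets(radius_mm, VOX)
    n_runs = betas.data.shape[1]
    y = np.array([0] * n_runs + [1] * n_runs)
    out = np.full(dims, np.nan)
    for center in np.argwhere(mask):
        pos = center[None] + offs
        ok = np.all((pos >= 0) & (pos < np.array(dims)), axis=1)
        pos = pos[ok]
        pos = pos[mask[pos[:, 0], pos[:, 1], pos[:, 2]]]
        if len(pos) < min_vox:
            continue
        feats = betas.data[:, :, pos[:, 0], pos[:, 1], pos[:, 2]]
        X = np.concatenate([feats[0], feats[1]])  # face rows then object rows
        accs = []
        for test in range(n_runs):
            tr = [r for r in range(n_runs) if r != test]
            idx = tr + [r + n_runs for r in tr]
            clf = SVC(kernel="linear", C=C, tol=1e-6).fit(X[idx], y[idx])
            pred = clf.predict(X[[test, test + n_runs]])
            accs.append(np.mean(pred == [0, 1]))
        out[tuple(center)] = np.mean(accs)
    return out


class TestSearchlightMap:
    def test_equals_naive_triple_loop_oracle(self, rng):
        mask = rng.random((6, 6, 4)) > 0.15
        betas = _random_betas(rng, mask=mask)
        cfg = SearchlightConfig(radius_mm=3.0)
        ours = searchlight_map(betas, ("face", "object"), mask=mask, config=cfg)
        oracle = _naive_searchlight(betas, mask, 3.0)
        assert np.allclose(ours.data, oracle, atol=1e-12, equal_nan=True)

    def test_category_label_swap_leaves_map_unchanged(self, rng):
        betas = _random_betas(rng)
        a = searchlight_map(betas, ("face", "object"),
                            config=SearchlightConfig(radius_mm=3.0))
        b = searchlight_map(betas, ("object", "face"),
                            config=SearchlightConfig(radius_mm=3.0))
        assert np.array_equal(a.data, b.data, equal_nan=True)

    def test_single_voxel_mask_reduces_to_scalar_classification(self, rng):
        dims = (5, 5, 4)
        mask = np.zeros(dims, bool)
        mask[2, 2, 2] = True
        betas = _random_betas(rng, dims=dims, n_runs=8)
        betas.mask = mask
        cfg = SearchlightConfig(radius_mm=3.0, min_sphere_voxels=1)
        amap = searchlight_map(betas, ("face", "object"), mask=mask, config=cfg)
        assert np.isfinite(amap.data).sum() == 1
        feats = betas.data[:, :, 2, 2, 2]
        vecs = {(r, c): feats[ci, r] for ci, c in enumerate(("face", "object"))
                for r in range(8)}
        expected = classify_pair_cv(vecs, leave_one_run_out_folds(range(8)), cfg)
        assert amap.data[2, 2, 2] == pytest.approx(expected, abs=1e-12)

    def test_accuracy_values_bounded_and_nan_outside_mask(self, rng):
        mask = np.zeros((6, 6, 4), bool)
        mask[1:5, 1:5, 1:3] = True
        betas = _random_betas(rng, mask=mask)
        amap = searchlight_map(betas, ("face", "object"), mask=mask,
                               config=SearchlightConfig(radius_mm=3.0))
        inside = amap.data[mask]
        assert np.nanmin(inside) >= 0.0 and np.nanmax(inside) <= 1.0
        assert np.isnan(amap.data[~mask]).all()

    def test_information_monotone_in_pattern_amplitude(self, rng):
        """Mean in-mask accuracy does not decrease with implanted signal."""
        levels = [0.0, 0.4, 1.2]
        means = []
        for signal in levels:
            accs = []
            for seed in range(20):
                r = np.random.default_rng(seed)
                betas = _random_betas(r, dims=(5, 5, 4), n_runs=8, signal=signal)
                amap = searchlight_map(betas, ("face", "object"),
                                       config=SearchlightConfig(radius_mm=3.0))
                accs.append(np.nanmean(amap.data))
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(0.5, abs=0.05)

    def test_standardized_path_matches_plain_on_standardized_features(self, rng):
        # per-fold z-scoring flag runs the gather path; outputs stay bounded
        betas = _random_betas(rng, dims=(5, 5, 3))
        cfg = SearchlightConfig(radius_mm=3.0, standardize=True)
        amap = searchlight_map(betas, ("face", "object"), config=cfg)
        vals = amap.data[np.isfinite(amap.data)]
        assert len(vals) and (vals >= 0).all() and (vals <= 1).all()

    def test_empty_mask_rejected(self, rng):
        betas = _random_betas(rng)
        with pytest.raises(ValueError, match="empty mask"):
            searchlight_map(betas, ("face", "object"),
                            mask=np.zeros((6, 6, 4), bool))
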