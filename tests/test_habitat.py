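"""Local feature maps and population K-means habitat discovery."""

from itertools import permutations

import numpy as np
import pytest

import habitatbm as hb
from habitatbm.habitat import (
    CHANNEL_NAMES,
    HabitatModel,
    pairwise_consistency,
    subsample_voxels,
)


class TestLocalFeatures:
    def test_channel_count_is_nineteen(self, resampled_patient):
        _, _, _, fmap = resampled_patient
        assert fmap.features.shape[1] == 19
        assert len(fmap.channel_names) == 19

    def test_constant_image_degenerate_channels(self):
        vol = hb.Volume(np.full((9, 9, 9), 42.0))
        mask = hb.LabelMask(np.ones((9, 9, 9), dtype=np.int32))
        fmap = hb.local_features(vol, mask)
        idx = {n: i for i, n in enumerate(CHANNEL_NAMES)}
        f = fmap.features
        for ch in ("sd", "variance", "range", "entropy", "mad", "gradient_magnitude"):
            assert np.allclose(f[:, idx[ch]], 0.0), ch
        assert np.allclose(f[:, idx["mean"]], 42.0)
        assert np.allclose(f[:, idx["uniformity"]], 1.0)

    def test_channels_match_direct_formulas_on_enumerated_block(self):
        """For a single lesion voxel whose window covers a known 5x5x5 block,
        every channel equals a direct formula evaluation on the 125 values."""
        rng = np.random.default_rng(0)
        block = rng.uniform(10, 90, (5, 5, 5))
        vol = hb.Volume(block)
        mask_arr = np.zeros((5, 5, 5), dtype=np.int32)
        mask_arr[2, 2, 2] = 1
        fmap = hb.local_features(vol, hb.LabelMask(mask_arr))
        got = dict(zip(fmap.channel_names, fmap.features[0]))

        x = block.ravel()
        mean = x.mean()
        expected = {
            "mean": mean,
            "median": np.median(x),
            "sd": x.std(),
            "variance": x.var(),
            "min": x.min(),
            "max": x.max(),
            "range": x.max() - x.min(),
            "p10": np.percentile(x, 10),
            "p25": np.percentile(x, 25),
            "p75": np.percentile(x, 75),
            "p90": np.percentile(x, 90),
            "skewness": ((x - mean) ** 3).mean() / x.var() ** 1.5,
            "kurtosis": ((x - mean) ** 4).mean() / x.var() ** 2 - 3.0,
            "energy": (x**2).mean(),
            "mad": np.abs(x - mean).mean(),
            "rms": np.sqrt((x**2).mean()),
        }
        # 32-bin histogram entropy/uniformity over the window range
        lev = np.clip(np.floor((x - x.min()) / (x.max() - x.min()) * 32), 0, 31)
        p = np.bincount(lev.astype(int), minlength=32) / x.size
        expected["entropy"] = -(p[p > 0] * np.log2(p[p > 0])).sum()
        expected["uniformity"] = (p**2).sum()
        g = np.gradient(block, 1.0)
        expected["gradient_magnitude"] = np.sqrt(sum(a**2 for a in g)).mean()
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, abs=1e-9), name

    def test_window_validation(self, resampled_patient):
        _, vol, mask, _ = resampled_patient
        with pytest.raises(ValueError):
            hb.local_features(vol, mask, window=4)
        with pytest.raises(ValueError):
            hb.local_features(vol, mask, window=1)


class TestSelectK:
    def test_recovers_three_separated_blobs(self):
        # centers 30 noise-SDs apart: in 19-D the within-cluster spread is
        # ~sqrt(2*19) ~ 6.2, so this separation puts the silhouette above 0.8
        # (10-SD separation only reaches ~0.6 at this dimensionality)
        centers = np.zeros((3, 19))
        centers[0, 0], centers[1, 1], centers[2, 2] = 30, 30, 30
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 1.0, (1000, 19)) for c in centers])
        k, diag = hb.select_k(X, k_range=(3, 10), n_seeds=10)
        assert k == 3
        assert diag[3]["silhouette"] > 0.8

    def test_uniform_data_flagged_weak(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(600, 19))
        _, diag = hb.select_k(X, k_range=(3, 6), n_seeds=3)
        assert all(diag[k]["silhouette"] < 0.5 for k in range(3, 7))
        assert diag.get("weak_structure") is True

    def test_k_range_validation(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(ValueError):
            hb.select_k(X, k_range=(3, 10))


class TestFitAssign:
    def test_consistency_one_for_permuted_labelings(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 500)
        perm = np.array([2, 0, 1])
        assert pairwise_consistency([a, perm[a]], k=3) == pytest.approx(1.0)

    def test_random_labelings_match_monte_carlo_expectation(self):
        """Independent uniform labelings: consistency equals the
        best-permutation matched-overlap expectation (Monte-Carlo oracle)."""
        rng = np.random.default_rng(2)
        n = 4000
        got = pairwise_consistency([rng.integers(0, 3, n) for _ in range(4)], k=3)
        # oracle: brute-force maximum over the 6 label permutations
        oracle = []
        for _ in range(12):
            a, b = rng.integers(0, 3, n), rng.integers(0, 3, n)
            oracle.append(max((np.array(p)[a] == b).mean()
                              for p in permutations(range(3))))
        assert got == pytest.approx(np.mean(oracle), abs=0.02)

    def test_default_cohort_consistency_exceeds_90(self, small_cohort):
        _, pats = small_cohort
        maps = []
        for p in pats:
            vol, mask = hb.resample_isotropic(p.volume, p.mask)
            maps.append(hb.local_features(vol, mask))
        model = hb.fit_habitats(maps, k=3, n_seeds=10, subsample_per_patient=300, seed=0)
        assert model.consistency > 0.90

    def test_voxel_at_center_gets_its_label_and_tiebreak(self):
        model = HabitatModel(
            k=2,
            centers=np.array([[0.0, 0.0], [1.0, 1.0]]),
            scaler_mean=np.zeros(2),
            scaler_sd=np.ones(2),
            channel_names=("mean", "sd"),
        )
        fmap = hb.LocalFeatureMap(
            features=np.array([[1.0, 1.0], [0.0, 0.0], [0.5, 0.5]]),
            voxel_indices=np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]]),
            channel_names=("mean", "sd"),
            grid_shape=(1, 1, 3),
            spacing=(1.0, 1.0, 1.0),
            origin=(0.0, 0.0, 0.0),
            window=5,
        )
        out = hb.assign_habitats(model, fmap)
        assert out.values[0, 0, 0] == 2  # exactly at center 2
        assert out.values[0, 0, 1] == 1  # exactly at center 1
        assert out.values[0, 0, 2] == 1  # equidistant -> lowest label

    def test_channel_mismatch_rejected(self):
        model = HabitatModel(
            k=2, centers=np.zeros((2, 2)), scaler_mean=np.zeros(2),
            scaler_sd=np.ones(2), channel_names=("mean", "nonexistent"),
        )
        fmap = hb.LocalFeatureMap(
            features=np.zeros((1, 2)), voxel_indices=np.array([[0, 0, 0]]),
            channel_names=("mean", "sd"), grid_shape=(1, 1, 1),
            spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), window=5,
        )
        with pytest.raises(ValueError):
            hb.assign_habitats(model, fmap)

    def test_truth_recovery_on_separable_two_phenotype_lesions(self):
        """Separable phenotypes: assignment recovers generating labels at
        > 0.9 best-permutation accuracy."""
        from habitatbm.synthdata import PhenotypeSpec

        phen = [
            PhenotypeSpec(1, 180.0, 10.0, 0.5, 0.55),
            PhenotypeSpec(2, 100.0, 10.0, 0.5, 0.45),
        ]
        cfg = hb.CohortConfig(
            n_patients=3, n_phenotypes=2, phenotypes=phen,
            lesion_diameter_mm=(22, 28), bias_amplitude=0.0,
            native_spacing=(0.9, 0.9, 1.0), transition_mm=4.0, seed=5,
        )
        pats = hb.generate_cohort(cfg)
        maps, store = [], []
        for p in pats:
            vol, mask = hb.resample_isotropic(p.volume, p.mask)
            maps.append(hb.local_features(vol, mask))
            store.append(p)
        model = hb.fit_habitats(maps, k=2, n_seeds=5, subsample_per_patient=500, seed=0)
        for p, fm in zip(store, maps):
            hmap = hb.assign_habitats(model, fm)
            _, truth_r = hb.resample_isotropic(p.volume, p.truth_labels)
            t = truth_r.values[tuple(fm.voxel_indices.T)]
            h = hmap.values[tuple(fm.voxel_indices.T)]
            ok = t > 0
            acc = max((np.array(perm)[h[ok] - 1] == t[ok]).mean()
                      for perm in permutations((1, 2)))
            assert acc > 0.9

    def test_train_only_fitting(self, small_cohort):
        """Scaler and centers depend only on training voxels."""
        _, pats = small_cohort
        maps = []
        for p in pats[:4]:
            vol, mask = hb.resample_isotropic(p.volume, p.mask)
            maps.append(hb.local_features(vol, mask))
        m1 = hb.fit_habitats(maps, k=3, n_seeds=3, subsample_per_patient=200, seed=0)
        m2 = hb.fit_habitats(maps, k=3, n_seeds=3, subsample_per_patient=200, seed=0)
        assert np.array_equal(m1.centers, m2.centers)
        assert np.array_equal(m1.scaler_mean, m2.scaler_mean)

    def test_model_json_roundtrip(self, small_cohort):
        _, pats = small_cohort
        vol, mask = hb.resample_isotropic(pats[0].volume, pats[0].mask)
        fmap = hb.local_features(vol, mask)
        model = hb.fit_habitats([fmap], k=2, n_seeds=2, subsample_per_patient=200, seed=0)
        back = HabitatModel.from_json(model.to_json())
        assert np.allclose(back.centers, model.centers)
        a = hb.assign_habitats(model, fmap)
        b = hb.assign_habitats(back, fmap)
        assert np.array_equal(a.values, b.values)
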