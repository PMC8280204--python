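import numpy as np
import pytest

from perifw.patches import Patch, PatchSet
from perifw.texture import (GABOR_ORIENTATIONS_DEG, GABOR_WAVELENGTHS,
                            N_GRAY_LEVELS, RandomForestConfig,
                            TextureRfClassifier, extract_features,
                            gabor_feature_vector, pca_reduce,
                            radiomic_feature_vector, rf_train_predict)


def _rand_patch(seed=0):
    return np.random.default_rng(seed).random((16, 16))


def _checkerboard():
    """2-level checkerboard at exact gray-level bin centers."""
    lo, hi = 0.5 / N_GRAY_LEVELS, 15.5 / N_GRAY_LEVELS
    img = np.full((16, 16), lo)
    img[::2, 1::2] = hi
    img[1::2, ::2] = hi
    return img


def _glcm_contrast_oracle(levels, dx, dy):
    """Enumerate all ordered voxel pairs at offset (dx, dy) and average the
    squared level difference (symmetric normalized GLCM contrast)."""
    h, w = levels.shape
    diffs = []
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dy, j + dx
            if 0 <= i2 < h and 0 <= j2 < w:
                diffs.append((int(levels[i, j]) - int(levels[i2, j2])) ** 2)
    return np.mean(diffs)


class TestGaborFeatures:
    def test_feature_count_and_names(self):
        fv = gabor_feature_vector(_rand_patch())
        assert len(fv.values) == len(GABOR_WAVELENGTHS) * \
            len(GABOR_ORIENTATIONS_DEG) * 2 == 32
        assert fv.extractor == "gabor"

    def test_constant_patch_responds_zero(self):
        fv = gabor_feature_vector(np.full((16, 16), 0.37))
        assert np.all(np.abs(fv.values) <= 1e-6)

    def test_deterministic_bit_for_bit(self):
        a = gabor_feature_vector(_rand_patch(3))
        b = gabor_feature_vector(_rand_patch(3))
        assert np.array_equal(a.values, b.values)

    def test_rotation_permutes_orientation_blocks(self):
        """Rotating the patch by 90 degrees maps each orientation's features
        onto the 90-degree-shifted orientation."""
        img = _rand_patch(5)
        f = gabor_feature_vector(img).values.reshape(4, 4, 2)     # wl, th, stat
        f_rot = gabor_feature_vector(np.rot90(img)).values.reshape(4, 4, 2)
        # theta + 90deg: orientation index shifts by 2 (0,45,90,135)
        assert np.allclose(f_rot, np.roll(f, shift=-2, axis=1), atol=1e-6)

    def test_all_nan_patch_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            gabor_feature_vector(np.full((16, 16), np.nan))


class TestRadiomicFeatures:
    def test_constant_patch_degenerate_values(self):
        fv = radiomic_feature_vector(np.full((16, 16), 0.5))
        d = dict(zip(fv.names, fv.values))
        assert fv.degenerate
        assert d["fo_variance"] == 0.0
        assert d["fo_entropy"] == 0.0
        assert d["glcm_contrast"] == 0.0
        assert d["glcm_correlation"] == 0.0

    def test_checkerboard_glcm_contrast_matches_enumeration(self):
        img = _checkerboard()
        levels = np.clip((img * N_GRAY_LEVELS).astype(int), 0, 15)
        # our feature averages distance-1 offsets at 0/45/90/135 degrees
        expected = np.mean([
            _glcm_contrast_oracle(levels, 1, 0),    # 0 deg
            _glcm_contrast_oracle(levels, 1, -1),   # 45 deg
            _glcm_contrast_oracle(levels, 0, -1),   # 90 deg
            _glcm_contrast_oracle(levels, -1, -1),  # 135 deg
        ])
        fv = radiomic_feature_vector(img)
        d = dict(zip(fv.names, fv.values))
        assert d["glcm_contrast"] == pytest.approx(expected, abs=1e-10)
        # horizontal/vertical neighbors always differ by 15 levels,
        # diagonal neighbors never differ
        assert expected == pytest.approx((225 + 225) / 4)

    def test_intensity_inversion_preserves_glcm_energy(self):
        rng = np.random.default_rng(7)
        img = (rng.integers(0, 16, (16, 16)) + 0.5) / N_GRAY_LEVELS
        fv1 = radiomic_feature_vector(img)
        d1 = dict(zip(fv1.names, fv1.values))
        inv = 1.0 - img
        d2 = dict(zip(radiomic_feature_vector(inv).names,
                      radiomic_feature_vector(inv).values))
        assert d1["glcm_energy"] == pytest.approx(d2["glcm_energy"], abs=1e-12)

    def test_deterministic_and_finite(self):
        a = radiomic_feature_vector(_rand_patch(1))
        b = radiomic_feature_vector(_rand_patch(1))
        assert np.array_equal(a.values, b.values)
        assert np.all(np.isfinite(a.values))

    def test_extract_features_matrix(self):
        patches = PatchSet([
            Patch(values=_rand_patch(i), origin=(0, 0, i), subject_id="s",
                  label="glioblastoma", map_kind="FW-VF") for i in range(4)],
            "FW-VF")
        X, names = extract_features(patches, "radiomic")
        assert X.shape == (4, len(names))
        assert np.all(np.isfinite(X))


class TestPca:
    def test_exact_rank_two_data(self):
        rng = np.random.default_rng(0)
        basis = rng.random((2, 10))
        X = rng.random((40, 2)) @ basis
        _, tf = pca_reduce(X, 0.98)
        assert tf.retained <= 2

    def test_full_variance_target_keeps_full_rank(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 5))
        _, tf = pca_reduce(X, 1.0)
        assert tf.retained == 5

    def test_explained_variance_bookkeeping(self):
        X = np.random.default_rng(2).random((30, 8))
        _, tf = pca_reduce(X)
        assert abs(tf.explained_variance_ratio.sum() - 1.0) < 1e-10
        cum = np.cumsum(tf.explained_variance_ratio)
        assert cum[tf.retained - 1] >= 0.98 - 1e-12

    def test_reconstruction_error_within_residual_variance(self):
        rng = np.random.default_rng(3)
        X = rng.random((50, 12))
        Z, tf = pca_reduce(X, 0.98)
        X_hat = Z @ tf.components + tf.mean
        resid = ((X - X_hat) ** 2).sum()
        total = ((X - X.mean(axis=0)) ** 2).sum()
        assert resid / total <= 0.02 + 1e-12

    def test_apply_never_refits(self):
        rng = np.random.default_rng(4)
        X = rng.random((30, 6))
        _, tf = pca_reduce(X)
        before = tf.components.copy()
        tf.apply(rng.random((100, 6)) * 50)
        assert np.array_equal(tf.components, before)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_reduce(np.ones((10, 4)))


class TestRandomForest:
    def test_memorizes_separable_toy_data(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(0, 0.1, (20, 5)), rng.normal(3, 0.1, (20, 5))]
        y = np.array(["glioblastoma"] * 20 + ["metastasis"] * 20)
        probs = rf_train_predict(X, y, X, RandomForestConfig(seed=0))
        pred = np.where(probs[:, 0] > 0.5, "glioblastoma", "metastasis")
        assert np.array_equal(pred, y)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 4))
        y = np.array(["glioblastoma", "metastasis"] * 15)
        a = rf_train_predict(X, y, X, RandomForestConfig(seed=5))
        b = rf_train_predict(X, y, X, RandomForestConfig(seed=5))
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        X = np.random.default_rng(2).random((10, 3))
        y = np.array(["glioblastoma"] * 10)
        with pytest.raises(ValueError, match="both classes"):
            rf_train_predict(X, y, X)


class TestTextureRfClassifier:
    def test_pipeline_fit_predict(self):
        rng = np.random.default_rng(0)
        patches = []
        for i in range(12):
            for label, scale in (("glioblastoma", 0.45), ("metastasis", 0.1)):
                vals = np.clip(0.5 + scale * rng.standard_normal((16, 16)), 0, 1)
                patches.append(Patch(values=vals, origin=(0, 0, i),
                                     subject_id=f"s{i}", label=label,
                                     map_kind="FW-VF"))
        ps = PatchSet(patches, "FW-VF")
        clf = TextureRfClassifier("radiomic", seed=0).fit(ps)
        probs = clf.predict_proba(ps)
        assert probs.shape == (len(ps), 2)
        assert np.allclose(probs.sum(axis=1), 1.0)
        pred = probs.argmax(axis=1)
        truth = (ps.labels == "metastasis").astype(int)
        assert (pred == truth).mean() > 0.9
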