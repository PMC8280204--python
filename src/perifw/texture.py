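"""Texture baselines: Gabor filter-bank and radiomic features + random forest.

These reproduce the comparison classifiers: hand-designed texture features
extracted per 16x16 patch, reduced by PCA to the components covering 98
percent of the training variance, and classified with a random forest.

Gabor bank: 4 wavelengths {2, 4, 8, 16} voxels x 4 orientations
{0, 45, 90, 135} degrees, sigma = 0.56 * wavelength, unit aspect ratio.
Each filter contributes the mean and standard deviation of its response
magnitude on the mean-subtracted patch (so a constant patch responds zero),
giving 32 features.

Radiomic set (restricted to what is meaningful on a fixed-size 16x16
single-map patch; shape/size descriptors are constant here and excluded):
first-order intensity statistics, gray-level co-occurrence (GLCM) features
at distance 1 averaged over 4 directions, and gray-level run-length (GLRLM)
features averaged over 4 directions, all on a 16-level discretization of the
map's fixed physical range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import gabor_kernel
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from .patches import Patch, PatchSet

__all__ = ["FeatureVector", "PcaTransform", "gabor_feature_vector",
           "radiomic_feature_vector", "extract_features", "pca_reduce",
           "rf_train_predict", "TextureRfClassifier",
           "GABOR_WAVELENGTHS", "GABOR_ORIENTATIONS_DEG", "N_GRAY_LEVELS"]

GABOR_WAVELENGTHS = (2.0, 4.0, 8.0, 16.0)
GABOR_ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)
_GABOR_SIGMA_FACTOR = 0.56
N_GRAY_LEVELS = 16
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class FeatureVector:
    """Fixed-length named features from one patch."""

    values: np.ndarray
    names: tuple[str, ...]
    extractor: str                       # 'gabor' or 'radiomic'
    subject_id: str = ""
    origin: tuple[int, int, int] = (0, 0, 0)
    degenerate: bool = False             # e.g. constant patch

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature values and names differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values left the extractor")


def _patch_plane(patch: Patch | np.ndarray) -> np.ndarray:
    vals = patch.values if isinstance(patch, Patch) else np.asarray(patch, float)
    if vals.ndim == 3:
        raise ValueError("texture features are per-channel; pass one plane")
    return np.asarray(vals, dtype=float)


_KERNEL_FFT_CACHE: dict[tuple[float, float, int], np.ndarray] = {}


def _wrapped_kernel_fft(wl: float, th: float, size: int) -> np.ndarray:
    """FFT of the complex Gabor kernel wrapped onto the patch grid, so that
    multiplication in the frequency domain realizes wrap-around filtering."""
    key = (wl, th, size)
    if key not in _KERNEL_FFT_CACHE:
        kern = gabor_kernel(frequency=1.0 / wl, theta=np.deg2rad(th),
                            sigma_x=_GABOR_SIGMA_FACTOR * wl,
                            sigma_y=_GABOR_SIGMA_FACTOR * wl)
        kh, kw = kern.shape
        cy, cx = kh // 2, kw // 2
        wrapped = np.zeros((size, size), dtype=complex)
        rows = (np.arange(kh) - cy) % size
        cols = (np.arange(kw) - cx) % size
        np.add.at(wrapped, (rows[:, None], cols[None, :]), kern)
        _KERNEL_FFT_CACHE[key] = np.fft.fft2(wrapped)
    return _KERNEL_FFT_CACHE[key]


def gabor_feature_vector(patch: Patch | np.ndarray) -> FeatureVector:
    """Mean and std of each Gabor filter's response magnitude (32 features).

    The patch is mean-subtracted first (a constant patch responds zero), and
    filtering is wrap-around on the square window — realized as a cached
    frequency-domain product — which keeps the orientation blocks exactly
    equivariant under 90-degree patch rotation.
    """
    img = _patch_plane(patch)
    if np.isnan(img).all():
        raise ValueError("degenerate all-NaN patch")
    img = img - img.mean()
    size = img.shape[0]
    img_fft = np.fft.fft2(img)
    names: list[str] = []
    vals: list[float] = []
    for wl in GABOR_WAVELENGTHS:
        for th in GABOR_ORIENTATIONS_DEG:
            resp = np.fft.ifft2(img_fft * _wrapped_kernel_fft(wl, th, size))
            mag = np.abs(resp)
            names += [f"gabor_wl{wl:g}_th{th:g}_mean",
                      f"gabor_wl{wl:g}_th{th:g}_std"]
            vals += [float(mag.mean()), float(mag.std())]
    meta = _patch_meta(patch)
    return FeatureVector(np.array(vals), tuple(names), "gabor", **meta)


def _patch_meta(patch) -> dict:
    if isinstance(patch, Patch):
        return {"subject_id": patch.subject_id, "origin": patch.origin}
    return {}


def _discretize(img: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Fixed [0, 1] range binning into n_levels gray levels."""
    return np.clip((img * n_levels).astype(int), 0, n_levels - 1).astype(np.uint8)


def _glrlm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Gray-level run-length matrix averaged over 4 directions.

    Returns (n_levels, max_run) with counts of maximal runs."""
    h, w = levels.shape
    max_run = max(h, w)
    acc = np.zeros((n_levels, max_run))

    def runs(lines):
        out = np.zeros((n_levels, max_run))
        for line in lines:
            if len(line) == 0:
                continue
            start = 0
            for i in range(1, len(line) + 1):
                if i == len(line) or line[i] != line[start]:
                    out[line[start], min(i - start, max_run) - 1] += 1
                    start = i
        return out

    acc += runs([levels[i, :] for i in range(h)])                     # 0 deg
    acc += runs([levels[:, j] for j in range(w)])                     # 90 deg
    acc += runs([np.diagonal(levels, k) for k in range(-h + 1, w)])   # 45 deg
    flipped = levels[:, ::-1]
    acc += runs([np.diagonal(flipped, k) for k in range(-h + 1, w)])  # 135 deg
    return acc / 4.0


def radiomic_feature_vector(patch: Patch | np.ndarray) -> FeatureVector:
    """First-order + GLCM + GLRLM features (19 values) of one patch.

    A constant patch is degenerate: skewness, kurtosis, and GLCM correlation
    are defined as 0 and the vector is flagged.
    """
    img = _patch_plane(patch)
    if np.isnan(img).all():
        raise ValueError("degenerate all-NaN patch")
    n = img.size
    var = float(img.var())
    degenerate = var < 1e-24

    # first-order statistics on the normalized intensities
    hist, _ = np.histogram(img, bins=N_GRAY_LEVELS, range=(0.0, 1.0))
    p = hist / n
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    first = {
        "fo_mean": float(img.mean()),
        "fo_variance": var,
        "fo_skewness": 0.0 if degenerate else float(stats.skew(img.ravel())),
        "fo_kurtosis": 0.0 if degenerate else float(stats.kurtosis(img.ravel())),
        "fo_entropy": entropy,
        "fo_energy": float((img ** 2).sum() / n),
        "fo_p10": float(np.percentile(img, 10)),
        "fo_median": float(np.median(img)),
        "fo_p90": float(np.percentile(img, 90)),
        "fo_range": float(img.max() - img.min()),
    }

    levels = _discretize(img)
    glcm = graycomatrix(levels, distances=[1], angles=list(_GLCM_ANGLES),
                        levels=N_GRAY_LEVELS, symmetric=True, normed=True)
    glcm_feats = {}
    for prop in ("contrast", "correlation", "energy", "homogeneity"):
        v = graycoprops(glcm, prop)[0]      # (n_angles,)
        glcm_feats[f"glcm_{prop}"] = float(v.mean())
    if levels.min() == levels.max():
        glcm_feats["glcm_correlation"] = 0.0   # degenerate variance

    rlm = _glrlm(levels, N_GRAY_LEVELS)
    n_runs = rlm.sum()
    j = np.arange(1, rlm.shape[1] + 1)
    pr = rlm.sum(axis=0)       # runs per length
    pg = rlm.sum(axis=1)       # runs per gray level
    glrlm_feats = {
        "glrlm_sre": float((pr / j ** 2).sum() / n_runs),
        "glrlm_lre": float((pr * j ** 2).sum() / n_runs),
        "glrlm_gln": float((pg ** 2).sum() / n_runs),
        "glrlm_rln": float((pr ** 2).sum() / n_runs),
        "glrlm_rp": float(n_runs / n),
    }

    feats = {**first, **glcm_feats, **glrlm_feats}
    meta = _patch_meta(patch)
    return FeatureVector(np.array(list(feats.values())), tuple(feats),
                         "radiomic", degenerate=degenerate, **meta)


_EXTRACTORS = {"gabor": gabor_feature_vector, "radiomic": radiomic_feature_vector}


def extract_features(patches: PatchSet, extractor: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature matrix (n_patches, n_features) for a whole patch set.

    Multi-channel patches are handled per channel and concatenated."""
    fn = _EXTRACTORS[extractor]
    rows, names = [], None
    for p in patches:
        planes = [p.values] if p.values.ndim == 2 else [
            p.values[..., c] for c in range(p.values.shape[2])]
        vecs = [fn(pl) for pl in planes]
        row = np.concatenate([v.values for v in vecs])
        if names is None:
            if len(planes) == 1:
                names = vecs[0].names
            else:
                names = tuple(f"ch{c}_{nm}" for c, v in enumerate(vecs)
                              for nm in v.names)
        rows.append(row)
    return np.asarray(rows), names or ()


def features_frame(patches: PatchSet, extractor: str):
    """Named-column feature matrix for CSV export."""
    import pandas as pd
    X, names = extract_features(patches, extractor)
    df = pd.DataFrame(X, columns=list(names))
    df.insert(0, "subject_id", patches.subject_ids)
    df.insert(1, "label", patches.labels)
    return df


@dataclass
class PcaTransform:
    """A fitted PCA basis truncated at the target explained variance."""

    components: np.ndarray               # (retained, p)
    mean: np.ndarray                     # (p,)
    explained_variance_ratio: np.ndarray  # all components
    retained: int
    variance_target: float

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Project held-out data; never refits the basis."""
        return (np.asarray(X, float) - self.mean) @ self.components.T


def pca_reduce(X: np.ndarray, variance_target: float = 0.98
               ) -> tuple[np.ndarray, PcaTransform]:
    """Reduce to the smallest component count whose cumulative explained
    variance reaches ``variance_target`` (fit on training data only)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if float(X.var(axis=0).sum()) <= 0:
        raise ValueError("feature matrix has zero variance")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    retained = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
    retained = min(retained, len(evr))
    tf = PcaTransform(components=pca.components_[:retained].copy(),
                      mean=pca.mean_.copy(),
                      explained_variance_ratio=evr.copy(),
                      retained=retained, variance_target=variance_target)
    return scores[:, :retained], tf


@dataclass(frozen=True)
class RandomForestConfig:
    n_estimators: int = 500
    max_features: str = "sqrt"
    seed: int = 0


def rf_train_predict(X_train: np.ndarray, y_train: np.ndarray,
                     X_test: np.ndarray,
                     config: RandomForestConfig = RandomForestConfig()
                     ) -> np.ndarray:
    """Random-forest class probabilities on the test rows.

    ``y_train`` holds class-name strings; the returned columns follow the
    canonical (glioblastoma, metastasis) order."""
    from .cnn import CLASSES
    y_train = np.asarray(y_train)
    present = set(np.unique(y_train))
    if len(present) < 2:
        raise ValueError("random forest training needs both classes")
    clf = RandomForestClassifier(n_estimators=config.n_estimators,
                                 max_features=config.max_features,
                                 random_state=config.seed)
    clf.fit(X_train, y_train)
    probs = clf.predict_proba(X_test)
    order = [list(clf.classes_).index(c) for c in CLASSES]
    return probs[:, order]


class TextureRfClassifier:
    """Feature-extractor + PCA(98%) + random-forest pipeline over PatchSets.

    Mirrors the CNN classifier's fit/predict interface so both can be run
    through the same cross-validation driver.
    """

    def __init__(self, extractor: str, variance_target: float = 0.98,
                 rf_config: RandomForestConfig | None = None, seed: int = 0):
        if extractor not in _EXTRACTORS:
            raise ValueError(f"unknown extractor {extractor!r}")
        self.extractor = extractor
        self.variance_target = variance_target
        self.rf_config = rf_config or RandomForestConfig(seed=seed)
        self._pca: PcaTransform | None = None
        self._clf: RandomForestClassifier | None = None

    def fit(self, patches: PatchSet) -> "TextureRfClassifier":
        from .cnn import CLASSES
        X, _ = extract_features(patches, self.extractor)
        y = patches.labels
        if len(set(y)) < 2:
            raise ValueError("training needs both classes")
        Xr, self._pca = pca_reduce(X, self.variance_target)
        self._clf = RandomForestClassifier(
            n_estimators=self.rf_config.n_estimators,
            max_features=self.rf_config.max_features,
            random_state=self.rf_config.seed)
        self._clf.fit(Xr, y)
        self._order = [list(self._clf.classes_).index(c) for c in CLASSES]
        return self

    def predict_proba(self, patches: PatchSet) -> np.ndarray:
        if self._clf is None or self._pca is None:
            raise RuntimeError("classifier is not fitted")
        X, _ = extract_features(patches, self.extractor)
        Xr = self._pca.apply(X)
        return self._clf.predict_proba(Xr)[:, self._order]
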