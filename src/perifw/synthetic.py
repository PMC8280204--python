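"""Synthetic phantom cohorts with class-distinct peritumoral free-water texture.

Real glioblastoma/metastasis cohorts are IRB-restricted, so this module
generates the study's inputs: per-subject brain/tumor/edema masks, a
ground-truth free-water volume-fraction (FW-VF) field, ground-truth tissue
tensors, and simulated single-shell DWI.

The biological contrast emulated is vasogenic versus infiltrative edema:

* metastasis — peritumoral edema dominated by acellular fluid: high mean
  FW-VF, spatially smooth (long correlation length, low amplitude);
* glioblastoma — edema infiltrated by tumor cells: lower mean FW-VF with
  short-correlation-length mottling and a radial trend away from the tumor
  boundary (most infiltration, hence least free water, next to the tumor).

Texture is a Gaussian random field made by smoothing white noise with a
Gaussian kernel of the configured correlation length; the field is de-meaned
and unit-normalized over the edema before scaling, so the realized edema mean
tracks the configured class mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .dwi import DWIVolume, save_map
from .gradients import GradientTable, default_gradient_table
from .tensor import ScalarMap, TensorField

__all__ = ["PhantomParams", "SyntheticSubject", "make_phantom", "simulate_dwi",
           "make_cohort", "generate_cohort", "CLASSES"]

CLASSES = ("glioblastoma", "metastasis")

#: per-class edema texture defaults: mean FW-VF, correlation length (mm),
#: heterogeneity amplitude (FW-VF units), radial gradient amplitude
CLASS_TEXTURE = {
    "glioblastoma": dict(edema_f_mean=0.55, texture_corr_len_mm=4.0,
                         heterogeneity_amp=0.12, radial_gradient_amp=0.10),
    "metastasis": dict(edema_f_mean=0.80, texture_corr_len_mm=15.0,
                       heterogeneity_amp=0.03, radial_gradient_amp=0.0),
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, texture, and acquisition parameters of one phantom subject."""

    label: str = "glioblastoma"
    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.72, 1.72, 3.0)
    tumor_radius_mm: tuple[float, float] = (8.0, 12.0)
    edema_thickness_mm: tuple[float, float] = (10.0, 16.0)
    edema_f_mean: float = 0.55
    texture_corr_len_mm: float = 4.0
    heterogeneity_amp: float = 0.12
    radial_gradient_amp: float = 0.10
    background_f: float = 0.10
    tumor_f: float = 0.30
    tissue_evals: tuple[float, float, float] = (1.5e-3, 0.4e-3, 0.4e-3)
    edema_tissue_evals: tuple[float, float, float] = (1.2e-3, 0.5e-3, 0.5e-3)
    tumor_tissue_evals: tuple[float, float, float] = (1.0e-3, 1.0e-3, 1.0e-3)
    second_lesion_prob: float = 0.1
    snr: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shape", "spacing", "tumor_radius_mm", "edema_thickness_mm",
                     "tissue_evals", "edema_tissue_evals", "tumor_tissue_evals"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}")
        for v in (self.edema_f_mean, self.background_f, self.tumor_f):
            if not 0.0 <= v <= 1.0:
                raise ValueError("volume fractions must lie in [0, 1]")
        if self.heterogeneity_amp < 0:
            raise ValueError("heterogeneity amplitude must be non-negative")

    @classmethod
    def for_class(cls, label: str, seed: int = 0, **overrides) -> "PhantomParams":
        """Class defaults (vasogenic vs infiltrative texture) plus overrides."""
        kw = dict(CLASS_TEXTURE[label])
        kw.update(overrides)
        return cls(label=label, seed=seed, **kw)


@dataclass
class SyntheticSubject:
    """One phantom: masks, ground-truth FW-VF and tissue tensors, class label."""

    brain: np.ndarray
    tumor: np.ndarray
    edema: np.ndarray
    truth_f: ScalarMap
    truth_tensors: TensorField
    label: str
    subject_id: str
    lesion_count: int
    params: PhantomParams

    def __post_init__(self) -> None:
        if (self.tumor & ~self.brain).any() or (self.edema & ~self.brain).any():
            raise ValueError("tumor and edema must lie inside the brain mask")
        if (self.tumor & self.edema).any():
            raise ValueError("tumor and edema masks must be disjoint")


def _voxel_grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _grf(shape, spacing, corr_len_mm, rng) -> np.ndarray:
    """Gaussian random field: white noise smoothed at the correlation length."""
    noise = rng.standard_normal(shape)
    sigma = [max(corr_len_mm / s, 1e-6) for s in spacing]
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")


def make_phantom(params: PhantomParams, subject_id: str = "sub-000") -> SyntheticSubject:
    """Build one phantom subject, deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    shape, spacing = params.shape, params.spacing
    X, Y, Z = _voxel_grid_mm(shape, spacing)
    fov = [n * s for n, s in zip(shape, spacing)]
    center = [f / 2 for f in fov]
    semi = [0.45 * f for f in fov]
    norm_r = np.sqrt(((X - center[0]) / semi[0]) ** 2 +
                     ((Y - center[1]) / semi[1]) ** 2 +
                     ((Z - center[2]) / semi[2]) ** 2)
    brain = norm_r <= 1.0

    max_feasible = min(semi) * 0.9
    if params.tumor_radius_mm[0] > max_feasible:
        raise ValueError("tumor radius too large for the grid")

    n_lesions = 1 + int(rng.random() < params.second_lesion_prob)
    tumor = np.zeros(shape, dtype=bool)
    edema = np.zeros(shape, dtype=bool)
    thicknesses = []
    placed = 0
    for _ in range(n_lesions):
        radius = rng.uniform(*params.tumor_radius_mm)
        thickness = rng.uniform(*params.edema_thickness_mm)
        for _attempt in range(200):
            # candidate centers inside the inner half of the brain ellipsoid
            c = [rng.uniform(0.25 * f, 0.75 * f) for f in fov]
            d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
            cand_tumor = d <= radius
            cand_shell = (d <= radius + thickness) & ~cand_tumor
            if not cand_tumor.any():
                continue
            if (cand_tumor & ~brain).any():
                continue  # tumor must sit fully inside the brain
            if ((cand_tumor | cand_shell) & (tumor | edema)).any():
                continue  # keep lesions disjoint
            tumor |= cand_tumor
            edema |= cand_shell
            thicknesses.append(thickness)
            placed += 1
            break
        else:
            if placed == 0:
                raise ValueError("could not place a tumor of the requested size")
    edema &= brain
    edema &= ~tumor

    # --- ground-truth free-water field -------------------------------------
    f = np.full(shape, 0.0)
    f[brain] = params.background_f
    # mild shared background texture so healthy brain is not a constant cue
    bg_tex = _grf(shape, spacing, 6.0, rng)
    bg_tex /= max(bg_tex[brain].std(), 1e-12)
    f[brain] += 0.02 * bg_tex[brain]
    f[tumor] = params.tumor_f

    if edema.any():
        tex = _grf(shape, spacing, params.texture_corr_len_mm, rng)
        tex_e = tex[edema]
        tex_e = (tex_e - tex_e.mean()) / max(tex_e.std(), 1e-12)
        dist = ndimage.distance_transform_edt(~tumor, sampling=spacing)
        mean_th = float(np.mean(thicknesses)) if thicknesses else 1.0
        radial = np.clip(dist[edema] / mean_th, 0.0, 1.0)
        radial -= radial.mean()
        f[edema] = (params.edema_f_mean
                    + params.radial_gradient_amp * radial
                    + params.heterogeneity_amp * tex_e)
    f = np.clip(f, 0.0, 1.0)

    # --- ground-truth tissue tensors ----------------------------------------
    tensors = np.zeros(shape + (6,))
    idx_brain = np.flatnonzero(brain.ravel())
    evals = np.empty((idx_brain.size, 3))
    evals[:] = params.tissue_evals
    flat_edema = edema.ravel()[idx_brain]
    flat_tumor = tumor.ravel()[idx_brain]
    evals[flat_edema] = params.edema_tissue_evals
    evals[flat_tumor] = params.tumor_tissue_evals
    rots = Rotation.random(idx_brain.size, random_state=np.random.RandomState(
        int(rng.integers(2 ** 31)))).as_matrix()
    D = np.einsum("nij,nj,nkj->nik", rots, evals, rots)
    t6 = np.stack([D[:, 0, 0], D[:, 1, 1], D[:, 2, 2],
                   D[:, 0, 1], D[:, 0, 2], D[:, 1, 2]], axis=-1)
    tensors.reshape(-1, 6)[idx_brain] = t6

    return SyntheticSubject(
        brain=brain, tumor=tumor, edema=edema,
        truth_f=ScalarMap(values=f, kind="FW-VF", mask=brain),
        truth_tensors=TensorField(tensors=tensors, S0=brain.astype(float),
                                  fit_mask=brain),
        label=params.label, subject_id=subject_id,
        lesion_count=placed, params=params,
    )


def simulate_dwi(subject: SyntheticSubject, gtab: GradientTable | None = None,
                 snr: float | None = None, seed: int = 0,
                 noise: str = "rician", s0: float = 1.0,
                 d_water: float = 3.0e-3) -> DWIVolume:
    """Forward-simulate single-shell DWI from the phantom's truth fields.

    Signal model per brain voxel:
    S = S0 [ (1 - f) exp(-b g^T D_t g) + f exp(-b d_water) ], with Rician
    noise of scale S0/snr (``snr=np.inf`` gives the noiseless signal;
    ``noise='gaussian'`` is available for debugging).
    """
    if snr is None:
        snr = subject.params.snr
    if not snr > 0:
        raise ValueError("snr must be positive (use np.inf for noiseless)")
    if gtab is None:
        gtab = default_gradient_table()
    bvals = np.asarray(gtab.bvals)
    g = np.asarray(gtab.bvecs)
    quad = np.column_stack([g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
                            2 * g[:, 1] * g[:, 2]])            # (n, 6)
    brain = subject.brain
    f = subject.truth_f.values[brain][:, None]
    t6 = subject.truth_tensors.tensors[brain]
    At = np.exp(-bvals[None, :] * (t6 @ quad.T))
    Aw = np.exp(-bvals * d_water)[None, :]
    sig_flat = s0 * ((1.0 - f) * At + f * Aw)

    signal = np.zeros(subject.brain.shape + (len(gtab),))
    signal[brain] = sig_flat
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        if noise == "rician":
            e1 = rng.normal(0, sigma, signal.shape)
            e2 = rng.normal(0, sigma, signal.shape)
            signal = np.sqrt((signal + e1) ** 2 + e2 ** 2)
        elif noise == "gaussian":
            signal = np.clip(signal + rng.normal(0, sigma, signal.shape), 0, None)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    return DWIVolume(signal=signal, gradient_table=gtab,
                     spacing=subject.params.spacing)


def generate_cohort(n_glioblastoma: int, n_metastasis: int, seed: int = 0,
                    overrides_by_class: dict[str, dict] | None = None):
    """Lazily yield phantom subjects for a two-class cohort.

    Subject parameter seeds fan out deterministically from ``seed``; classes
    are interleaved (gbm, met, gbm, ...) so truncation stays near-balanced.
    """
    if n_glioblastoma < 0 or n_metastasis < 0:
        raise ValueError("cohort counts must be non-negative")
    overrides_by_class = overrides_by_class or {}
    rng = np.random.default_rng(seed)
    order = ["glioblastoma"] * n_glioblastoma + ["metastasis"] * n_metastasis
    order = [order[i] for i in _interleave(n_glioblastoma, n_metastasis)]
    for i, label in enumerate(order):
        sub_seed = int(rng.integers(2 ** 31))
        params = PhantomParams.for_class(
            label, seed=sub_seed, **overrides_by_class.get(label, {}))
        yield make_phantom(params, subject_id=f"sub-{i:03d}")


def _interleave(n_a: int, n_b: int) -> list[int]:
    ids_a = list(range(n_a))
    ids_b = list(range(n_a, n_a + n_b))
    out = []
    while ids_a or ids_b:
        if ids_a:
            out.append(ids_a.pop(0))
        if ids_b:
            out.append(ids_b.pop(0))
    return out


def make_cohort(out_dir: str | Path, n_glioblastoma: int, n_metastasis: int,
                seed: int = 0, gtab: GradientTable | None = None,
                snr: float | None = None,
                overrides_by_class: dict[str, dict] | None = None,
                overwrite: bool = False) -> pd.DataFrame:
    """Write a phantom cohort to disk: per-subject NIfTI masks, truth FW-VF,
    DWI + bval/bvec, a manifest CSV, and a YAML parameter sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    if gtab is None:
        gtab = default_gradient_table()
    rows = []
    for subject in generate_cohort(n_glioblastoma, n_metastasis, seed=seed,
                                   overrides_by_class=overrides_by_class):
        sid = subject.subject_id
        spacing = subject.params.spacing
        dwi = simulate_dwi(subject, gtab=gtab, snr=snr,
                           seed=subject.params.seed + 1)
        paths = {
            "brain": out_dir / f"{sid}_brain.nii.gz",
            "tumor": out_dir / f"{sid}_tumor.nii.gz",
            "edema": out_dir / f"{sid}_edema.nii.gz",
            "truth_fwvf": out_dir / f"{sid}_truth_fwvf.nii.gz",
            "dwi": out_dir / f"{sid}_dwi.nii.gz",
        }
        for key in ("brain", "tumor", "edema"):
            save_map(getattr(subject, key).astype(np.uint8), paths[key],
                     spacing=spacing)
        save_map(subject.truth_f.values, paths["truth_fwvf"], spacing=spacing)
        dwi.save(paths["dwi"], out_dir / f"{sid}_dwi.bval",
                 out_dir / f"{sid}_dwi.bvec")
        rows.append({"subject_id": sid, "label": subject.label,
                     "lesion_count": subject.lesion_count,
                     "seed": subject.params.seed,
                     **{f"path_{k}": str(v) for k, v in paths.items()}})
    manifest = pd.DataFrame(rows, columns=[
        "subject_id", "label", "lesion_count", "seed",
        "path_brain", "path_tumor", "path_edema", "path_truth_fwvf", "path_dwi"])
    manifest.to_csv(manifest_path, index=False)
    with open(out_dir / "cohort_params.yaml", "w") as fh:
        yaml.safe_dump({
            "n_glioblastoma": n_glioblastoma, "n_metastasis": n_metastasis,
            "seed": seed, "snr": snr,
            "class_defaults": CLASS_TEXTURE,
            "overrides_by_class": overrides_by_class or {},
        }, fh)
    return manifest
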