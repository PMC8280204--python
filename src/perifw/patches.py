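"""Peritumoral patch extraction: 16x16 axial windows inside edema.

Sampling rules:

* per-subject patch budget = floor(edema voxels / 256), with a minimum of one
  when the edema is non-empty;
* a candidate patch is admissible when its center voxel lies in edema, its
  footprint contains zero tumor voxels and stays inside the brain, and at
  most 20 percent of the footprint falls on healthy (non-edema) brain —
  the same overlap bound that governs augmentation;
* candidates are drawn by picking a random edema voxel and jittering the
  window around it, with rejection-resampling capped per requested patch;
* every patch inherits the subject's class label;
* augmentation shifts a source patch in-plane, allowing at most 20 percent of
  the footprint (51 of 256 voxels) to fall on healthy brain
  (brain and not edema and not tumor), still with zero tumor voxels.

Patch intensities are the map values normalized to [0, 1] by each map kind's
fixed physical range, so scaling is deterministic and subject-independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .tensor import ScalarMap

__all__ = ["Patch", "PatchSet", "patch_budget", "sample_patches",
           "augment_patches", "augmentation_admissible", "PATCH_SIZE",
           "MAX_HEALTHY_FRACTION"]

logger = logging.getLogger(__name__)

PATCH_SIZE = 16
#: maximum fraction of an augmented patch's footprint on healthy brain
MAX_HEALTHY_FRACTION = 0.20
_MAX_HEALTHY_VOXELS = int(MAX_HEALTHY_FRACTION * PATCH_SIZE * PATCH_SIZE)  # 51
_REJECTION_CAP = 1000      # attempts per requested patch
_JITTER = 4                # max offset of the window center from the seed voxel
_AUG_MAX_SHIFT = 8         # max in-plane shift of an augmented patch


@dataclass
class Patch:
    """One 16x16 axial window: normalized values, provenance, label."""

    values: np.ndarray                   # (16, 16) or (16, 16, C)
    origin: tuple[int, int, int]         # min-corner voxel (x, y, z)
    subject_id: str
    label: str
    map_kind: str
    lesion_id: int = 0
    augmented: bool = False
    axis: str = "axial"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, "
                             f"got {self.values.shape}")


@dataclass
class PatchSet:
    """An ordered collection of patches from one map kind, plus provenance."""

    patches: list[Patch]
    map_kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.patches:
            if p.map_kind != self.map_kind:
                raise ValueError("all patches in a set must share a map kind")

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def to_array(self) -> np.ndarray:
        """Stack values to (N, 16, 16[, C])."""
        if not self.patches:
            return np.zeros((0, PATCH_SIZE, PATCH_SIZE), dtype=np.float32)
        return np.stack([p.values for p in self.patches])

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patches])

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([p.subject_id for p in self.patches])

    def extend(self, other: "PatchSet") -> "PatchSet":
        if other.map_kind != self.map_kind:
            raise ValueError("cannot merge patch sets of different map kinds")
        return PatchSet(self.patches + other.patches, self.map_kind,
                        {**self.provenance, **other.provenance})

    # -- serialization: flat array container + JSON manifest -----------------

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        np.save(stem.with_suffix(".npy"), self.to_array())
        manifest = {
            "map_kind": self.map_kind,
            "provenance": _jsonable(self.provenance),
            "patches": [{k: v for k, v in _jsonable(asdict(p)).items()
                         if k != "values"} for p in self.patches],
        }
        stem.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, stem: str | Path) -> "PatchSet":
        stem = Path(stem)
        arr = np.load(stem.with_suffix(".npy"))
        meta = json.loads(stem.with_suffix(".json").read_text())
        patches = [Patch(values=arr[i], **{**m, "origin": tuple(m["origin"])})
                   for i, m in enumerate(meta["patches"])]
        return cls(patches, meta["map_kind"], meta.get("provenance", {}))

    def export_nifti(self, out_dir: str | Path) -> None:
        """Write each patch as a small NIfTI image (inspection aid), plus
        the CSV index, into ``out_dir``."""
        import nibabel as nib
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(self.patches):
            img = nib.Nifti1Image(np.asarray(p.values, dtype=np.float32),
                                  np.eye(4))
            nib.save(img, str(out_dir / f"patch_{i:05d}.nii.gz"))
        self.index_frame().to_csv(out_dir / "index.csv", index=False)

    def index_frame(self) -> pd.DataFrame:
        """CSV-ready index (one row per patch, no pixel data)."""
        return pd.DataFrame([
            {"subject_id": p.subject_id, "label": p.label, "map_kind": p.map_kind,
             "x": p.origin[0], "y": p.origin[1], "z": p.origin[2],
             "lesion_id": p.lesion_id, "augmented": p.augmented}
            for p in self.patches])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def patch_budget(edema_mask: np.ndarray) -> int:
    """floor(edema voxels / 256); one patch minimum for a non-empty edema."""
    n = int(np.count_nonzero(edema_mask))
    if n == 0:
        return 0
    return max(n // (PATCH_SIZE * PATCH_SIZE), 1)


def _normalized_values(maps: list[ScalarMap]) -> np.ndarray:
    vols = [m.normalized() for m in maps]
    return vols[0] if len(vols) == 1 else np.stack(vols, axis=-1)


def _window(vol: np.ndarray, x: int, y: int, z: int) -> np.ndarray:
    return vol[x:x + PATCH_SIZE, y:y + PATCH_SIZE, z]


def _admissible(x: int, y: int, cx: int, cy: int, z: int,
                masks: dict[str, np.ndarray]) -> bool:
    """Non-augmented admissibility: bounds, center voxel in edema, zero
    tumor voxels, footprint inside the brain with at most 20 percent of it
    on healthy (non-edema, non-tumor) brain."""
    shape = masks["edema"].shape
    if x < 0 or y < 0 or x + PATCH_SIZE > shape[0] or y + PATCH_SIZE > shape[1]:
        return False
    if not masks["edema"][cx, cy, z]:
        return False
    if _window(masks["tumor"], x, y, z).any():
        return False
    if not _window(masks["brain"], x, y, z).all():
        return False
    n_edema = int(_window(masks["edema"], x, y, z).sum())
    n_tumor = 0
    healthy = PATCH_SIZE * PATCH_SIZE - n_edema - n_tumor
    return healthy <= _MAX_HEALTHY_VOXELS


def sample_patches(maps: ScalarMap | list[ScalarMap],
                   masks: dict[str, np.ndarray], n: int, seed: int = 0,
                   subject_id: str = "sub-000", label: str = "glioblastoma",
                   ) -> PatchSet:
    """Draw ``n`` admissible patches from one or more co-registered maps.

    Multi-map input yields multi-channel patches sampled at identical
    coordinates (map kinds joined with '+'). With multiple lesions the edema
    mask is their union, so all peritumoral areas are sampled; ``lesion_id``
    records the connected component the seed voxel belongs to. If fewer than
    ``n`` admissible patches exist within the rejection cap, the feasible
    subset is returned with a warning (patches are never fabricated).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    map_list = [maps] if isinstance(maps, ScalarMap) else list(maps)
    kind = "+".join(m.kind for m in map_list)
    for key in ("edema", "tumor", "brain"):
        if key not in masks:
            raise ValueError(f"masks must include {key!r}")
        if masks[key].shape != map_list[0].values.shape:
            raise ValueError("masks and maps must share a grid")
    vol = _normalized_values(map_list)
    prov = {"seed": seed, "n_requested": n, "map_kind": kind,
            "subject_id": subject_id}
    rng = np.random.default_rng(seed)
    edema_idx = np.argwhere(masks["edema"])
    lesion_labels, _ = ndimage.label(masks["edema"])
    patches: list[Patch] = []
    if n == 0 or edema_idx.size == 0:
        if n > 0:
            logger.warning("subject %s: empty edema, no patches", subject_id)
        return PatchSet(patches, kind, prov)
    half = PATCH_SIZE // 2
    for _ in range(n):
        for _attempt in range(_REJECTION_CAP):
            cx0, cy0, z = edema_idx[rng.integers(len(edema_idx))]
            jx, jy = rng.integers(-_JITTER, _JITTER + 1, size=2)
            cx, cy = cx0 + jx, cy0 + jy  # window center voxel
            x, y = cx - half, cy - half
            if not (0 <= cx < masks["edema"].shape[0]
                    and 0 <= cy < masks["edema"].shape[1]):
                continue
            if _admissible(x, y, cx, cy, z, masks):
                patches.append(Patch(
                    values=_window(vol, x, y, z),
                    origin=(int(x), int(y), int(z)),
                    subject_id=subject_id, label=label, map_kind=kind,
                    lesion_id=int(lesion_labels[cx0, cy0, z])))
                break
        else:
            logger.warning(
                "subject %s: placed %d of %d requested patches before the "
                "rejection cap", subject_id, len(patches), n)
            break
    return PatchSet(patches, kind, prov)


def augmentation_admissible(origin: tuple[int, int, int], shift: tuple[int, int],
                            masks: dict[str, np.ndarray]) -> bool:
    """Whether shifting a source patch at ``origin`` by in-plane ``shift``
    yields an admissible augmented patch: inside the grid and brain, zero
    tumor voxels, and at most 20 percent of the footprint on healthy brain."""
    healthy = masks["brain"] & ~masks["edema"] & ~masks["tumor"]
    shape = masks["edema"].shape
    x, y, z = origin[0] + shift[0], origin[1] + shift[1], origin[2]
    if x < 0 or y < 0 or x + PATCH_SIZE > shape[0] or y + PATCH_SIZE > shape[1]:
        return False
    if _window(masks["tumor"], x, y, z).any():
        return False
    if not _window(masks["brain"], x, y, z).all():
        return False
    return int(_window(healthy, x, y, z).sum()) <= _MAX_HEALTHY_VOXELS


def augment_patches(patchset: PatchSet, maps: ScalarMap | list[ScalarMap],
                    masks: dict[str, np.ndarray], n_aug: int = 1,
                    seed: int = 0) -> PatchSet:
    """Shift-augment every source patch ``n_aug`` times.

    An augmented patch is an in-plane integer shift of its source whose
    footprint has zero tumor voxels, lies inside the brain, and has at most
    20 percent (51 of 256) of its voxels on healthy brain. If no admissible
    shift is found within the cap, the source is kept unaugmented and a
    warning is logged. The returned set contains the sources followed by the
    augmented patches.
    """
    map_list = [maps] if isinstance(maps, ScalarMap) else list(maps)
    vol = _normalized_values(map_list)
    rng = np.random.default_rng(seed)
    out = list(patchset.patches)
    for p in patchset.patches:
        made = 0
        for _attempt in range(_REJECTION_CAP):
            if made >= n_aug:
                break
            dx, dy = rng.integers(-_AUG_MAX_SHIFT, _AUG_MAX_SHIFT + 1, size=2)
            if not augmentation_admissible(p.origin, (dx, dy), masks):
                continue
            x, y, z = p.origin[0] + dx, p.origin[1] + dy, p.origin[2]
            out.append(Patch(values=_window(vol, x, y, z),
                             origin=(int(x), int(y), int(z)),
                             subject_id=p.subject_id, label=p.label,
                             map_kind=p.map_kind, lesion_id=p.lesion_id,
                             augmented=True))
            made += 1
        if made < n_aug:
            logger.warning("subject %s: %d/%d augmentations placed for patch "
                           "at %s", p.subject_id, made, n_aug, p.origin)
    prov = dict(patchset.provenance)
    prov.update({"augment_seed": seed, "n_aug": n_aug})
    return PatchSet(out, patchset.map_kind, prov)
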