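"""4D diffusion-weighted volumes and NIfTI input/output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import GradientTable

__all__ = ["DWIVolume", "load_dwi", "save_map", "load_mask"]


@dataclass
class DWIVolume:
    """A 4D DWI acquisition: signal[x, y, z, volume] plus its gradient table.

    ``spacing`` is the voxel size in mm per axis; ``affine`` is the NIfTI
    voxel-to-world transform (defaults to a scaled identity).
    """

    signal: np.ndarray
    gradient_table: GradientTable
    spacing: tuple[float, float, float] = (1.72, 1.72, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != len(self.gradient_table):
            raise ValueError(
                f"{self.signal.shape[3]} volumes but gradient table has "
                f"{len(self.gradient_table)} entries"
            )
        if np.any(self.signal < 0):
            raise ValueError("DWI signal must be non-negative")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def mean_b0(self) -> np.ndarray:
        """Per-voxel mean of the unweighted (b=0) volumes."""
        return self.signal[..., self.gradient_table.b0_mask].mean(axis=-1)

    def save(self, nifti_path: str | Path, bval_path: str | Path | None = None,
             bvec_path: str | Path | None = None) -> None:
        img = nib.Nifti1Image(self.signal.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(self.spacing) + (1.0,))
        nib.save(img, str(nifti_path))
        if bval_path is not None and bvec_path is not None:
            self.gradient_table.to_files(bval_path, bvec_path)


def load_dwi(nifti_path: str | Path, bval_path: str | Path,
             bvec_path: str | Path) -> DWIVolume:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    gtab = GradientTable.from_files(bval_path, bvec_path)
    zooms = img.header.get_zooms()[:3]
    return DWIVolume(signal=np.clip(data, 0, None), gradient_table=gtab,
                     spacing=tuple(float(z) for z in zooms), affine=img.affine)


def save_map(values: np.ndarray, path: str | Path,
             affine: np.ndarray | None = None,
             spacing: tuple[float, float, float] = (1.72, 1.72, 3.0)) -> None:
    """Write a 3D scalar volume as NIfTI on the given grid."""
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5
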