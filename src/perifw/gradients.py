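"""Acquisition geometry: b-values and gradient directions for single-shell DWI.

The reference acquisition this package targets is a clinical single-shell
protocol: a few b=0 s/mm^2 volumes plus ~30 diffusion-weighted volumes at
b = 1000 s/mm^2. Gradient tables are read and written in the FSL dialect
(one whitespace-separated row of b-values; three rows of x/y/z components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientTable", "default_gradient_table"]

#: b-values at or below this (s/mm^2) count as unweighted reference volumes
B0_THRESHOLD = 50.0


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions for each DWI volume.

    Invariants enforced at construction: all b-values are non-negative,
    non-b0 directions have unit norm (to 1e-6), there is at least one b0
    volume, and the non-b0 directions span the six tensor degrees of
    freedom (non-collinear in the design-matrix sense).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size):
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        b0 = self.b0_mask
        if not b0.any():
            raise ValueError("gradient table needs at least one b=0 volume")
        dwi_vecs = bvecs[~b0]
        if dwi_vecs.shape[0] < 6:
            raise ValueError("need at least six diffusion-weighted directions")
        norms = np.linalg.norm(dwi_vecs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 gradient directions must have unit norm")
        # collinearity check: the quadratic-form design over the non-b0
        # directions must span all six unique tensor elements
        g = dwi_vecs
        quad = np.column_stack(
            [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
             2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
        )
        if np.linalg.matrix_rank(quad) < 6:
            raise ValueError("diffusion directions are collinear/degenerate; "
                             "cannot determine a full tensor")

    @property
    def b0_mask(self) -> np.ndarray:
        return np.asarray(self.bvals) <= self.b0_threshold

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def mean_dwi_bval(self) -> float:
        return float(self.bvals[self.dwi_mask].mean())

    # -- FSL-dialect text IO -------------------------------------------------

    @classmethod
    def from_files(cls, bval_path: str | Path, bvec_path: str | Path) -> "GradientTable":
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
        bvecs = np.loadtxt(bvec_path, ndmin=2)
        return cls(bvals=bvals, bvecs=bvecs)

    def to_files(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")


def _electrostatic_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Quasi-uniform unit directions via electrostatic repulsion on the sphere."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.1
    for _ in range(n_iter):
        # antipodally symmetric repulsion, as diffusion directions are axial
        diff = v[:, None, :] - v[None, :, :]
        diff_a = v[:, None, :] + v[None, :, :]
        d2 = (diff ** 2).sum(-1) + np.eye(n)
        d2a = (diff_a ** 2).sum(-1) + 1e-12
        force = (diff / d2[..., None] ** 1.5).sum(1) + (diff_a / d2a[..., None] ** 1.5).sum(1)
        v = v + step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.98
    return v


def default_gradient_table(n_dirs: int = 30, n_b0: int = 3, bval: float = 1000.0,
                           seed: int = 0) -> GradientTable:
    """Single-shell table mirroring the reference protocol: ``n_b0`` b=0
    volumes followed by ``n_dirs`` quasi-uniform directions at ``bval``."""
    dirs = _electrostatic_directions(n_dirs, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, bval)])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)
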