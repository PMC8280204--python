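"""Single-tensor diffusion modelling: weighted least-squares fit and scalar maps.

The tensor model is S_j = S0 * exp(-b_j g_j^T D g_j). Fitting is done in the
log domain: ln S = B theta with theta = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0)
and design rows (-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1).
An ordinary LS pass provides the weights (predicted squared signal) for one
weighted LS solve, the standard heteroscedasticity correction for log-domain
tensor fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi import DWIVolume
from .gradients import GradientTable

__all__ = [
    "TensorField", "ScalarMap", "design_matrix", "fit_dti_wls",
    "tensor_scalars", "eigenvalues", "fa_from_eigenvalues",
    "MAP_KINDS", "MAP_RANGES",
]

#: scalar map identifiers and the fixed physical range used to normalize each
#: kind to [0, 1] before patch-based classification (diffusivities in mm^2/s)
MAP_RANGES: dict[str, tuple[float, float]] = {
    "FW-VF": (0.0, 1.0),
    "FA": (0.0, 1.0),
    "FW-FA": (0.0, 1.0),
    "MD": (0.0, 3.0e-3),
    "AX": (0.0, 3.0e-3),
    "RAD": (0.0, 3.0e-3),
    "FW-AX": (0.0, 3.0e-3),
    "FW-RAD": (0.0, 3.0e-3),
}
MAP_KINDS = tuple(MAP_RANGES)

#: eigenvalue clipping range (mm^2/s) applied before any scalar derivation
EVAL_BOUNDS = (0.0, 5.0e-3)

_SIGNAL_FLOOR_FRAC = 1e-6  # floor for non-positive signals, relative to S0


@dataclass
class ScalarMap:
    """A 3D scalar image of one diffusion-derived quantity.

    ``values`` are defined only where ``mask`` is true (zero elsewhere);
    ``kind`` is one of MAP_KINDS; ``units`` is 'mm^2/s' for diffusivities and
    dimensionless ('1') for FA and the free-water volume fraction.
    """

    values: np.ndarray
    kind: str
    mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in MAP_RANGES:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if not self.units:
            self.units = "1" if MAP_RANGES[self.kind][1] == 1.0 else "mm^2/s"
        self.values = np.where(self.mask, self.values, 0.0)

    def normalized(self) -> np.ndarray:
        """Values scaled to [0, 1] by the kind's fixed physical range."""
        lo, hi = MAP_RANGES[self.kind]
        return np.clip((self.values - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors in compact 6-element form
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), with the fitted S0 and a fit mask."""

    tensors: np.ndarray          # (X, Y, Z, 6), mm^2/s
    S0: np.ndarray               # (X, Y, Z)
    fit_mask: np.ndarray         # (X, Y, Z) bool

    def as_matrices(self) -> np.ndarray:
        """Expand to full (X, Y, Z, 3, 3) symmetric matrices."""
        t = self.tensors
        m = np.empty(t.shape[:-1] + (3, 3))
        m[..., 0, 0] = t[..., 0]
        m[..., 1, 1] = t[..., 1]
        m[..., 2, 2] = t[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
        return m


def tensors_from_matrices(m: np.ndarray) -> np.ndarray:
    """Compact (..., 3, 3) symmetric matrices into 6-element form."""
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1)


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-domain tensor design matrix, one row per volume (n, 7)."""
    b = np.asarray(gtab.bvals)
    g = np.asarray(gtab.bvecs)
    return np.column_stack([
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ])


def _wls_solve(B: np.ndarray, log_s: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Batched weighted LS: solve (B' W B) theta = B' W y per voxel.

    log_s, weights: (n_voxels, n_volumes). Returns theta (n_voxels, 7).
    """
    # normal equations assembled with einsum; 7x7 solve batched over voxels
    Bw = weights[:, :, None] * B[None, :, :]          # (V, n, 7)
    lhs = np.einsum("vnp,nq->vpq", Bw, B)             # (V, 7, 7)
    rhs = np.einsum("vnp,vn->vp", Bw, log_s)          # (V, 7)
    lhs += 1e-12 * np.eye(7)[None]
    return np.linalg.solve(lhs, rhs[..., None])[..., 0]


def fit_signals_wls(signals: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """WLS tensor fit of flat signals (n_voxels, n_volumes) against design B.

    Returns (tensors (V, 6), S0 (V,)). Non-positive signals are floored at
    _SIGNAL_FLOOR_FRAC of the voxel's maximum before taking logs.
    """
    signals = np.asarray(signals, dtype=float)
    floor = np.maximum(signals.max(axis=1, keepdims=True), 1e-300) * _SIGNAL_FLOOR_FRAC
    s = np.maximum(signals, floor)
    log_s = np.log(s)
    # OLS pass: shared pseudo-inverse
    theta0 = log_s @ np.linalg.pinv(B).T
    pred = np.exp(np.clip(theta0 @ B.T, -700, 700))
    theta = _wls_solve(B, log_s, pred ** 2)
    return theta[:, :6], np.exp(np.clip(theta[:, 6], -700, 700))


def fit_dti_wls(dwi: DWIVolume, mask: np.ndarray) -> TensorField:
    """Weighted least-squares single-tensor fit inside ``mask``.

    Voxels outside the mask are left unfitted (zero tensor, fit_mask False).
    Voxels with non-positive signal are floored, not dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask shape does not match DWI grid")
    B = design_matrix(dwi.gradient_table)
    if len(dwi.gradient_table) < 7:
        raise ValueError("need at least 7 volumes (1 b0 + 6 directions)")
    flat = dwi.signal[mask]                      # (V, n)
    tensors = np.zeros(dwi.shape + (6,))
    S0 = np.zeros(dwi.shape)
    if flat.size:
        t, s0 = fit_signals_wls(flat, B)
        tensors[mask] = t
        S0[mask] = s0
    return TensorField(tensors=tensors, S0=S0, fit_mask=mask)


# -- scalar derivation -------------------------------------------------------

def eigenvalues(tensors6: np.ndarray, clip: tuple[float, float] = EVAL_BOUNDS) -> np.ndarray:
    """Sorted (descending) eigenvalues of compact tensors, clipped to
    physically plausible bounds before any scalar is derived."""
    t = np.asarray(tensors6)
    m = np.empty(t.shape[:-1] + (3, 3))
    m[..., 0, 0] = t[..., 0]
    m[..., 1, 1] = t[..., 1]
    m[..., 2, 2] = t[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
    ev = np.linalg.eigvalsh(m)[..., ::-1]
    return np.clip(ev, clip[0], clip[1])


def fa_from_eigenvalues(ev: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from sorted eigenvalues; 0 for an all-zero tensor."""
    ev = np.asarray(ev, dtype=float)
    md = ev.mean(axis=-1, keepdims=True)
    num = ((ev - md) ** 2).sum(axis=-1)
    den = (ev ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def tensor_scalars(field: TensorField, prefix: str = "") -> dict[str, ScalarMap]:
    """FA / MD / AX / RAD maps from a tensor field.

    With ``prefix='FW-'`` the same formulas are applied to a free-water
    corrected tissue tensor field, yielding FW-FA / FW-AX / FW-RAD.
    """
    ev = eigenvalues(field.tensors)
    mask = field.fit_mask
    fa = fa_from_eigenvalues(ev)
    md = ev.mean(axis=-1)
    ax = ev[..., 0]
    rad = ev[..., 1:].mean(axis=-1)
    out: dict[str, ScalarMap] = {}
    for name, vals in [("FA", fa), ("MD", md), ("AX", ax), ("RAD", rad)]:
        kind = prefix + name if prefix + name in MAP_RANGES else name
        if prefix and prefix + name not in MAP_RANGES:
            continue  # FW-MD is not a defined map kind
        out[kind] = ScalarMap(values=vals, kind=kind, mask=mask)
    return out
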