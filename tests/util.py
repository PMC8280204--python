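"""Shared test helpers: forward simulation of the bi-tensor signal model,
independent of the fitting code under test."""

from __future__ import annotations

import numpy as np

from perifw import DWIVolume, GradientTable

D_WATER = 3.0e-3


def quad_forms(gtab: GradientTable, D: np.ndarray) -> np.ndarray:
    """g^T D g per volume for a single 3x3 tensor."""
    g = np.asarray(gtab.bvecs)
    return np.einsum("ni,ij,nj->n", g, D, g)


def bitensor_signal(gtab: GradientTable, D_t: np.ndarray, f: float,
                    s0: float = 1.0, d_water: float = D_WATER) -> np.ndarray:
    """Noiseless bi-tensor signal per volume."""
    b = np.asarray(gtab.bvals)
    at = np.exp(-b * quad_forms(gtab, D_t))
    aw = np.exp(-b * d_water)
    return s0 * ((1.0 - f) * at + f * aw)


def dwi_from_signals(signals: np.ndarray, gtab: GradientTable,
                     shape: tuple[int, int, int] | None = None) -> DWIVolume:
    """Wrap flat per-voxel signals (V, n) into a DWIVolume grid."""
    signals = np.atleast_2d(signals)
    v = signals.shape[0]
    if shape is None:
        shape = (v, 1, 1)
    vol = signals.reshape(shape + (signals.shape[1],))
    return DWIVolume(signal=np.clip(vol, 0, None), gradient_table=gtab,
                     spacing=(1.0, 1.0, 1.0))


def add_rician(signal: np.ndarray, snr: float, rng: np.random.Generator,
               s0: float = 1.0) -> np.ndarray:
    sigma = s0 / snr
    e1 = rng.normal(0, sigma, signal.shape)
    e2 = rng.normal(0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2 ** 2)
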