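"""Deconvolution-based CT perfusion mapping.

The discrete indicator-dilution model links each voxel's contrast curve
C(t) to the arterial input function (AIF) through the residue function
R(t):

    C = dt * A @ (F_s * R),      A[i, j] = AIF[i - j]  (lower-triangular
                                            Toeplitz, rectangle rule)

where F_s is the flow scale.  The system is inverted voxelwise by
truncated SVD: singular values below ``truncation_fraction`` of the
largest are zeroed (Ostergaard-style regularization).  Maps follow the
standard readings:

    CBF = 60 * 100 * max_t k(t)        [mL / 100 g / min]
    CBV = 100 * integral(C) / integral(AIF)   [mL / 100 g]
    MTT = 60 * CBV / CBF               [s]
    TTP = argmax_t C(t)                [s]

Density/hematocrit calibration constants are folded into a single
``calibration`` factor (default 1), so absolute units are conventional
but tests assert on ratios and parameter recovery rather than absolute
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .core import PerfusionSeries, ValidationError

__all__ = ["DeconvolutionParams", "PerfusionMaps", "svd_deconvolve",
           "perfusion_maps"]


@dataclass(frozen=True)
class DeconvolutionParams:
    """``truncation_fraction``: relative singular-value cutoff in (0, 1);
    ``baseline_frames``: leading pre-contrast frames averaged and
    subtracted before deconvolution."""

    truncation_fraction: float = 0.2
    baseline_frames: int = 2
    calibration: float = 1.0
    cbf_floor: float = 1.0  # mL/100g/min below which MTT is masked out

    def __post_init__(self) -> None:
        if not (0 < self.truncation_fraction < 1):
            raise ValidationError("truncation_fraction must be in (0, 1)")
        if self.baseline_frames < 1:
            raise ValidationError("baseline_frames must be >= 1")


@dataclass(frozen=True)
class PerfusionMaps:
    """CBF/CBV/MTT/TTP on the spatial grid (units in the module docstring).
    MTT is 0 where CBF is below the floor (no meaningful transit time)."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray

    def __post_init__(self) -> None:
        if (self.cbf < 0).any() or (self.cbv < 0).any():
            raise ValidationError("CBF and CBV must be non-negative")


def _baseline_subtract(series: PerfusionSeries, n_base: int):
    frames = series.frames.reshape(series.n_frames, -1)
    baseline = frames[:n_base].mean(axis=0)
    return frames - baseline[None, :]


def _aif_matrix(aif: np.ndarray, dt: float) -> np.ndarray:
    return dt * toeplitz(aif, np.zeros_like(aif))


def svd_deconvolve(series: PerfusionSeries,
                   params: DeconvolutionParams = DeconvolutionParams()) -> np.ndarray:
    """Recover the scaled residue field k(t) = F_s * R(t) per voxel.

    Returns an array of shape ``(n_frames, *spatial_shape)``.  Linear and
    deterministic: doubling a tissue curve doubles its residue vector.
    """
    if not np.any(series.aif > 0):
        raise ValidationError("AIF is identically zero")
    times = series.times
    dt = float(np.mean(np.diff(times)))
    A = _aif_matrix(series.aif, dt)
    U, s, Vt = np.linalg.svd(A)
    cutoff = params.truncation_fraction * s[0]
    s_inv = np.where(s >= cutoff, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    A_pinv = (Vt.T * s_inv) @ U.T
    C = _baseline_subtract(series, params.baseline_frames)
    k = A_pinv @ C
    return k.reshape(series.n_frames, *series.spatial_shape)


def perfusion_maps(series: PerfusionSeries,
                   params: DeconvolutionParams = DeconvolutionParams()) -> PerfusionMaps:
    """CBF/CBV/MTT/TTP maps from the deconvolved residue field."""
    k = svd_deconvolve(series, params)
    times = series.times
    dt = float(np.mean(np.diff(times)))
    C = _baseline_subtract(series, params.baseline_frames)
    C = C.reshape(series.n_frames, *series.spatial_shape)

    aif_area = float(series.aif.sum() * dt)
    if aif_area <= 0:
        raise ValidationError("AIF has zero area")

    cbf = 6000.0 * params.calibration * np.maximum(k, 0.0).max(axis=0)
    cbv = 100.0 * params.calibration * np.maximum(C.sum(axis=0) * dt, 0.0) / aif_area
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > params.cbf_floor, 60.0 * cbv / np.maximum(cbf, 1e-12), 0.0)
    ttp = times[np.argmax(C, axis=0)]
    ttp = np.where(cbv > 0, ttp, 0.0)
    return PerfusionMaps(cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp)
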