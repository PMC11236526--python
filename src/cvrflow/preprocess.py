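"""Signal conditioning shared by all analyses.

Regional mean extraction with edema exclusion, mask dilation, wavelet
de-noising with the Donoho-Johnstone universal threshold, temporal
derivative (the CBV-change surrogate), trace resampling to the volume grid,
and bulk BOLD-PetCO2 alignment.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .containers import BoldSeries, MaskVolume, PhysioTrace
from .errors import EmptyRegionError, UndefinedCorrelationError

__all__ = [
    "dilate_mask",
    "extract_regional_mean",
    "universal_threshold",
    "denoise_wavelet",
    "temporal_derivative",
    "resample_trace",
    "bulk_align",
]


def dilate_mask(
    mask: MaskVolume, label: str, voxels: int, connectivity: int = 6
) -> MaskVolume:
    """Morphologically dilate one labelled mask by ``voxels`` iterations.

    Parameters
    ----------
    connectivity
        6 (face-adjacent, default) or 26 (face/edge/corner) neighbourhood.

    Returns a new :class:`MaskVolume`; other labels are unchanged.
    """
    if voxels < 0:
        raise ValueError("voxels must be >= 0")
    target = mask.get(label)  # raises on unknown label
    if label == "background":
        raise ValueError("background is derived and cannot be dilated")
    if voxels == 0 or not target.any():
        return mask.with_label(label, target.copy())
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    dilated = ndimage.binary_dilation(target, structure=structure, iterations=voxels)
    return mask.with_label(label, dilated)


def extract_regional_mean(
    bold: BoldSeries, mask: MaskVolume, include: str, exclude: str | None = None
) -> np.ndarray:
    """Per-volume mean over voxels carrying ``include`` and not ``exclude``.

    Any exclusion-margin dilation (e.g. of the edema mask) is applied by the
    caller beforehand via :func:`dilate_mask`.
    """
    if bold.is_regional:
        raise ValueError("regional extraction requires a 4D BoldSeries")
    sel = mask.get(include)
    if exclude is not None:
        sel = sel & ~mask.get(exclude)
    if sel.shape != bold.data.shape[:3]:
        raise ValueError("mask grid does not match BOLD grid")
    if not sel.any():
        raise EmptyRegionError(
            f"no voxels remain for include={include!r}, exclude={exclude!r}"
        )
    return bold.data[sel].mean(axis=0)


def universal_threshold(sigma: float, n: int) -> float:
    """Donoho-Johnstone universal threshold ``sigma * sqrt(2 ln n)``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(sigma * np.sqrt(2.0 * np.log(n)))


def denoise_wavelet(
    trace: np.ndarray,
    family: str = "sym4",
    level: int = 2,
    threshold_rule: str = "universal",
    threshold_mode: str = "hard",
) -> np.ndarray:
    """Wavelet de-noising with a level-independent universal threshold.

    The trace is decomposed to ``level`` with symmetric boundary extension.
    The noise scale is the median absolute deviation of the finest-level
    detail coefficients divided by 0.6745, the threshold is
    ``sigma * sqrt(2 ln N)`` with ``N`` the trace length, and the same
    threshold is applied (hard, by default) to every detail level. The
    approximation coefficients are untouched.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1D")
    if x.size < 2**level:
        raise ValueError(f"trace too short for level {level} decomposition")
    if threshold_rule != "universal":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    coeffs = pywt.wavedec(x, family, level=level, mode="symmetric")
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest)) / 0.6745)
    lam = universal_threshold(sigma, x.size)
    denoised = [coeffs[0]] + [
        pywt.threshold(c, lam, mode=threshold_mode) for c in coeffs[1:]
    ]
    return pywt.waverec(denoised, family, mode="symmetric")[: x.size]


def temporal_derivative(trace: np.ndarray, tr: float) -> np.ndarray:
    """Temporal derivative in signal units per second.

    Central differences in the interior, one-sided at the ends; output has
    the input length. Applied to the BOLD signal this is the CBV-change
    surrogate used throughout the coupling analysis.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not tr > 0:
        raise ValueError("tr must be positive")
    return np.gradient(x, tr)


def resample_trace(trace: PhysioTrace, tr: float, n_volumes: int) -> np.ndarray:
    """Linearly interpolate a gas trace onto the volume times ``k * tr``.

    Values beyond the trace support are held at the nearest endpoint.
    """
    if not tr > 0:
        raise ValueError("tr must be positive")
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    t_out = np.arange(n_volumes) * tr
    return np.interp(t_out, trace.times, trace.values)


def _corr_at_shift(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Pearson r between x and y with y delayed by ``lag`` volumes.

    Positive ``lag`` means y is treated as a delayed copy of x: the overlap
    compared is ``x[:n-lag]`` against ``y[lag:]``. Only overlapping samples
    are used (no padding). Returns NaN if either overlap segment is constant.
    """
    n = x.size
    if lag >= 0:
        xs, ys = x[: n - lag], y[lag:]
    else:
        xs, ys = x[-lag:], y[: n + lag]
    if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def _best_lag(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[int, float]:
    """Lag in [-max_lag, max_lag] maximizing signed Pearson r.

    Ties are broken toward the smallest |lag| (and toward the positive lag
    at equal magnitude) by visiting lags in that order and keeping strict
    improvements only.
    """
    order = sorted(range(-max_lag, max_lag + 1), key=lambda L: (abs(L), -np.sign(L)))
    best_lag, best_r = 0, -np.inf
    for lag in order:
        r = _corr_at_shift(x, y, lag)
        if np.isfinite(r) and r > best_r:
            best_lag, best_r = lag, r
    if not np.isfinite(best_r):
        raise UndefinedCorrelationError("no shift produced a defined correlation")
    return best_lag, best_r


def bulk_align(
    bold_mean: np.ndarray, co2_resampled: np.ndarray, max_lag: int
) -> tuple[np.ndarray, int]:
    """Globally align the resampled PetCO2 trace to the whole-brain BOLD mean.

    Finds the integer volume lag in ``[-max_lag, max_lag]`` maximizing the
    Pearson correlation (overlap samples only; ties toward smallest |lag|)
    and returns the CO2 trace shifted by that lag with edge-hold padding,
    together with the lag. Positive lag means the CO2 trace lags (is delayed
    relative to) the BOLD signal.
    """
    x = np.asarray(bold_mean, dtype=float)
    y = np.asarray(co2_resampled, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    if max_lag < 0 or max_lag >= x.size // 2:
        raise ValueError("max_lag must satisfy 0 <= max_lag < length/2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input has undefined correlation")
    lag, _ = _best_lag(x, y, max_lag)
    idx = np.clip(np.arange(x.size) + lag, 0, x.size - 1)
    return y[idx], lag
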