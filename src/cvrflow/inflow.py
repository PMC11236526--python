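"""CSF inflow-signal characterization.

Inflow voxels near the fourth ventricle are selected from the bottom slices
of the imaging stack by signal contrast; the inflow peak that follows the
return of CO2 to baseline is fit with an Azzalini skew-normal density plus
a linear baseline; peak width is summarized as the right-sided half width
at half maximum (HWHM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .containers import BoldSeries
from .errors import FitFailureError, UndefinedWidthError
from .preprocess import denoise_wavelet

__all__ = [
    "select_inflow_voxels",
    "skew_normal_model",
    "InflowPeakFit",
    "fit_inflow_peak",
    "hwhm_right",
]

#: Default fit window (volumes, inclusive): end of the hypercapnic block to
#: the midpoint between block end and ramp peak.
DEFAULT_INFLOW_WINDOW = (250, 525)


def _skew_component(
    t: np.ndarray, amplitude: float, xi: float, omega: float, alpha: float
) -> np.ndarray:
    z = (t - xi) / omega
    return amplitude * (2.0 / omega) * norm.pdf(z) * norm.cdf(alpha * z)


def skew_normal_model(
    t: np.ndarray | float,
    amplitude: float,
    xi: float,
    omega: float,
    alpha: float,
    a: float,
    b: float,
):
    """Skew-normal peak plus linear baseline.

    ``amplitude * (2/omega) * phi((t-xi)/omega) * Phi(alpha*(t-xi)/omega)
    + a + b*t`` with phi/Phi the standard normal density/CDF. ``alpha = 0``
    reduces to a scaled Gaussian centred at ``xi``.
    """
    if not omega > 0:
        raise ValueError("omega must be positive")
    t = np.asarray(t, dtype=float)
    return _skew_component(t, amplitude, xi, omega, alpha) + a + b * t


def select_inflow_voxels(
    bold: BoldSeries,
    n_bottom_slices: int = 2,
    contrast_window: tuple[int, int] = DEFAULT_INFLOW_WINDOW,
    k_voxels: int = 5,
    denoise: bool = True,
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Select high-contrast voxels in the bottom slices; return their trace.

    Within each of the ``n_bottom_slices`` lowest slices voxels are ranked
    by signal contrast (max - min over ``contrast_window``, computed on the
    de-noised trace) and the top ``k_voxels`` are kept; ties are broken by
    voxel index order. The per-slice mean traces are averaged across slices.
    Inflow of fresh spins produces the strongest signal excursions in these
    entry slices, which is what the contrast ranking isolates.

    Returns the selected voxel indices (full-volume ``(i, j, slice)``
    coordinates) and the averaged 1D trace.
    """
    if bold.is_regional:
        raise ValueError("inflow voxel selection requires a 4D BoldSeries")
    if n_bottom_slices < 1:
        raise ValueError("n_bottom_slices must be >= 1")
    data = np.moveaxis(bold.data, bold.slice_axis, 2)  # (a, b, slice, t)
    n_slices = data.shape[2]
    if n_bottom_slices > n_slices:
        raise ValueError("more bottom slices requested than slices present")
    w0, w1 = int(contrast_window[0]), int(contrast_window[1])
    if not (0 <= w0 < w1 < bold.n_volumes):
        raise ValueError("contrast window outside the series")
    selected: list[tuple[int, int, int]] = []
    slice_means = []
    for s in range(n_bottom_slices):
        slab = data[:, :, s, :]
        na, nb = slab.shape[:2]
        traces = slab.reshape(na * nb, -1)
        if denoise:
            traces = np.stack([denoise_wavelet(tr) for tr in traces])
        contrast = np.ptp(traces[:, w0 : w1 + 1], axis=1)
        k = k_voxels
        if k > traces.shape[0]:
            warnings.warn(
                f"k_voxels={k_voxels} exceeds {traces.shape[0]} voxels in slice {s}; "
                "clipping",
                stacklevel=2,
            )
            k = traces.shape[0]
        # stable sort on -contrast: ties resolve to the lowest flat index
        top = np.argsort(-contrast, kind="stable")[:k]
        slice_means.append(traces[top].mean(axis=0))
        for flat in top:
            i, j = divmod(int(flat), nb)
            orig = [i, j, s]
            # map slab coordinates back to the original axis order
            coord = [0, 0, 0]
            axes = [ax for ax in range(3) if ax != bold.slice_axis]
            coord[bold.slice_axis] = s
            coord[axes[0]], coord[axes[1]] = i, j
            selected.append(tuple(coord))
    return selected, np.mean(slice_means, axis=0)


def average_voxel_trace(
    bold: BoldSeries, voxels: list[tuple[int, int, int]]
) -> np.ndarray:
    """Raw (un-denoised) inflow trace for a set of selected voxels.

    Averages voxel traces within each slice, then across slices — the same
    aggregation used by :func:`select_inflow_voxels` — so the measurement
    noise of the selected-voxel signal can be estimated without smoothing.
    """
    if bold.is_regional:
        raise ValueError("requires a 4D BoldSeries")
    if not voxels:
        raise ValueError("no voxels given")
    by_slice: dict[int, list[np.ndarray]] = {}
    for coord in voxels:
        s = coord[bold.slice_axis]
        by_slice.setdefault(s, []).append(bold.data[tuple(coord)])
    slice_means = [np.mean(traces, axis=0) for traces in by_slice.values()]
    return np.mean(slice_means, axis=0)


@dataclass(frozen=True)
class InflowPeakFit:
    """Skew-normal + linear fit of the CSF inflow peak.

    ``hwhm_right`` is NaN when the fitted amplitude is not positive (no
    peak; the baseline carries the signal).
    """

    amplitude: float
    xi: float  # location, s
    omega: float  # scale, s
    alpha: float  # shape (skewness)
    a: float  # baseline intercept
    b: float  # baseline slope, signal units per s
    hwhm_right: float  # s
    rss: float
    window: tuple[int, int]

    def component(self, t: np.ndarray) -> np.ndarray:
        """Baseline-free skew-normal component evaluated at ``t`` (s)."""
        return _skew_component(np.asarray(t, float), self.amplitude, self.xi,
                               self.omega, self.alpha)

    def model(self, t: np.ndarray) -> np.ndarray:
        return skew_normal_model(t, self.amplitude, self.xi, self.omega,
                                 self.alpha, self.a, self.b)


def _peak_mode(amplitude: float, xi: float, omega: float, alpha: float) -> float:
    """Mode of the skew-normal component (numerical; no closed form)."""
    grid = xi + np.linspace(-3.0, 3.0, 3001) * omega
    vals = _skew_component(grid, amplitude, xi, omega, alpha)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_skew_component(np.asarray(t), amplitude, xi, omega, alpha),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9 * omega},
    )
    return float(res.x)


def hwhm_right(fit: InflowPeakFit) -> float:
    """Right-sided half width at half maximum of the fitted peak.

    Locates the mode of the baseline-free skew-normal component, then finds
    the unique point right of the mode where the component falls to half its
    peak value (bisection to 1e-6 * omega). The linear baseline never enters.
    For ``alpha = 0`` this equals ``omega * sqrt(2 ln 2)``.
    """
    if not fit.amplitude > 0:
        raise UndefinedWidthError("peak amplitude must be positive")
    amp, xi, om, al = fit.amplitude, fit.xi, fit.omega, fit.alpha
    t_peak = _peak_mode(amp, xi, om, al)
    half = 0.5 * _skew_component(np.asarray(t_peak), amp, xi, om, al)
    # bracket the crossing by doubling the step
    step = om
    hi = t_peak + step
    while _skew_component(np.asarray(hi), amp, xi, om, al) > half:
        step *= 2.0
        hi = t_peak + step
        if step > 1e6 * om:  # pragma: no cover - defensive
            raise UndefinedWidthError("half-height crossing not found")
    lo = max(t_peak, hi - step)
    tol = 1e-6 * om
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _skew_component(np.asarray(mid), amp, xi, om, al) > half:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) - t_peak


def fit_inflow_peak(
    inflow: np.ndarray,
    tr: float,
    window: tuple[int, int] = DEFAULT_INFLOW_WINDOW,
) -> InflowPeakFit:
    """Fit the inflow peak with a skew-normal density plus linear baseline.

    Nonlinear least squares over (amplitude, xi, omega, alpha, a, b) on the
    windowed trace. Initialization: xi at the detrended maximum, omega at a
    sixth of the window span, line through the window endpoints, amplitude
    from the detrended peak height; on failure the fit is restarted from
    shape values alpha0 in {-2, 2}. Bounds keep omega in (tr, span),
    |alpha| <= 20 and amplitude >= 0 (time-of-flight inflow cannot be
    negative).
    """
    y_full = np.asarray(inflow, dtype=float)
    if y_full.ndim != 1:
        raise ValueError("inflow trace must be 1D")
    w0, w1 = int(window[0]), int(window[1])
    if not (0 <= w0 < w1 < y_full.size):
        raise ValueError(f"window {window} outside series of {y_full.size} volumes")
    if w1 - w0 + 1 < 7:
        raise ValueError("window must contain at least 7 samples")
    t = np.arange(w0, w1 + 1) * tr
    y = y_full[w0 : w1 + 1]
    span = t[-1] - t[0]

    b0 = (y[-1] - y[0]) / span
    a0 = y[0] - b0 * t[0]
    resid = y - (a0 + b0 * t)
    i_pk = int(np.argmax(resid))
    xi0 = float(t[i_pk])
    omega0 = span / 6.0
    amp0 = max(float(resid[i_pk]), 1e-9) * omega0 * np.sqrt(2.0 * np.pi)

    lower = [0.0, t[0] - 0.5 * span, tr * (1 + 1e-6), -20.0, -np.inf, -np.inf]
    upper = [np.inf, t[-1] + 0.5 * span, span, 20.0, np.inf, np.inf]

    def model(tt, amp, xi, om, al, aa, bb):
        return _skew_component(tt, amp, xi, om, al) + aa + bb * tt

    best = None
    failures = []
    for alpha0 in (0.0, -2.0, 2.0):
        p0 = [amp0, xi0, min(max(omega0, tr * 2), span * 0.99), alpha0, a0, b0]
        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=p0, bounds=(lower, upper), maxfev=5000,
                x_scale=[max(amp0, 1e-6), span, span / 6.0, 4.0, 1.0, 1.0 / span],
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            failures.append(f"alpha0={alpha0}: {exc}")
            continue
        rss = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailureError(
            "inflow peak fit did not converge; attempts: " + "; ".join(failures)
        )
    popt, rss = best
    amp, xi, om, al, aa, bb = (float(v) for v in popt)
    fit = InflowPeakFit(
        amplitude=amp, xi=xi, omega=om, alpha=al, a=aa, b=bb,
        hwhm_right=np.nan, rss=rss, window=(w0, w1),
    )
    width = hwhm_right(fit) if amp > 0 else np.nan
    return InflowPeakFit(
        amplitude=amp, xi=xi, omega=om, alpha=al, a=aa, b=bb,
        hwhm_right=float(width), rss=rss, window=(w0, w1),
    )
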