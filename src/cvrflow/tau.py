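"""Vascular response time-constant (tau) estimation.

The BOLD response to a step change in arterial CO2 is modelled as the
end-tidal CO2 trace convolved with a causal exponential hemodynamic
response function h_tau(t) = (1/tau) exp(-t/tau). Tau is estimated by
exhaustive grid search: for each candidate tau the BOLD signal is regressed
on the convolved CO2 trace over the analysis window by ordinary least
squares, and the tau minimizing the residual sum of squares is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .errors import UndefinedFitError

__all__ = [
    "convolve_exponential",
    "default_tau_grid",
    "TauFitResult",
    "TauGridFitter",
    "fit_tau",
]

#: Default analysis window (volumes, inclusive): the hypercapnic-block
#: portion of the default protocol. With TR = 1.05 s this is 262.5-472.5 s.
DEFAULT_TAU_WINDOW = (250, 450)


def default_tau_grid() -> np.ndarray:
    """Candidate time constants: 0.5 s to 120 s in 0.5-s steps."""
    return np.arange(0.5, 120.0 + 1e-9, 0.5)


def convolve_exponential(signal: np.ndarray, tau: float, tr: float) -> np.ndarray:
    """Causal convolution with a unit-sum exponential kernel.

    The kernel is exp(-t/tau) sampled at ``tr`` and normalized to unit
    discrete sum, so a constant input is mapped to itself and regression
    amplitudes keep their per-mmHg interpretation independent of tau. The
    signal is assumed to sit at its initial value before the first sample
    (edge-hold), which matches a scan starting at gas baseline.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    if not tr > 0:
        raise ValueError("tr must be positive")
    x = np.asarray(signal, dtype=float)
    n = x.size
    # kernel support to 25 tau: truncation error < 2e-11 of the mass
    k = int(np.ceil(25.0 * tau / tr)) + 1
    h = np.exp(-np.arange(k) * tr / tau)
    h /= h.sum()
    if k > 1:
        x = np.concatenate([np.full(k - 1, x[0]), x])
    out = fftconvolve(x, h)[k - 1 : k - 1 + n]
    return out


@dataclass(frozen=True)
class TauFitResult:
    """Result of the exponential-HRF grid fit.

    ``beta1`` is the CVR amplitude (signal units per mmHg); ``beta2`` is the
    optional linear drift coefficient (signal units per volume), None when
    drift is not modelled. ``fitted`` covers the fit window only.
    """

    tau: float
    beta0: float
    beta1: float
    rss: float
    fitted: np.ndarray
    window: tuple[int, int]
    beta2: float | None = None
    tau_grid: np.ndarray | None = None
    rss_grid: np.ndarray | None = None


class TauGridFitter:
    """Precomputes convolved regressors for repeated tau fits.

    Convolving the CO2 trace with every candidate kernel dominates the cost
    of a single fit; when many BOLD traces share one CO2 trace (replicates,
    cohorts) the regressors are computed once here and each ``fit`` reduces
    to closed-form simple regressions.
    """

    def __init__(
        self,
        co2: np.ndarray,
        tr: float,
        window: tuple[int, int] = DEFAULT_TAU_WINDOW,
        tau_grid: np.ndarray | None = None,
        include_drift: bool = False,
    ) -> None:
        co2 = np.asarray(co2, dtype=float)
        if co2.ndim != 1:
            raise ValueError("co2 must be 1D")
        grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("tau grid must be nonempty and positive")
        if np.any(np.diff(grid) <= 0):
            grid = np.unique(grid)
        w0, w1 = int(window[0]), int(window[1])
        if not (0 <= w0 < w1 < co2.size):
            raise ValueError(f"window {window} outside series of {co2.size} volumes")
        if np.ptp(co2[w0 : w1 + 1]) == 0:
            raise UndefinedFitError("CO2 trace is constant within the fit window")
        self.tr = float(tr)
        self.window = (w0, w1)
        self.tau_grid = grid
        self.include_drift = include_drift
        # regressor matrix: one convolved, windowed CO2 trace per candidate tau
        self._reg = np.empty((grid.size, w1 - w0 + 1))
        for i, tau in enumerate(grid):
            self._reg[i] = convolve_exponential(co2, float(tau), self.tr)[w0 : w1 + 1]
        self._drift = np.arange(w0, w1 + 1, dtype=float)

    def fit(self, bold: np.ndarray) -> TauFitResult:
        w0, w1 = self.window
        y = np.asarray(bold, dtype=float)
        if y.ndim != 1 or y.size <= w1:
            raise ValueError("BOLD series shorter than the fit window")
        y = y[w0 : w1 + 1]
        R = self._reg
        grid = self.tau_grid
        if self.include_drift:
            rss = np.empty(grid.size)
            betas = np.empty((grid.size, 3))
            for i in range(grid.size):
                X = np.column_stack([np.ones(y.size), R[i], self._drift])
                coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                betas[i] = coef
                rss[i] = float(np.sum((y - X @ coef) ** 2))
        else:
            # closed-form simple regression per candidate tau
            rm = R.mean(axis=1)
            ym = y.mean()
            rc = R - rm[:, None]
            yc = y - ym
            srr = np.einsum("ij,ij->i", rc, rc)
            sry = rc @ yc
            syy = float(yc @ yc)
            with np.errstate(divide="ignore", invalid="ignore"):
                rss = syy - np.where(srr > 0, sry**2 / np.maximum(srr, 1e-300), 0.0)
            rss = np.where(srr > 0, rss, np.inf)
            if not np.any(np.isfinite(rss)):
                raise UndefinedFitError("all candidate regressors are degenerate")
        # np.argmin returns the first (smallest-tau) minimizer on exact ties
        i = int(np.argmin(rss))
        if self.include_drift:
            b0, b1, b2 = betas[i]
            fitted = b0 + b1 * R[i] + b2 * self._drift
        else:
            b1 = sry[i] / srr[i]
            b0 = ym - b1 * rm[i]
            b2 = None
            fitted = b0 + b1 * R[i]
        return TauFitResult(
            tau=float(grid[i]),
            beta0=float(b0),
            beta1=float(b1),
            rss=float(rss[i]),
            fitted=fitted,
            window=self.window,
            beta2=None if b2 is None else float(b2),
            tau_grid=grid,
            rss_grid=np.asarray(rss, float),
        )


def fit_tau(
    bold_gm: np.ndarray,
    co2: np.ndarray,
    tr: float,
    window: tuple[int, int] = DEFAULT_TAU_WINDOW,
    tau_grid: np.ndarray | None = None,
    include_drift: bool = False,
) -> TauFitResult:
    """Estimate tau by exhaustive grid search over exponential HRFs.

    For each tau in the grid the full CO2 trace is convolved with the
    unit-sum exponential kernel, the convolved trace is restricted to
    ``window`` (volume indices, inclusive), and the GM BOLD signal is
    regressed on it (with intercept, optional linear drift). The tau with
    minimal residual sum of squares wins; exact ties go to the smaller tau.
    """
    fitter = TauGridFitter(co2, tr, window=window, tau_grid=tau_grid,
                           include_drift=include_drift)
    return fitter.fit(bold_gm)
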