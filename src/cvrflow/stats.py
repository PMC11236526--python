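"""CSF-vascular coupling and group-level statistics.

Shifted cross-correlation between inflow and the CBV/CO2 derivative
surrogates, edema load, simple linear regression (tau versus inflow width,
tau versus edema load) and the paired pre/post comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import MaskVolume
from .errors import DegenerateTestError, UndefinedCorrelationError, UndefinedFitError
from .preprocess import _best_lag

__all__ = [
    "LagResult",
    "GroupRecord",
    "RegressionResult",
    "shifted_crosscorr",
    "edema_fraction",
    "regress",
    "paired_change_test",
]


@dataclass(frozen=True)
class LagResult:
    """Lag (s) and correlation at the best shift.

    Positive lag means the second signal is delayed relative to the first:
    ``shifted_crosscorr(reference, inflow)`` returns a positive lag when the
    inflow peak follows the reference peak.
    """

    lag: float  # s
    r_max: float
    max_lag: float  # searched range, s

    def __post_init__(self) -> None:
        if abs(self.r_max) > 1 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")
        if abs(self.lag) > self.max_lag + 1e-12:
            raise ValueError("lag outside the searched range")


@dataclass(frozen=True)
class GroupRecord:
    """One dataset's summary row for cohort analyses.

    ``hwhm_right`` is NaN when the dataset showed no inflow signal; such
    datasets are excluded from inflow analyses but kept for tau analyses.
    """

    dataset_id: str
    timepoint: str  # "pre" or "post"
    tau: float
    edema_fraction: float
    hwhm_right: float = float("nan")
    inflow_present: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError("timepoint must be 'pre' or 'post'")
        if not (0 <= self.edema_fraction < 1):
            raise ValueError("edema_fraction must be in [0, 1)")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def shifted_crosscorr(
    x: np.ndarray, y: np.ndarray, tr: float, max_lag: float
) -> LagResult:
    """Pearson correlation maximized over integer-volume shifts.

    Shifts span ``[-max_lag, +max_lag]`` seconds (floored to whole volumes);
    at each shift only overlapping samples enter the correlation (no
    padding), the signed maximum is kept (anticorrelation is not chased),
    and ties break toward the smallest absolute lag. The returned lag is in
    seconds and is positive when ``y`` lags ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input has undefined correlation")
    if not tr > 0:
        raise ValueError("tr must be positive")
    max_lag_vols = int(np.floor(max_lag / tr))
    if max_lag_vols < 0 or x.size - max_lag_vols < 3:
        raise ValueError("max_lag leaves too little overlap")
    lag, r = _best_lag(x, y, max_lag_vols)
    return LagResult(lag=lag * tr, r_max=r, max_lag=max_lag)


def edema_fraction(mask: MaskVolume) -> float:
    """Edema voxel count relative to the whole-brain voxel count."""
    n_brain = int(mask.brain.sum())
    if n_brain == 0:
        raise ValueError("brain mask is empty")
    return float(mask.edema.sum() / n_brain)


def regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least-squares simple regression of y on x.

    Two-sided p-value for the slope from the t distribution with n - 2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise UndefinedFitError("constant x: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def paired_change_test(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t test on post - pre differences.

    By convention identical pre/post values return ``(0.0, 1.0)``; a
    constant nonzero difference (zero variance, nonzero mean) raises
    :class:`DegenerateTestError` because the t statistic is unbounded.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1D arrays of equal length")
    if pre.size < 2:
        raise ValueError("paired test needs at least 2 pairs")
    d = post - pre
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateTestError("zero-variance nonzero differences")
    t, p = sps.ttest_rel(post, pre)
    return float(t), float(p)
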