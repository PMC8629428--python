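"""Regression models and ratio arithmetic for per-sheet summary metrics.

Covers the intensity-intensity linear regression across membrane sheets with
a Welch-style comparison of slopes between conditions, the exponential decay
of the clustering degree with staining intensity,
``y = (a - b) exp(-d x) + b``, and the copy-number ratio propagation used to
relate overexpression folds and plasma-membrane fractions to the
SNAP25:syntaxin ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    n: int
    r2: float

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass
class ExpDecayFit:
    """Fit of y = (a - b) exp(-d x) + b: value a at x = 0, asymptote b."""

    a: float
    b: float
    d: float
    r2: float
    d_identifiable: bool = True

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        return (self.a - self.b) * np.exp(-self.d * np.asarray(x, dtype=float)) + self.b


@dataclass
class RatioScenario:
    """Propagation of a baseline copy-number ratio through fold changes.

    ``base_ratio`` is the physiological numerator:denominator fold;
    ``fold_a``/``fold_b`` are the multiplicative changes of the two species;
    ``pm_fraction_a``/``pm_fraction_b`` the fractions localized to the plasma
    membrane.
    """

    base_ratio: float
    fold_a: float = 1.0
    fold_b: float = 1.0
    pm_fraction_a: float = 1.0
    pm_fraction_b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("base_ratio", "fold_a", "fold_b", "pm_fraction_a", "pm_fraction_b"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.pm_fraction_a > 1 or self.pm_fraction_b > 1:
            raise ValueError("plasma-membrane fractions must be <= 1")


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares line with slope standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        n=len(x),
        r2=float(res.rvalue) ** 2,
    )


def compare_slopes(fit1: LinearFit, fit2: LinearFit) -> tuple[float, float]:
    """Two-tailed Welch-style t-test for equality of two regression slopes.

    t = (slope1 - slope2) / sqrt(se1^2 + se2^2), degrees of freedom by
    Welch-Satterthwaite with per-fit df = n - 2.  Returns (t, p).
    """
    se1, se2 = fit1.slope_se, fit2.slope_se
    if not (se1 > 0 and se2 > 0) or not (math.isfinite(se1) and math.isfinite(se2)):
        raise ValueError("slope standard errors must be positive and finite")
    v1, v2 = se1**2, se2**2
    t = (fit1.slope - fit2.slope) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / fit1.df + v2**2 / fit2.df)
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def _exp_model(x, a, b, d):
    return (a - b) * np.exp(-d * x) + b


def exp_decay_fit(x, y, init: tuple[float, float, float] | None = None) -> ExpDecayFit:
    """Nonlinear least squares for y = (a - b) exp(-d x) + b.

    Default initialization: a = y at the smallest x, b = y at the largest x,
    and d from a log-linearized first pass on (y - b); unweighted residuals.
    A constant response yields a = b = const with d flagged unidentifiable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("need equal-length 1-D arrays with n >= 4")
    if np.any(x < 0):
        raise ValueError("x must be non-negative")

    if np.ptp(y) == 0:
        return ExpDecayFit(a=float(y[0]), b=float(y[0]), d=0.0, r2=1.0, d_identifiable=False)

    if init is None:
        order = np.argsort(x)
        a0 = float(y[order[0]])
        b0 = float(y[order[-1]])
        resid = y - b0
        sign = np.sign(a0 - b0) or 1.0
        pos = sign * resid > 0
        if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
            slope = np.polyfit(x[pos], np.log(np.abs(resid[pos])), 1)[0]
            d0 = max(-slope, 1e-6)
        else:
            d0 = 1.0 / max(np.ptp(x), 1.0)
        init = (a0, b0, d0)

    try:
        popt, _ = optimize.curve_fit(_exp_model, x, y, p0=init, maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"exponential fit did not converge (init={init})") from err
    a, b, d = (float(v) for v in popt)
    resid = y - _exp_model(x, a, b, d)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot
    identifiable = abs(a - b) > 1e-10 * max(1.0, abs(a), abs(b))
    return ExpDecayFit(a=a, b=b, d=d, r2=r2, d_identifiable=identifiable)


def relative_staining_increase(pct_a: float, pct_b: float, offset_pct: float = 100.0) -> float:
    """Fold increase of condition A over B after removing a common offset.

    Both inputs are percent-of-control values; the control level
    (``offset_pct``, typically 100) is subtracted from each before the ratio
    is taken, so the ratio reflects the added staining only.
    """
    if pct_a <= offset_pct or pct_b <= offset_pct:
        raise ValueError("both percentages must exceed the offset")
    return (pct_a - offset_pct) / (pct_b - offset_pct)


def expression_ratio(s: RatioScenario) -> float:
    """Copy-number ratio after fold changes and plasma-membrane partitioning.

    base_ratio * (fold_a * pm_fraction_a) / (fold_b * pm_fraction_b).
    """
    return s.base_ratio * (s.fold_a * s.pm_fraction_a) / (s.fold_b * s.pm_fraction_b)
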