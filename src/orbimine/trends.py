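"""Trend regression of mining statistics on profile information content.

Hit proportions and string/hit ratios are regressed on profile information
content under three model families: linear y = a + b*x, exponential
y = a*exp(b*x) and power y = a*x^b.  Exponential and power models are fitted
by least squares on the log-transformed response (and log x for power), the
spreadsheet-trendline convention; an optional nonlinear refinement
(Levenberg-Marquardt) is available.  R^2 is always reported on the original
scale of y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class TrendInputError(ValueError):
    pass


MODELS = ("linear", "exponential", "power")


@dataclass
class TrendFit:
    model: str
    a: float
    b: float
    r_squared: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            return self.a + self.b * x
        if self.model == "exponential":
            return self.a * np.exp(self.b * x)
        return self.a * x ** self.b


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_trend(x, y, model: str, refine: bool = False) -> TrendFit:
    """Fit one trend model; see module docstring for conventions."""
    if model not in MODELS:
        raise TrendInputError(f"unknown model {model!r}; choose from {MODELS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TrendInputError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise TrendInputError("need at least 2 points")
    if model in ("exponential", "power"):
        bad = np.nonzero(y <= 0)[0]
        if bad.size:
            raise TrendInputError(
                f"nonpositive y at index {bad[0]} (y={y[bad[0]]!r}) "
                f"invalid for {model} fit")
    if model == "power":
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            raise TrendInputError(
                f"nonpositive x at index {bad[0]} (x={x[bad[0]]!r}) "
                "invalid for power fit")

    if model == "linear":
        b, a = np.polyfit(x, y, 1)
    elif model == "exponential":
        b, log_a = np.polyfit(x, np.log(y), 1)
        a = float(np.exp(log_a))
    else:
        b, log_a = np.polyfit(np.log(x), np.log(y), 1)
        a = float(np.exp(log_a))

    if refine and model != "linear":
        func = ((lambda t, a_, b_: a_ * np.exp(b_ * t)) if model == "exponential"
                else (lambda t, a_, b_: a_ * t ** b_))
        try:
            (a, b), _ = curve_fit(func, x, y, p0=(a, b), maxfev=10000)
        except RuntimeError:
            pass  # keep the log-linear estimate

    fit = TrendFit(model, float(a), float(b), 0.0, len(x))
    fit.r_squared = _r_squared(y, fit.predict(x))
    return fit


@dataclass
class RatioSummary:
    mean: float
    sd: float
    n: int
    single_value: bool


def summarize_ratios(ratios) -> RatioSummary:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    A single value yields sd = 0 with the ``single_value`` flag set.
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise TrendInputError("summarize_ratios requires at least one value")
    if r.size == 1:
        return RatioSummary(float(r[0]), 0.0, 1, True)
    return RatioSummary(float(r.mean()), float(r.std(ddof=1)), int(r.size), False)
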