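"""Logistic saturation curves for variant counts, and the tangent-slope criteria.

Variant counts y_raw observed along a titration axis x (sequencing coverage
in ×, or iteration round) saturate; on a log2 scale the series is well fitted
by a logistic

    rising:  y = a / (1 + b * exp(-c x))      (coverage titration, increasing)
    falling: y = a / (1 - b * exp(-c x))      (iteration rounds, decreasing)

with asymptote a (log2 counts), shape b and rate c, all positive.  The
operational decisions both use the analytic tangent slope dy/dx:

* optimal coverage — the x past the inflection where the rising slope falls
  to a threshold tau (1e-4 by default), rounded up to an integer coverage;
* optimal iterations — the smallest round n >= 2 where |slope| <= tau.

The log base is 2 because the fitted asymptotes then coincide with the log2
of the terminal variant counts; it is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class LogisticFit:
    """Fitted logistic parameters; ``orientation`` is 'rising' or 'falling'.

    ``r_squared`` is the coefficient of determination 1 − SS_res/SS_tot on the
    log scale; ``correlation`` is the Pearson correlation between observed and
    fitted values — the goodness-of-fit statistic curve-fitting desktop tools
    conventionally print, so it is the number to compare against published
    fit tables.
    """

    a: float
    b: float
    c: float
    orientation: str
    r_squared: float = float("nan")
    correlation: float = float("nan")

    def __post_init__(self) -> None:
        if self.orientation not in ("rising", "falling"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("logistic parameters a, b, c must all be positive")

    @property
    def sign(self) -> float:
        return 1.0 if self.orientation == "rising" else -1.0


@dataclass
class CurveSeries:
    """A titration series: x (coverage or round), raw counts, and log counts."""

    x: np.ndarray
    y_raw: np.ndarray
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y_raw = np.asarray(self.y_raw, dtype=float)
        if self.x.size != self.y_raw.size:
            raise ValueError("x and y_raw must have equal length")
        if np.any(np.diff(self.x) <= 0) or np.any(self.x <= 0):
            raise ValueError("x must be strictly increasing and positive")
        if np.any(self.y_raw <= 0):
            raise ValueError("y_raw must be positive (log-transform required)")

    @property
    def y(self) -> np.ndarray:
        return np.log(self.y_raw) / np.log(self.log_base)


def logistic_eval(fit: LogisticFit, x) -> np.ndarray | float:
    """Evaluate y = a / (1 ± b e^(−c x)); domain error if the denominator ≤ 0."""
    x = np.asarray(x, dtype=float)
    denom = 1.0 + fit.sign * fit.b * np.exp(-fit.c * x)
    if np.any(denom <= 0):
        raise ValueError(
            "falling logistic undefined where b*exp(-c*x) >= 1 "
            f"(a={fit.a}, b={fit.b}, c={fit.c})"
        )
    out = fit.a / denom
    return float(out) if out.ndim == 0 else out


def tangent_slope(fit: LogisticFit, x) -> np.ndarray | float:
    """Analytic dy/dx: ±a·b·c·e^(−cx) / (1 ± b·e^(−cx))²."""
    x = np.asarray(x, dtype=float)
    e = np.exp(-fit.c * x)
    denom = 1.0 + fit.sign * fit.b * e
    if np.any(denom <= 0):
        raise ValueError("slope undefined where the logistic denominator vanishes")
    out = fit.sign * fit.a * fit.b * fit.c * e / denom**2
    return float(out) if out.ndim == 0 else out


def _model(orientation: str):
    sign = 1.0 if orientation == "rising" else -1.0

    def f(x, a, b, c):
        return a / (1.0 + sign * b * np.exp(-c * x))

    return f


def _initial_guess(x: np.ndarray, y: np.ndarray, orientation: str) -> tuple[float, float, float]:
    # Linearize: |a/y - 1| = b e^{-cx}  ->  log is linear in x.
    if orientation == "rising":
        a0 = float(y.max()) * 1.001
        resid = a0 / y - 1.0
    else:
        a0 = float(y.min()) * 0.999
        resid = 1.0 - a0 / y
    resid = np.clip(resid, 1e-12, None)
    slope, intercept = np.polyfit(x, np.log(resid), 1)
    c0 = max(-slope, 1e-3)
    b0 = float(np.clip(math.exp(intercept), 1e-6, None))
    if orientation == "falling":
        b0 = min(b0, 0.95)
    return a0, b0, c0


def fit_logistic(
    series: CurveSeries,
    orientation: str,
    max_restarts: int = 20,
    seed: int = 0,
) -> LogisticFit:
    """Nonlinear least squares of the logistic on (x, log y_raw).

    Starts from a linearized guess; on non-convergence the guess is perturbed
    up to ``max_restarts`` times before giving up.
    """
    x, y = series.x, series.y
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter logistic")
    model = _model(orientation)
    p0 = _initial_guess(x, y, orientation)
    upper_b = np.inf if orientation == "rising" else 1.0 - 1e-9
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    guess = np.array(p0)
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = optimize.curve_fit(
                model, x, y, p0=guess,
                bounds=([1e-9, 1e-9, 1e-9], [np.inf, upper_b, np.inf]),
                maxfev=20000,
            )
            a, b, c = (float(v) for v in popt)
            pred = model(x, a, b, c)
            ss_res = float(np.sum((y - pred) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            corr = float(np.corrcoef(y, pred)[0, 1]) if y.size > 1 else 1.0
            return LogisticFit(
                a=a, b=b, c=c, orientation=orientation, r_squared=r2, correlation=corr
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            factors = rng.uniform(0.5, 2.0, size=3)
            guess = np.clip(np.array(p0) * factors, 1e-6, None)
            if orientation == "falling":
                guess[1] = min(guess[1], 0.95)
    raise RuntimeError(
        f"logistic fit failed to converge after {max_restarts} restarts "
        f"(orientation={orientation}, initial guess={p0}): {last_err}"
    )


@dataclass
class ThresholdResult:
    """Where the tangent slope crosses tau; ``recommendation`` = ceil(x_star)."""

    x_star: float
    recommendation: int
    boundary_warning: bool = False


def threshold_coverage(fit: LogisticFit, tau: float = 1e-4, x_max: float = 1e4) -> ThresholdResult:
    """Coverage at which the rising tangent slope decays to ``tau``.

    The slope of a rising logistic peaks at the inflection x = ln(b)/c and
    decays monotonically to the right; the crossing is bracketed there and
    solved by bisection to |Δx| <= 1e-4.  If the slope never exceeds tau the
    lower domain bound is returned with a warning flag.
    """
    if fit.orientation != "rising":
        raise ValueError("threshold_coverage expects a rising fit")
    x_lo = max(math.log(fit.b) / fit.c, 1e-9)
    if tangent_slope(fit, x_lo) <= tau:
        return ThresholdResult(x_star=x_lo, recommendation=math.ceil(x_lo), boundary_warning=True)
    x_hi = x_lo + 1.0
    while tangent_slope(fit, x_hi) > tau:
        x_hi = x_lo + (x_hi - x_lo) * 2.0
        if x_hi > x_max:
            raise ValueError(f"slope stays above tau={tau} out to x={x_max}")
    x_star = optimize.brentq(lambda x: tangent_slope(fit, x) - tau, x_lo, x_hi, xtol=1e-4)
    return ThresholdResult(x_star=float(x_star), recommendation=math.ceil(x_star))


def optimal_iterations(fit: LogisticFit, tau: float = 1e-4, n_max: int = 1000) -> int:
    """Smallest round n >= 2 with |tangent slope| <= tau on a falling fit."""
    if fit.orientation != "falling":
        raise ValueError("optimal_iterations expects a falling fit")
    for n in range(2, n_max + 1):
        if abs(tangent_slope(fit, n)) <= tau:
            return n
    raise ValueError(f"|slope| never reaches tau={tau} within {n_max} rounds")


def multi_breed_recommendation(
    fits: list[LogisticFit], tau: float = 1e-4
) -> ThresholdResult:
    """Coverage recommendation across breeds: the slowest-saturating one rules."""
    if not fits:
        raise ValueError("need at least one fit")
    results = [threshold_coverage(f, tau) for f in fits]
    worst = max(results, key=lambda r: r.x_star)
    return ThresholdResult(
        x_star=worst.x_star,
        recommendation=math.ceil(worst.x_star),
        boundary_warning=any(r.boundary_warning for r in results),
    )
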