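"""The GM(1,1) grey prediction model.

The model fits a short positive series x(0)(1..n) by first accumulating it
(1-AGO), x(1)(m) = sum_{k<=m} x(0)(k), then regressing the original values on
the adjacent means z(k) = (x(1)(k) + x(1)(k-1))/2 of the accumulated series:

    x(0)(k) + a z(k) = b,   k = 2..n

(a, b) solve the normal equations of this regression; a is the development
coefficient (a < 0 means a growing series), b the grey action quantity.  The
fitted/predicted values on the original scale come from the restored response
function

    xhat(0)(m) = (1 - e^a) (x(0)(1) - b/a) e^{-a (m-1)},   m >= 2,

a geometric sequence with per-step ratio e^{-a}.  The a -> 0 limit is the
constant forecast b.  |a| <= 0.3 is the conventional applicability range for
short/medium-term prediction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .series import EquidistantSeries, validate_for_modeling

__all__ = [
    "GM11Model",
    "accumulate",
    "adjacent_means",
    "estimate_parameters",
    "restored_value",
    "fit_and_forecast",
    "applicability_class",
]

#: Development coefficients at or above this bound suit short/medium horizons.
APPLICABILITY_BOUND = -0.3


def accumulate(values) -> np.ndarray:
    """First-order accumulating generation operator (1-AGO): running sums."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot accumulate an empty sequence")
    return np.cumsum(values)


def adjacent_means(ago_values) -> np.ndarray:
    """Pairwise means of consecutive 1-AGO values; length n-1."""
    ago_values = np.asarray(ago_values, dtype=float)
    if ago_values.size < 2:
        raise ValueError("need at least 2 accumulated values")
    return (ago_values[1:] + ago_values[:-1]) / 2.0


@dataclass(frozen=True)
class GM11Model:
    """Estimated GM(1,1) parameters bound to the series they were fitted on."""

    a: float
    b: float
    x1: float
    restored_coefficient: float
    n_fit: int
    source: EquidistantSeries

    def to_dict(self) -> dict:
        s = self.source
        return {
            "a": self.a,
            "b": self.b,
            "x1": self.x1,
            "restored_coefficient": self.restored_coefficient,
            "n_fit": self.n_fit,
            "origin_year": s.origin_year,
            "step_years": s.step_years,
            "has_prefix": s.has_prefix,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def estimate_parameters(series: EquidistantSeries) -> GM11Model:
    """Least-squares estimate of (a, b) from the adjacent-mean regression.

    The 2x2 normal equations are solved in closed centered form: with
    y(k) = x(0)(k) and regressor z(k),

        slope = cov(z, y) / var(z),   a = -slope,   b = mean(y) + a mean(z).

    A constant adjacent-mean sequence (var(z) = 0) makes the normal equations
    singular; for positive data this cannot occur with n >= 3, but it is
    guarded explicitly.  A zero slope (a = 0) is a legitimate degenerate
    model: the restored coefficient then equals b (constant forecast).
    """
    report = validate_for_modeling(series)
    if not report.ok:
        raise ValueError("series not modelable: " + "; ".join(report.messages))
    x0 = np.asarray(series.values, dtype=float)
    z = adjacent_means(accumulate(x0))
    y = x0[1:]
    dz = z - z.mean()
    dz2 = float(dz @ dz)
    if dz2 == 0.0:
        raise ValueError("singular normal equations: constant adjacent means")
    slope = float(dz @ (y - y.mean())) / dz2
    a = -slope
    b = float(y.mean() + a * z.mean())
    x1 = float(x0[0])
    if a != 0.0:
        # -expm1(a) rather than (1 - e^a): the direct form cancels to zero
        # for |a| below machine epsilon while b/a still diverges
        coef = -math.expm1(a) * (x1 - b / a)
    else:
        coef = b
    return GM11Model(a=a, b=b, x1=x1, restored_coefficient=coef,
                     n_fit=len(x0) - 1, source=series)


def restored_value(model: GM11Model, m: int) -> float:
    """Value of the restored response function at slot m >= 2."""
    if m < 2:
        raise ValueError("slot 1 is the initial value and is never restored")
    if model.a == 0.0:
        return model.b
    return model.restored_coefficient * math.exp(-model.a * (m - 1))


def fit_and_forecast(model: GM11Model, horizon_steps: int = 0) -> tuple[tuple[int, ...], np.ndarray]:
    """Fitted values for every real observation slot plus horizon predictions.

    Returns (years, values): fitted values at m = 2..n, then ``horizon_steps``
    further predictions at consecutive slots, each paired with its calendar
    year from the source series' grid.
    """
    if horizon_steps < 0:
        raise ValueError("horizon_steps must be non-negative")
    n = len(model.source)
    slots = range(2, n + 1 + horizon_steps)
    years = tuple(model.source.year(m) for m in slots)
    values = np.array([restored_value(model, m) for m in slots])
    return years, values


def applicability_class(model: GM11Model) -> str:
    """'short_medium_term_ok' iff a >= -0.3, else 'out_of_range'."""
    return "short_medium_term_ok" if model.a >= APPLICABILITY_BOUND else "out_of_range"
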