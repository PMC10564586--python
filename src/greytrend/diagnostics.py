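"""Model-quality battery for a GM(1,1) fit.

Residuals and per-point precision, mean relative error, the posterior
variance test (mean-square-error ratio C and small-error probability P), and
a four-level grade.  Conventions fixed here:

* S1 and S2 are *population* (divide-by-n) standard deviations of the
  original values entering the regression and of the residuals.  C = S2/S1
  is invariant to the n vs n-1 choice (the factor cancels); P is not, and the
  population form is the standard grey-literature convention.
* Residuals are centered before the P threshold test:
  P = #{|e_k - mean(e)| < 0.6745 S1} / n.
* Grade thresholds, applied with strict inequalities:

  ===========  =======  =======  ============
  level        C        P        precision
  ===========  =======  =======  ============
  1 Excellent  < 0.35   > 0.95   > 99.0%
  2 Good       < 0.50   > 0.80   > 95.0%
  3 Qualified  < 0.65   > 0.70   > 90.0%
  4 Nonconforming (otherwise)
  ===========  =======  =======  ============

  The overall grade is the *worst* of the three criterion grades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GM11Model, fit_and_forecast
from .series import EquidistantSeries

__all__ = [
    "FitDiagnostics",
    "residual_table",
    "mean_relative_error",
    "posterior_variance_test",
    "grade_model",
    "diagnose",
    "GRADE_LABELS",
]

GRADE_LABELS = {1: "Excellent", 2: "Good", 3: "Qualified", 4: "Nonconforming"}

_C_THRESHOLDS = (0.35, 0.50, 0.65)
_P_THRESHOLDS = (0.95, 0.80, 0.70)
_PRECISION_THRESHOLDS = (99.0, 95.0, 90.0)


@dataclass(frozen=True)
class FitDiagnostics:
    table: pd.DataFrame            # per-year original/fitted/residual/precision
    mean_relative_error: float     # %
    average_relative_precision: float  # % == 100 - mean_relative_error
    c_ratio: float
    small_error_probability: float
    grade: int

    @property
    def grade_label(self) -> str:
        return GRADE_LABELS[self.grade]

    def to_dict(self) -> dict:
        return {
            "mean_relative_error_pct": self.mean_relative_error,
            "average_relative_precision_pct": self.average_relative_precision,
            "c_ratio": self.c_ratio,
            "small_error_probability": self.small_error_probability,
            "grade": self.grade,
            "grade_label": self.grade_label,
        }


def _regression_originals(series: EquidistantSeries) -> np.ndarray:
    """Observations entering the grey regression: slots m = 2..n.

    For a prefixed series these are all real observations; without a prefix
    the first observation serves as the initial value and has no fitted
    counterpart.
    """
    return np.asarray(series.values[1:], dtype=float)


def _check_lengths(series: EquidistantSeries, fitted) -> np.ndarray:
    fitted = np.asarray(fitted, dtype=float)
    n = len(series) - 1
    if fitted.shape != (n,):
        raise ValueError(
            f"fitted length {fitted.size} does not match the {n} regression observations")
    return fitted


def residual_table(series: EquidistantSeries, fitted) -> pd.DataFrame:
    """Per-year rows: original, fitted, residual (original - fitted), precision %."""
    fitted = _check_lengths(series, fitted)
    original = _regression_originals(series)
    years = [series.year(m) for m in range(2, 2 + original.size)]
    residual = original - fitted
    precision = 100.0 * (1.0 - np.abs(residual) / original)
    return pd.DataFrame({
        "year": years,
        "original": original,
        "fitted": fitted,
        "residual": residual,
        "precision_pct": precision,
    })


def mean_relative_error(series: EquidistantSeries, fitted) -> float:
    """Mean of 100 |original - fitted| / original over the real observations (%)."""
    fitted = _check_lengths(series, fitted)
    original = _regression_originals(series)
    return float(np.mean(100.0 * np.abs(original - fitted) / original))


def posterior_variance_test(series: EquidistantSeries, residuals) -> tuple[float, float]:
    """Mean-square-error ratio C and small-error probability P.

    C = S2/S1 with S1, S2 the population SDs of the originals and residuals;
    P is the fraction of centered residuals smaller than 0.6745 S1.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 2:
        raise ValueError("need at least 2 residuals")
    original = _regression_originals(series)
    if original.size != residuals.size:
        raise ValueError("residuals must match the regression observations")
    s1 = float(np.std(original))
    if s1 == 0.0:
        raise ValueError("constant original values: C is undefined")
    s2 = float(np.std(residuals))
    centered = np.abs(residuals - residuals.mean())
    p = float(np.mean(centered < 0.6745 * s1))
    return s2 / s1, p


def _criterion_grade(value: float, thresholds, larger_is_better: bool) -> int:
    for level, t in enumerate(thresholds, start=1):
        if (value > t) if larger_is_better else (value < t):
            return level
    return 4


def grade_model(c_ratio: float, small_error_probability: float,
                average_relative_precision: float) -> tuple[int, str]:
    """Worst-criterion grade over C, P and average relative precision."""
    g = max(
        _criterion_grade(c_ratio, _C_THRESHOLDS, larger_is_better=False),
        _criterion_grade(small_error_probability, _P_THRESHOLDS, larger_is_better=True),
        _criterion_grade(average_relative_precision, _PRECISION_THRESHOLDS, larger_is_better=True),
    )
    return g, GRADE_LABELS[g]


def diagnose(model: GM11Model) -> FitDiagnostics:
    """Full battery for an estimated model against its own source series."""
    series = model.source
    _, fitted = fit_and_forecast(model, horizon_steps=0)
    tab = residual_table(series, fitted)
    mre = mean_relative_error(series, fitted)
    precision = 100.0 - mre
    c, p = posterior_variance_test(series, tab["residual"].to_numpy())
    grade, _ = grade_model(c, p, precision)
    return FitDiagnostics(table=tab, mean_relative_error=mre,
                          average_relative_precision=precision,
                          c_ratio=c, small_error_probability=p, grade=grade)
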