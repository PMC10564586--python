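"""Survey-wave series and their preparation for grey modeling.

GM(1,1) requires a strictly positive, equidistant series of at least four
points.  National surveillance waves are five years apart except the fourth
wave (2014), which sits one year off the grid; that single off-grid point is
moved onto the grid by linear extrapolation along the slope of the preceding
inter-wave gap.  A short series may additionally be prefix-augmented: an
arbitrary positive value is prepended so that every real observation enters
the least-squares step (forecasts are provably invariant to the prefix value).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

__all__ = [
    "Indicator",
    "Sex",
    "ObservationSeries",
    "EquidistantSeries",
    "ValidationReport",
    "extrapolate_to_grid",
    "prepend_prefix",
    "validate_for_modeling",
]


class Indicator(str, Enum):
    HEIGHT = "height"
    WEIGHT = "weight"
    CHEST_CIRCUMFERENCE = "chest_circumference"
    BMI = "bmi"
    OVERWEIGHT_RATE = "overweight_rate"
    OBESITY_RATE = "obesity_rate"


class Sex(str, Enum):
    BOYS = "boys"
    GIRLS = "girls"


#: Indicators that are prevalence percentages rather than anthropometry.
RATE_INDICATORS = frozenset({Indicator.OVERWEIGHT_RATE, Indicator.OBESITY_RATE})


@dataclass(frozen=True)
class ObservationSeries:
    """A labeled year -> value series from survey waves.

    ``age_years`` is None for prevalence-rate series, which pool ages 3-6.
    """

    indicator: Indicator
    sex: Sex
    points: tuple[tuple[int, float], ...]
    age_years: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicator", Indicator(self.indicator))
        object.__setattr__(self, "sex", Sex(self.sex))
        years = [y for y, _ in self.points]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if any(v <= 0 for _, v in self.points):
            raise ValueError("all values must be strictly positive")
        if self.age_years is not None and not 3 <= self.age_years <= 6:
            raise ValueError("age_years must be in 3..6")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(y for y, _ in self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class EquidistantSeries:
    """Constant-step modeling series with an optional artificial prefix slot.

    Slots are indexed m = 1..n.  When ``has_prefix`` is set, slot m=1 holds an
    artificial value and the first real observation sits at m=2; ``origin_year``
    always refers to the first *real* observation.
    """

    origin_year: int
    step_years: int
    values: tuple[float, ...]
    has_prefix: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.step_years <= 0:
            raise ValueError("step_years must be positive")
        if any(v <= 0 for v in self.values):
            raise ValueError("all values must be strictly positive")

    @property
    def n_real(self) -> int:
        return len(self.values) - (1 if self.has_prefix else 0)

    @property
    def real_values(self) -> tuple[float, ...]:
        return self.values[1:] if self.has_prefix else self.values

    def year(self, m: int) -> int:
        """Calendar year of slot m (1-based)."""
        offset = m - 2 if self.has_prefix else m - 1
        return self.origin_year + offset * self.step_years

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    messages: tuple[str, ...] = field(default_factory=tuple)


def extrapolate_to_grid(series: ObservationSeries, step_years: int) -> EquidistantSeries:
    """Move the single off-grid observation onto the survey grid.

    The grid is anchored at the first observation year with spacing
    ``step_years``.  An observation at off-grid year y is carried forward to
    the nearest grid year g > y along the local slope from the previous
    on-grid point p::

        value(g) = value(y) + (value(y) - value(p)) * (g - y) / (y - p)

    On-grid observations pass through bit-exactly.
    """
    if step_years <= 0:
        raise ValueError("step_years must be positive")
    years, values = series.years, series.values
    origin = years[0]
    out_years: list[int] = []
    out_values: list[float] = []
    n_off_grid = 0
    for i, (y, v) in enumerate(zip(years, values)):
        if (y - origin) % step_years == 0:
            out_years.append(y)
            out_values.append(v)
            continue
        n_off_grid += 1
        if n_off_grid > 1:
            raise ValueError("more than one off-grid observation: unsupported layout")
        if i == 0:
            raise ValueError("first observation defines the grid and cannot be off-grid")
        g = origin + ((y - origin) // step_years + 1) * step_years
        py, pv = out_years[-1], out_values[-1]
        moved = v + (v - pv) * (g - y) / (y - py)
        if moved <= 0:
            raise ValueError(f"extrapolated value at {g} is non-positive ({moved:.4g})")
        out_years.append(g)
        out_values.append(moved)
    if any(b - a != step_years for a, b in zip(out_years, out_years[1:])):
        raise ValueError("observations do not fall on a constant-step grid")
    label = _label(series)
    return EquidistantSeries(origin_year=origin, step_years=step_years,
                             values=tuple(out_values), label=label)


def prepend_prefix(series: EquidistantSeries, prefix_value: float = 10.0) -> EquidistantSeries:
    """Prepend the artificial slot-1 value; real observations shift to m=2..n+1."""
    if series.has_prefix:
        raise ValueError("series is already prefixed")
    if prefix_value <= 0:
        raise ValueError("prefix value must be strictly positive")
    return replace(series, values=(float(prefix_value),) + series.values, has_prefix=True)


def validate_for_modeling(series: EquidistantSeries) -> ValidationReport:
    """Check the minimum requirements for a GM(1,1) fit.

    A report (never an exception): at least 4 real observations, all values
    strictly positive, constant step.  Positivity and step constancy are
    enforced by the type's own invariants, so violations can only be reported
    for series built by other means; the length check is the live one.
    """
    messages: list[str] = []
    if series.n_real < 4:
        messages.append(f"fewer than 4 data: {series.n_real} real observations")
    if any(v <= 0 for v in series.values):
        messages.append("non-positive value present")
    if series.step_years <= 0:
        messages.append("step must be a positive number of years")
    return ValidationReport(ok=not messages, messages=tuple(messages))


def _label(series: ObservationSeries) -> str:
    parts = [series.indicator.value, series.sex.value]
    if series.age_years is not None:
        parts.append(f"age{series.age_years}")
    return "/".join(parts)


def series_from_values(years: Sequence[int], values: Sequence[float],
                       indicator: Indicator = Indicator.HEIGHT,
                       sex: Sex = Sex.BOYS,
                       age_years: int | None = None) -> ObservationSeries:
    """Convenience constructor from parallel year/value sequences."""
    if len(years) != len(values):
        raise ValueError("years and values must have equal length")
    return ObservationSeries(indicator=indicator, sex=sex, age_years=age_years,
                             points=tuple(zip(map(int, years), map(float, values))))
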