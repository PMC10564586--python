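# greytrend

Grey GM(1,1) forecasting for short anthropometric time series, packaged
around a complete secular-trend analysis of Chinese preschool children
(ages 3–6) over the five national physical-fitness surveillance waves
(2000, 2005, 2010, 2014, 2020), with projections to 2025 and 2030.

## Who this is for

Epidemiologists and biostatisticians working with *short* summary series —
four to six survey waves of mean height, weight, chest circumference, BMI,
or overweight/obesity detection rates — where ordinary time-series models
have nothing to estimate from. The grey GM(1,1) model is the standard
small-data tool for this setting: it fits a near-exponential trend through
an accumulated transform of the series and grades its own adequacy.

## The model

For a positive series x⁽⁰⁾(1..n), form the first-order accumulation (1-AGO)
x⁽¹⁾(m) = Σ_{k≤m} x⁽⁰⁾(k) and the adjacent means
z(k) = (x⁽¹⁾(k) + x⁽¹⁾(k−1))/2. The grey differential equation gives the
affine regression

```
x⁽⁰⁾(k) + a·z(k) = b,   k = 2..n
```

solved by least squares for the development coefficient *a* (a < 0 ⇒
increasing trend; a ≥ −0.3 suits short/medium-term prediction) and grey
constant *b*. Fitted and predicted values come from the restored response
function

```
x̂⁽⁰⁾(m) = (1 − eᵃ)(x⁽⁰⁾(1) − b/a)·e^(−a(m−1)),   m ≥ 2.
```

Model adequacy is graded by the posterior-variance test: mean relative
error, the ratio C = S₂/S₁ of residual to data standard deviation, and the
small-error probability P = #{|eₖ − ē| < 0.6745·S₁}/n, mapped to four
levels (Excellent/Good/Qualified/Nonconforming) by the worst criterion.

Two preprocessing conventions from the surveillance pipeline are built in:
the off-grid 2014 wave is moved to 2015 by linear extrapolation along the
2010–2014 slope, and five-wave anthropometry series are prefix-augmented
with an arbitrary value (10 by default) so every real observation enters
the regression — predictions are provably invariant to the prefix value.
Four-wave rate series are fitted without the prefix.

## Worked example

```python
from greytrend import (series_from_values, extrapolate_to_grid, prepend_prefix,
                       estimate_parameters, diagnose, fit_and_forecast)

waves = series_from_values([2000, 2005, 2010, 2014, 2020],
                           [99.1, 100.2, 101.3, 102.1, 101.9])   # cm
series = prepend_prefix(extrapolate_to_grid(waves, step_years=5), 10.0)
model = estimate_parameters(series)
diag = diagnose(model)
```

Running `python examples/fit_worked_series.py` prints:

```
modeling vector: (10.0, 99.1, 100.2, 101.3, 102.3, 101.9)
development coefficient a = -0.0076032  (negative: increasing trend)
grey constant          b = 98.97662
restored coefficient     = 98.6770
mean relative error 0.36764% | C = 0.3672 | P = 1.0 | grade 2 (Good)
fitted + predicted (cm): {2000: 99.4, 2005: 100.2, 2010: 101.0, 2015: 101.7,
                          2020: 102.5, 2025: 103.3, 2030: 104.1}
```

The negative development coefficient says 3-year-old boys' mean height is
rising; the fit tracks every wave to within 0.6 cm, and the quality grade
is "Good" (the C ratio, 0.37, is the binding criterion). The model projects
103.3 cm by 2025.

The other example scripts cover the full table reproduction
(`reproduce_published_tables.py`), detection-rate projections
(`project_obesity_rates.py` — boys' obesity rises from 5.4% observed in
2000 to a projected 14.1% in 2030), and synthetic parameter recovery
(`parameter_recovery.py`).

A thin CLI wraps the same functions:

```
greytrend fit heights.csv --out artifacts/
greytrend forecast rates.csv --no-prefix --horizon 3
greytrend reproduce-tables --out tables/
greytrend simulate --sigma 0.3 --replicates 500
```

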