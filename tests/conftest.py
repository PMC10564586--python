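import pytest

from greytrend import (Indicator, Sex, estimate_parameters, extrapolate_to_grid,
                       prepend_prefix, series_from_values)

#: The five survey-wave heights (cm) of 3-year-old boys, 2000-2020.
WAVE_YEARS = (2000, 2005, 2010, 2014, 2020)
WAVE_HEIGHTS = (99.1, 100.2, 101.3, 102.1, 101.9)

#: The same series after grid adjustment (2014 -> 2015) and prefix 10.
MODELING_VECTOR = (10.0, 99.1, 100.2, 101.3, 102.3, 101.9)


@pytest.fixture
def wave_series():
    return series_from_values(WAVE_YEARS, WAVE_HEIGHTS,
                              indicator=Indicator.HEIGHT, sex=Sex.BOYS, age_years=3)


@pytest.fixture
def modeling_series(wave_series):
    return prepend_prefix(extrapolate_to_grid(wave_series, 5), 10.0)


@pytest.fixture
def fitted_model(modeling_series):
    return estimate_parameters(modeling_series)
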