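import numpy as np
import pandas as pd
import pytest

from frostdamage import CanopyCoverSeries, TemperatureSeries


@pytest.fixture
def hourly():
    """Factory for hourly temperature series."""

    def make(values=None, n=48, temp=-5.0, start="2020-01-10 01:00"):
        if values is not None:
            values = np.asarray(values, dtype=float)
            n = values.size
        else:
            values = np.full(n, float(temp))
        idx = pd.date_range(start, periods=n, freq="h")
        return TemperatureSeries(idx, values)

    return make


@pytest.fixture
def cc_series():
    """Factory for canopy-cover series from (day offsets, cc values)."""

    def make(days, cc, unit="u1", genotype="G01", origin="2020-01-01"):
        dates = pd.Timestamp(origin) + pd.to_timedelta(list(days), "D")
        return CanopyCoverSeries(unit, genotype, dates, np.asarray(cc, dtype=float))

    return make
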