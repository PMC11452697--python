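import datetime as dt

import pandas as pd
import pytest

from envlink import (
    EnvDatasetStations,
    HealthEvent,
    Station,
    SynthSpec,
    Variable,
    gen_stations_dataset,
)

BASE = "https://ex.org"


@pytest.fixture
def base_iri():
    return BASE


@pytest.fixture
def tiny_station_ds():
    """One station, one variable, two daily observations — small enough to
    enumerate its knowledge-graph uplift by hand."""
    obs = pd.DataFrame(
        {
            "station_id": ["st01", "st01"],
            "date": [dt.date(2021, 3, 1), dt.date(2021, 3, 2)],
            "variable": ["pm10", "pm10"],
            "value": [12.5, 14.0],
        }
    )
    return EnvDatasetStations(
        dataset_id="air",
        stations=[Station("st01", 0.5, 51.0)],
        observations=obs,
        variables=[Variable("pm10", "ug/m3")],
    )


@pytest.fixture
def standard_fixture():
    """3 events x 2 variables with full coverage over 10 stations."""
    spec = SynthSpec(seed=11, n_stations=10, n_days=90, n_events=3, missing_rate=0.0)
    ds = gen_stations_dataset(spec)
    events = [
        HealthEvent("ev-a", dt.date(2021, 3, 20), point=(-0.5, 50.5)),
        HealthEvent("ev-b", dt.date(2021, 3, 25), point=(0.2, 51.2)),
        HealthEvent("ev-c", dt.date(2021, 3, 30), point=(0.8, 51.8)),
    ]
    return ds, events
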