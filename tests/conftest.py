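import numpy as np
import pandas as pd
import pytest

import denphen
from denphen._mcmc import SamplerConfig


@pytest.fixture(scope="session")
def small_scenario():
    """3 parks x 6 years, first-exit events on the default 1..150 grid."""
    return denphen.SyntheticScenario(n_parks=3, first_year=2000, last_year=2005, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    climate = denphen.simulate_climate(small_scenario)
    coefs = denphen.simulate_coefficient_functions(small_scenario)
    events, truth = denphen.simulate_event_dates(climate, coefs, small_scenario)
    return {"scenario": small_scenario, "climate": climate, "coefs": coefs,
            "events": events, "truth": truth}


@pytest.fixture
def quick_sampler():
    return SamplerConfig(n_steps=50, n_warmup=30, n_keep=40, seed=1,
                         optimize_budget=400)


def make_climate_frame(park_ids, years, temp_fn, snow_fn=None):
    """Build a park-daily climate frame from day-level functions.

    ``temp_fn(park, year, doy)`` and optionally ``snow_fn`` give the values.
    """
    rows = []
    for pid in park_ids:
        for year in years:
            doy = np.arange(1, 366)
            rows.append(pd.DataFrame({
                "park_id": pid, "year": year, "doy": doy,
                "temperature_c": [temp_fn(pid, year, d) for d in doy],
                "snow_cm": [snow_fn(pid, year, d) if snow_fn else 0.0 for d in doy],
            }))
    return pd.concat(rows, ignore_index=True)


def make_events_frame(records, kind="first_exit"):
    """records: iterable of (park_id, year, day_of_year)."""
    return pd.DataFrame([
        {"park_id": p, "year": y, "event_kind": kind, "day_of_year": d}
        for p, y, d in records
    ])
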