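import numpy as np
import pandas as pd
import pytest

from phenopass.io import DailyCpueSeries
from phenopass.simulate import SimulationConfig, SpeciesSpec, simulate_station_dataset


def make_series(cpue, species="sp", year=2002, first_day=100, total=None):
    """DailyCpueSeries from a plain cpue vector (NaN = missing day)."""
    cpue = np.asarray(cpue, dtype=float)
    if total is None:
        total = int(np.nansum(cpue))
    return DailyCpueSeries(
        species=species,
        year=year,
        days=np.arange(first_day, first_day + len(cpue)),
        cpue=cpue,
        total_captures=total,
    )


@pytest.fixture(scope="session")
def small_config():
    """Three-species station, 12 years: fast but structurally complete."""
    species = [
        SpeciesSpec(name="early_mover", group="Sahel", mu0=105.0, beta=-0.8,
                    sigma0=7.0, volume=400.0, dimorphic=True),
        SpeciesSpec(name="steady", group="Tropical", mu0=118.0, beta=0.0,
                    sigma0=8.0, volume=300.0),
        SpeciesSpec(name="late_shifter", group="Tropical", mu0=125.0, beta=-0.2,
                    sigma0=8.0, volume=250.0),
        SpeciesSpec(name="sahel_second", group="Sahel", mu0=112.0, beta=-0.5,
                    sigma0=8.0, volume=350.0, dimorphic=True),
    ]
    return SimulationConfig(years=(2002, 2013), species=species,
                            season=(75, 150), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_station_dataset(small_config)


@pytest.fixture()
def capture_frames(small_dataset):
    return small_dataset.captures, small_dataset.effort, small_dataset.species_meta
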