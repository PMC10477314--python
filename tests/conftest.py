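import copy

import numpy as np
import pytest

from borealsim.climate import ClimateRecord
from borealsim.core import Cell, Cohort, Ecoregion, FireRegimeParams, Landscape, SoilTexture
from borealsim.runner import build_climate_streams
from borealsim.synth import MU_TEMPLATES, default_traits, generate_landscape


@pytest.fixture(scope="session")
def traits():
    return default_traits()


@pytest.fixture(scope="session")
def baseline_streams_mu1():
    return build_climate_streams("MU1", "baseline", 0)


@pytest.fixture(scope="session")
def baseline_streams_mu2():
    return build_climate_streams("MU2", "baseline", 0)


@pytest.fixture(scope="session")
def _mu1_landscape_cached():
    return generate_landscape(MU_TEMPLATES["MU1"], 196, 7)


@pytest.fixture(scope="session")
def _mu2_landscape_cached():
    return generate_landscape(MU_TEMPLATES["MU2"], 196, 7)


@pytest.fixture
def mu1_landscape(_mu1_landscape_cached):
    return copy.deepcopy(_mu1_landscape_cached)


@pytest.fixture
def mu2_landscape(_mu2_landscape_cached):
    return copy.deepcopy(_mu2_landscape_cached)


def make_cell(cohorts=(), active=True, ecoregion_code=21, row=0, col=0, soil_water=100.0):
    return Cell(
        row=row, col=col, ecoregion_code=ecoregion_code, active=active,
        cohorts=[Cohort(*c) if isinstance(c, tuple) else c for c in cohorts],
        soil_water=soil_water,
    )


def make_record(tmean=16.0, precip=100.0, par=600.0, co2=389.0, year=2010, month=7):
    return ClimateRecord(year=year, month=month, tmean=tmean, precip=precip, par=par, co2=co2)


def single_ecoregion_landscape(
    n_rows=10, n_cols=10, species=None, age=100, biomass=80.0,
    ignition_rate=0.0, wind_rotation=float("inf"), tsf=100,
):
    """Uniform landscape of one ecoregion for disturbance-rate oracles."""
    traits = default_traits()
    eco = Ecoregion(
        code=21, soil_texture=SoilTexture.CLAY,
        fire_regime=FireRegimeParams(ignition_rate=ignition_rate),
        wind_rotation=wind_rotation, climate_key="one",
    )
    sp = species or "black_spruce"
    cells = [
        [
            Cell(
                r, c, ecoregion_code=21, time_since_fire=tsf, soil_water=150.0,
                cohorts=[Cohort(species=sp, age=age, biomass=biomass)],
            )
            for c in range(n_cols)
        ]
        for r in range(n_rows)
    ]
    return Landscape(cells=cells, ecoregions={21: eco}, species=traits)
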