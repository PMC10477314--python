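import copy
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from borealsim.core import Cohort
from borealsim.growth import (
    GrowthParams,
    SeedSources,
    annual_hazard,
    annual_senescence,
    background_mortality,
    canopy_light,
    establish,
    establishment_probability,
    monthly_growth,
    soil_water_step,
    temperature_modifier,
    transmitted_light_fraction,
)
from borealsim.harvest import PRESCRIPTIONS, apply_prescription

from conftest import make_cell, make_record

PARAMS = GrowthParams()


# -- temperature response ---------------------------------------------------

def _traits(traits, name="black_spruce", **overrides):
    return dataclasses.replace(traits[name], **overrides)


def test_temperature_response_boundaries_and_optimum(traits):
    tr = traits["black_spruce"]
    assert temperature_modifier(tr.psn_tmin, tr) == 0.0
    assert temperature_modifier(tr.psn_tmax, tr) == 0.0
    assert temperature_modifier(tr.psn_topt, tr) == 1.0
    assert temperature_modifier(tr.psn_tmin - 10, tr) == 0.0


def test_temperature_response_midpoint_closed_form(traits):
    # parabola 1 - ((t - topt)/(topt - tmin))^2 at t=11, tmin=2, topt=20
    tr = _traits(traits, psn_tmin=2.0, psn_topt=20.0, psn_tmax=35.0)
    assert temperature_modifier(11.0, tr) == pytest.approx(1 - (9 / 18) ** 2)
    assert temperature_modifier(11.0, tr) == pytest.approx(0.75)


def test_temperature_response_is_continuous_at_optimum(traits):
    tr = traits["jack_pine"]
    eps = 1e-7
    below = temperature_modifier(tr.psn_topt - eps, tr)
    above = temperature_modifier(tr.psn_topt + eps, tr)
    assert below == pytest.approx(1.0, abs=1e-9)
    assert above == pytest.approx(1.0, abs=1e-9)


# -- canopy light -----------------------------------------------------------

def test_canopy_zero_leaf_area_transmits_everything():
    layers, transmitted = canopy_light([0.0, 0.0], 500.0, 0.5)
    assert transmitted == 500.0
    assert all(l.absorbed == 0.0 for l in layers)


def test_canopy_single_layer_closed_form():
    layers, transmitted = canopy_light([2.0], 1000.0, 0.5)
    assert transmitted / 1000.0 == pytest.approx(math.exp(-1.0))
    assert layers[0].absorbed == pytest.approx(1000.0 * (1 - math.exp(-1.0)))


@settings(max_examples=50, derandomize=True)
@given(
    lai=st.lists(st.floats(0.0, 8.0), min_size=1, max_size=5),
    par=st.floats(0.0, 2000.0),
    k=st.floats(0.05, 2.0),
)
def test_canopy_light_conservation(lai, par, k):
    layers, transmitted = canopy_light(lai, par, k)
    assert sum(l.absorbed for l in layers) + transmitted == pytest.approx(par, abs=1e-9)


def test_canopy_rejects_negative_leaf_area():
    with pytest.raises(ValueError):
        canopy_light([-1.0], 100.0, 0.5)


# -- soil water -------------------------------------------------------------

@pytest.mark.parametrize(
    "w, precip, demand, whc, expected",
    [
        (70.0, 0.0, 0.0, 100.0, (70.0, 0.0, 0.0)),
        (50.0, 100.0, 30.0, 100.0, (100.0, 30.0, 20.0)),
        (10.0, 5.0, 50.0, 100.0, (0.0, 15.0, 0.0)),
    ],
)
def test_soil_water_step_contract(w, precip, demand, whc, expected):
    assert soil_water_step(w, precip, demand, whc) == pytest.approx(expected)


@settings(max_examples=100, derandomize=True)
@given(
    w=st.floats(0, 150), precip=st.floats(0, 300),
    demand=st.floats(0, 300), whc=st.floats(1, 150),
)
def test_soil_water_never_leaves_bucket_bounds(w, precip, demand, whc):
    w = min(w, whc)
    w_new, supplied, drainage = soil_water_step(w, precip, demand, whc)
    assert 0.0 <= w_new <= whc
    assert supplied <= demand + 1e-12
    assert w_new + supplied + drainage == pytest.approx(w + precip, abs=1e-9)


# -- monthly growth ---------------------------------------------------------

def test_no_growth_below_photosynthesis_minimum(traits):
    cell = make_cell([("black_spruce", 60, 50.0), ("balsam_fir", 30, 20.0)])
    fluxes = monthly_growth(cell, make_record(tmean=-10.0), traits, whc=150.0)
    assert fluxes.gpp == 0.0
    assert fluxes.npp == 0.0


def test_unstressed_single_cohort_matches_closed_form(traits):
    # saturating light (tiny half-saturation), optimal temperature, baseline
    # CO2 and ample water -> npp = (1 - maint_resp_frac) * amax * foliage
    tr = _traits(traits, half_sat_light=1e-9)
    table = {"black_spruce": tr}
    cell = make_cell([("black_spruce", 60, 20.0)], soil_water=150.0)
    fluxes = monthly_growth(
        cell, make_record(tmean=tr.psn_topt, precip=500.0), table, whc=500.0
    )
    foliage = PARAMS.foliage_fraction * 20.0
    expected = (1 - tr.maint_resp_frac) * tr.amax * foliage
    assert fluxes.npp == pytest.approx(expected, rel=1e-9)
    assert fluxes.npp == pytest.approx(fluxes.gpp - fluxes.respiration, rel=1e-9)


def test_growth_monotone_in_incident_par(traits):
    base = make_cell([("black_spruce", 60, 50.0), ("white_birch", 30, 20.0)])
    results = []
    for par in (100.0, 200.0, 400.0, 800.0):
        cell = copy.deepcopy(base)
        fluxes = monthly_growth(cell, make_record(par=par), traits, whc=150.0)
        results.append(fluxes.gpp)
    assert all(b >= a for a, b in zip(results, results[1:]))


def test_stressed_months_deplete_reserve_and_positive_month_refills(traits):
    # a deeply shaded intolerant cohort runs a negative balance
    cell = make_cell([("black_spruce", 120, 200.0), ("trembling_aspen", 10, 1.0)])
    rec = make_record()
    monthly_growth(cell, rec, traits, whc=150.0)
    aspen = [c for c in cell.cohorts if c.species == "trembling_aspen"][0]
    assert aspen.stress_months == 1
    assert aspen.carbon_reserve < 1.0
    # alone in the open the same cohort refills immediately
    open_cell = make_cell([("trembling_aspen", 10, 1.0)])
    open_cell.cohorts[0].stress_months = 5
    monthly_growth(open_cell, rec, traits, whc=150.0)
    assert open_cell.cohorts[0].stress_months == 0
    assert open_cell.cohorts[0].carbon_reserve == 1.0


# -- establishment ----------------------------------------------------------

def test_no_seed_source_means_no_establishment(traits):
    rng = np.random.default_rng(0)
    for _ in range(500):
        cell = make_cell([], soil_water=150.0)
        new = establish(cell, SeedSources(), traits, rng, whc=150.0)
        assert new == []


def test_postfire_serotiny_establishes_without_seed_rain(traits):
    rng = np.random.default_rng(1)
    hits = 0
    n = 2000
    for _ in range(n):
        cell = make_cell([], soil_water=150.0)
        cell.time_since_fire = 0
        sources = SeedSources(
            burned=True, prefire_species=frozenset({"jack_pine", "balsam_fir"})
        )
        new = establish(cell, sources, traits, rng, whc=150.0)
        species = {c.species for c in new}
        assert "balsam_fir" not in species  # no post-fire pathway, no source
        hits += "jack_pine" in species
    p = PARAMS.postfire_serotiny_prob
    se = math.sqrt(p * (1 - p) / n)
    assert hits / n == pytest.approx(p, abs=3 * se)


def test_shade_suppressed_establishment_matches_probability_formula(traits):
    # closed black-spruce canopy transmits < 10% light; intolerant aspen
    canopy = [("black_spruce", 120, 200.0)]
    probe = make_cell(canopy, soil_water=150.0)
    floor_light = transmitted_light_fraction(probe, PARAMS)
    assert floor_light < 0.10
    sources = SeedSources(dispersal_factor={"trembling_aspen": 1.0})
    p_expected = establishment_probability(
        "trembling_aspen", traits["trembling_aspen"], sources, floor_light, 1.0, PARAMS
    )
    rng = np.random.default_rng(2)
    n = 10_000
    hits = 0
    for _ in range(n):
        cell = make_cell(canopy, soil_water=150.0)
        new = establish(cell, sources, traits, rng, whc=150.0)
        hits += any(c.species == "trembling_aspen" for c in new)
    se = math.sqrt(p_expected * (1 - p_expected) / n)
    assert hits / n == pytest.approx(p_expected, abs=3 * se)
    assert p_expected < 0.05  # well below the open-ground base probability


def test_new_cohorts_enter_first_age_bin(traits):
    rng = np.random.default_rng(3)
    cell = make_cell([], soil_water=150.0)
    sources = SeedSources(dispersal_factor={"black_spruce": 1.0})
    for _ in range(200):
        new = establish(cell, sources, traits, rng, whc=150.0)
        if new:
            assert all(c.age_bin == 1 for c in new)
            break
    else:
        pytest.fail("establishment never occurred in 200 attempts")


# -- background mortality ---------------------------------------------------

def test_cohort_at_longevity_always_dies(traits):
    rng = np.random.default_rng(0)
    cell = make_cell([("balsam_fir", 120, 50.0)])
    killed = background_mortality(cell, traits, rng, PARAMS)
    assert [c.species for c in killed] == ["balsam_fir"]
    assert cell.cohorts == []


def test_young_healthy_cohort_never_dies(traits):
    rng = np.random.default_rng(0)
    for _ in range(500):
        cell = make_cell([("black_spruce", 80, 50.0)])
        assert background_mortality(cell, traits, rng, PARAMS) == []


def test_depleted_reserve_kills_cohort(traits):
    rng = np.random.default_rng(0)
    cell = make_cell([("black_spruce", 40, 30.0)])
    cell.cohorts[0].stress_months = PARAMS.stress_months_lethal
    cell.cohorts[0].carbon_reserve = 0.0
    killed = background_mortality(cell, traits, rng, PARAMS)
    assert len(killed) == 1


def test_simulated_lifespans_match_analytic_hazard_mean():
    longevity = 200
    onset = int(PARAMS.senescence_onset * longevity)
    ages = np.arange(onset, longevity)
    hazards = np.array([annual_hazard(int(a), longevity, PARAMS) for a in ages])
    # analytic discrete mean age at death
    surv = np.cumprod(1 - hazards)
    p_die = np.empty(len(ages) + 1)
    p_die[0] = hazards[0]
    p_die[1:-1] = surv[:-1] * hazards[1:]
    p_die[-1] = surv[-1]  # forced death at the longevity limit
    ages_ext = np.append(ages, longevity)
    analytic_mean = float((p_die * ages_ext).sum())
    # Monte-Carlo lifespans from independent uniform draws
    rng = np.random.default_rng(42)
    n = 10_000
    u = rng.random((n, len(ages)))
    dies = u < hazards[None, :]
    first = np.where(dies.any(axis=1), dies.argmax(axis=1), len(ages))
    mc_mean = float(ages_ext[first].mean())
    assert mc_mean == pytest.approx(analytic_mean, rel=0.05)


# -- tracked-flux mass balance ---------------------------------------------

def test_cell_mass_balance_identity_over_a_year(traits):
    cell = make_cell(
        [("black_spruce", 90, 120.0), ("white_birch", 40, 30.0)], soil_water=120.0
    )
    b0 = sum(c.biomass for c in cell.cohorts)
    growth = 0.0
    for month in range(1, 13):
        tmean = [-18, -16, -9, -1, 6, 12, 16, 14.5, 9, 2, -6, -14][month - 1]
        fluxes = monthly_growth(
            cell, make_record(tmean=tmean, month=month, precip=80.0), traits, whc=150.0
        )
        growth += fluxes.npp_applied
    senescence = annual_senescence(cell, PARAMS)
    rng = np.random.default_rng(0)
    mortality = sum(c.biomass for c in background_mortality(cell, traits, rng, PARAMS))
    removed, _ = apply_prescription(cell, PRESCRIPTIONS["PC50"])
    b1 = sum(c.biomass for c in cell.cohorts)
    assert b1 == pytest.approx(b0 + growth - senescence - mortality - removed, abs=1e-8)
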