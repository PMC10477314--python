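import copy
import math

import numpy as np
import pytest

from borealsim.core import Cohort, FireRegimeParams, SbwRegimeParams
from borealsim.disturbance import (
    apply_fire,
    apply_sbw,
    draw_fire_size,
    fire_kills_cohort,
    fire_step,
    sbw_annual_kill_fraction,
    sbw_cycle,
    schedule_fires,
    spread_fire,
    wind_kill_fraction,
    wind_step,
)
from borealsim.climate import SCENARIOS
from borealsim.runner import build_climate_streams
from borealsim.simulate import Simulation
from borealsim.synth import MU_TEMPLATES, generate_landscape

from conftest import make_cell, single_ecoregion_landscape


# -- fire scheduling --------------------------------------------------------

def test_zero_ignition_rate_never_fires():
    ls = single_ecoregion_landscape(ignition_rate=0.0)
    rng = np.random.default_rng(0)
    for year in range(2010, 2110):
        assert schedule_fires(ls, 21, year, "baseline", rng) == []


def test_ignition_counts_recover_poisson_rate():
    rate = 2.0
    ls = single_ecoregion_landscape(ignition_rate=rate)
    rng = np.random.default_rng(1)
    n_years = 4000
    counts = [
        len(schedule_fires(ls, 21, 2010, "baseline", rng)) for _ in range(n_years)
    ]
    se = math.sqrt(rate / n_years)
    assert np.mean(counts) == pytest.approx(rate, abs=3 * se)


def test_fire_sizes_respect_truncation_bounds():
    regime = FireRegimeParams(ignition_rate=1.0, size_min=1, size_mean=8.0, size_max=60)
    rng = np.random.default_rng(2)
    sizes = [draw_fire_size(regime, rng) for _ in range(5000)]
    assert min(sizes) >= regime.size_min
    assert max(sizes) <= regime.size_max
    assert 4.0 < np.mean(sizes) < 9.0  # truncation pulls the mean below 8


# -- fire spread ------------------------------------------------------------

def test_spread_target_one_burns_only_ignition():
    ls = single_ecoregion_landscape()
    ignition = ls.cell(5, 5)
    rng = np.random.default_rng(3)
    burned = spread_fire(ls, ignition, 1, k_fuel_age=1.0, rng=rng)
    assert burned == [ignition]
    assert ignition.time_since_fire == 0
    assert "black_spruce" in ignition.prefire_species


def test_spread_reaches_target_and_stays_connected():
    ls = single_ecoregion_landscape()
    rng = np.random.default_rng(4)
    burned = spread_fire(ls, ls.cell(5, 5), 12, k_fuel_age=0.0, rng=rng)
    assert len(burned) == 12
    coords = {(c.row, c.col) for c in burned}
    for c in burned[1:]:  # every burned cell touches another burned cell
        assert any(
            (c.row + dr, c.col + dc) in coords
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
        )


def test_realized_burn_rate_matches_rate_oracle():
    # expected annual burned fraction = ignition_rate * E[size] / n_cells,
    # with E[size] estimated from the size distribution itself
    n_rows = n_cols = 40
    n = n_rows * n_cols
    target_fraction = 0.0015
    regime_rate = target_fraction * n / 8.0
    ls = single_ecoregion_landscape(n_rows, n_cols, ignition_rate=regime_rate)
    size_rng = np.random.default_rng(5)
    regime = ls.ecoregions[21].fire_regime
    mean_size = np.mean([draw_fire_size(regime, size_rng) for _ in range(20000)])
    expected = regime_rate * mean_size / n

    rng = np.random.default_rng(6)
    years = 2000
    burned_cells = 0
    for year in range(years):
        for cell, size, severity in schedule_fires(ls, 21, 2010, "baseline", rng):
            burned_cells += len(spread_fire(ls, cell, size, regime.k_fuel_age, rng))
        for row in ls.cells:
            for c in row:
                c.time_since_fire += 1
    realized = burned_cells / (n * years)
    assert realized == pytest.approx(expected, rel=0.25)


# -- fire mortality ---------------------------------------------------------

def test_low_severity_never_kills_tolerant_species(traits):
    tr = traits["jack_pine"]  # fire tolerance 4
    for age in (5, 50, 100, 140):
        assert not fire_kills_cohort(2, tr, age) or age <= 0.2 * tr.longevity
        assert not fire_kills_cohort(1, tr, age)


def test_severity_five_kills_everything(traits):
    for tr in traits.values():
        for age in (5, 50, tr.longevity - 1):
            assert fire_kills_cohort(5, tr, age)


def test_fire_kill_matrix_exhaustive(traits):
    # independent rule oracle: kill iff severity - tolerance >= offset, with
    # offset -1 for cohorts in the first 20% of the lifespan, 0 otherwise;
    # severity 5 unconditional
    tr0 = traits["black_spruce"]
    import dataclasses

    for severity in range(1, 6):
        for tol in range(1, 6):
            tr = dataclasses.replace(tr0, fire_tolerance=tol)
            for age in range(10, tr.longevity, 20):
                young = age <= 0.2 * tr.longevity
                expected = severity == 5 or severity - tol >= (-1 if young else 0)
                assert fire_kills_cohort(severity, tr, age) == expected


def test_apply_fire_event_biomass_equals_pool_difference():
    ls = single_ecoregion_landscape(age=150, biomass=60.0)
    cells = [ls.cell(0, 0), ls.cell(0, 1)]
    before = sum(c.biomass for cell in cells for c in cell.cohorts)
    event = apply_fire(ls, cells, severity=5, species_table=ls.species)
    after = sum(c.biomass for cell in cells for c in cell.cohorts)
    assert event.biomass_killed == pytest.approx(before - after)
    assert event.biomass_killed == pytest.approx(before)


# -- wind -------------------------------------------------------------------

def test_infinite_rotation_means_no_wind():
    ls = single_ecoregion_landscape(wind_rotation=float("inf"))
    rng = np.random.default_rng(7)
    for year in range(500):
        assert wind_step(ls, year, rng) == []


def test_wind_rate_recovers_inverse_rotation():
    rotation = 200.0
    ls = single_ecoregion_landscape(40, 40, wind_rotation=rotation)
    rng = np.random.default_rng(8)
    years = 2000
    affected = 0
    for year in range(years):
        for ev in wind_step(ls, year, rng):
            affected += len(ev.cells)
    realized = affected / (1600 * years)
    assert realized == pytest.approx(1.0 / rotation, rel=0.06)


def test_wind_damage_increases_with_age_class():
    assert (
        wind_kill_fraction(10, 200)
        <= wind_kill_fraction(100, 200)
        <= wind_kill_fraction(190, 200)
    )
    assert wind_kill_fraction(190, 200) > wind_kill_fraction(10, 200)


# -- spruce budworm ---------------------------------------------------------

def test_broadleaf_cell_untouched_by_outbreak():
    params = SbwRegimeParams()
    cell = make_cell([("white_birch", 60, 40.0), ("trembling_aspen", 40, 20.0)])
    event = apply_sbw(cell, params)
    assert event.biomass_killed == 0.0
    assert sum(c.biomass for c in cell.cohorts) == 60.0


def test_sbw_interval_mean_recovers_return_interval():
    params = SbwRegimeParams(return_interval_mean=32.0, return_interval_sd=6.0)
    rng = np.random.default_rng(9)
    onsets = sbw_cycle(params, horizon=32 * 200, rng=rng)
    intervals = np.diff(onsets)
    assert len(intervals) > 150
    se = params.return_interval_sd / math.sqrt(len(intervals))
    assert intervals.mean() == pytest.approx(32.0, abs=3 * se + 0.5)


def test_sbw_host_vulnerability_order_preserved():
    params = SbwRegimeParams()
    f = {sp: sbw_annual_kill_fraction(params, sp) for sp in
         ("balsam_fir", "white_spruce", "black_spruce", "jack_pine")}
    assert f["balsam_fir"] > f["white_spruce"] > f["black_spruce"] > 0
    assert f["jack_pine"] == 0.0
    cell = make_cell(
        [("balsam_fir", 80, 50.0), ("white_spruce", 80, 50.0), ("black_spruce", 80, 50.0)]
    )
    apply_sbw(cell, params)
    loss = {c.species: 50.0 - c.biomass for c in cell.cohorts}
    assert loss["balsam_fir"] > loss["white_spruce"] > loss["black_spruce"] > 0


# -- climate indirection ----------------------------------------------------

def test_only_fire_carries_climate_scaling():
    ls = generate_landscape(MU_TEMPLATES["MU1"], 196, 7)
    ls2 = generate_landscape(MU_TEMPLATES["MU1"], 196, 7)
    for code in ls.ecoregions:
        a, b = ls.ecoregions[code], ls2.ecoregions[code]
        # wind and SBW configs are identical and carry no scenario dimension
        assert a.wind_rotation == b.wind_rotation
        assert a.sbw_params == b.sbw_params
        fr = a.fire_regime
        assert set(fr.climate_scaling) == set(SCENARIOS)
        assert fr.scaling("rcp85", 90) > fr.scaling("baseline", 90) == 1.0


# -- cumulative disturbance ladder ------------------------------------------

def _end_conifer_carbon(landscape, streams, years, seed, wind, fire, sbw):
    sim = Simulation(
        landscape=copy.deepcopy(landscape), climate_streams=streams,
        years=years, seed=seed, enable_wind=wind, enable_fire=fire, enable_sbw=sbw,
    )
    out = sim.run()
    s = out.series
    last = s["step"].max()
    return float(s[(s.group == "conifer") & (s.step == last)].tC_per_ha.iloc[0])


def test_cumulative_disturbance_ladder_ordering(
    _mu1_landscape_cached, baseline_streams_mu1
):
    """Mean end-of-run coniferous biomass over paired replicates declines as
    disturbances accumulate: succession-only >= +wind >= +fire >= +SBW."""
    configs = [(False, False, False), (True, False, False),
               (True, True, False), (True, True, True)]
    means = []
    for wind, fire, sbw in configs:
        vals = [
            _end_conifer_carbon(
                _mu1_landscape_cached, baseline_streams_mu1, 80, seed, wind, fire, sbw
            )
            for seed in range(10)
        ]
        means.append(np.mean(vals))
    assert means[0] >= means[1] >= means[2] >= means[3]
    assert means[0] > means[3]  # the full ladder loses biomass overall
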