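"""Annual simulation loop for one landscape under one scenario.

Clock: monthly growth, then an annual demographic and disturbance sequence
in fixed order — senescence, background mortality, wind, fire, spruce
budworm, harvest, establishment, aging — with landscape state reported
every 20 simulated years.  All stochastic components draw from independent
child streams of one seed, so enabling or disabling one disturbance does
not perturb the draws of the others and matched-seed scenario contrasts
stay paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .analysis import landscape_age_shares, landscape_type_shares, CarbonSeries
from .climate import ClimateRecord, ClimateStream
from .core import (
    DEFAULT_CARBON_FRACTION,
    Landscape,
    merge_age_bins,
)
from .disturbance import fire_step, sbw_cycle, sbw_step, wind_step
from .growth import (
    DEFAULT_GROWTH_PARAMS,
    GrowthParams,
    SeedSources,
    annual_senescence,
    background_mortality,
    establish,
    monthly_growth,
    temperature_modifier,
    DISPERSAL_TAIL_FACTOR,
)
from .harvest import ScenarioConfig, annual_harvest

REPORT_STEP_YEARS = 20


class _LazyRng:
    """Uniform-draw source from a Philox stream keyed by (cell, year).

    The underlying generator is only built on first use, so cells with no
    stochastic event this year cost nothing.
    """

    __slots__ = ("_key", "_counter", "_gen")

    def __init__(self, key: np.ndarray, year: int, row: int, col: int) -> None:
        self._key = key
        self._counter = (0, year, row, col)
        self._gen = None

    def random(self) -> float:
        if self._gen is None:
            self._gen = np.random.Generator(
                np.random.Philox(counter=self._counter, key=self._key)
            )
        return float(self._gen.random())


@dataclass
class RunOutput:
    """Tidy tables from one simulation run."""

    climate: str
    management: str
    seed: int
    start_year: int
    years: int
    series: pd.DataFrame       # year, step, group, tC_per_ha
    age_shares: pd.DataFrame   # year, age_class, share
    type_shares: pd.DataFrame  # year, forest_type, share
    harvest: pd.DataFrame      # annual records per treatment
    events: pd.DataFrame       # kind, year, n_cells, severity, biomass_killed
    fluxes: pd.DataFrame       # annual landscape totals (mass-balance columns)

    def carbon_series(self, group: str = "total") -> CarbonSeries:
        sel = self.series[self.series["group"] == group]
        return CarbonSeries(
            climate=self.climate,
            management=self.management,
            years=sel["year"].to_numpy(),
            values=sel["tC_per_ha"].to_numpy(),
        )


@dataclass
class Simulation:
    """One (landscape, climate scenario, management scenario) run."""

    landscape: Landscape
    climate_streams: dict[str, ClimateStream]  # keyed by ecoregion climate_key
    scenario: ScenarioConfig | None = None
    area_quota_ha: float = 0.0
    years: int = 300
    start_year: int = 2010
    enable_wind: bool = True
    enable_fire: bool = True
    enable_sbw: bool = True
    seed: int = 0
    params: GrowthParams = field(default_factory=lambda: DEFAULT_GROWTH_PARAMS)
    carbon_fraction: float = DEFAULT_CARBON_FRACTION

    def __post_init__(self) -> None:
        streams = set(self.climate_streams)
        needed = {e.climate_key for e in self.landscape.ecoregions.values()}
        missing = needed - streams
        if missing:
            raise ValueError(f"missing climate streams for: {sorted(missing)}")
        scenarios = {s.scenario for s in self.climate_streams.values()}
        if len(scenarios) != 1:
            raise ValueError("all climate streams must share one scenario")
        self.climate_scenario = scenarios.pop()
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(6)
        (self._rng_wind, self._rng_fire,
         self._rng_sbw, self._rng_harvest) = (
            np.random.default_rng(c) for c in children[:4]
        )
        # Establishment and mortality draw from counter-based streams keyed
        # by (cell, year): local state changes never shift the draws of
        # other cells, keeping matched-seed scenario contrasts paired.
        self._est_key = children[4].generate_state(2, np.uint64)
        self._mort_key = children[5].generate_state(2, np.uint64)
        self._index_climate()
        self._prepare_dispersal()
        self._schedule_sbw()

    # -- precomputation -------------------------------------------------

    def _index_climate(self) -> None:
        self._climate_by_year: dict[str, dict[int, list[ClimateRecord]]] = {}
        for key, stream in self.climate_streams.items():
            d = stream.data
            by_year: dict[int, list[ClimateRecord]] = {}
            years = d["year"].to_numpy()
            arrs = {c: d[c].to_numpy() for c in ("month", "tmean", "precip", "par", "co2")}
            for i in range(len(d)):
                by_year.setdefault(int(years[i]), []).append(
                    ClimateRecord(
                        year=int(years[i]), month=int(arrs["month"][i]),
                        tmean=float(arrs["tmean"][i]), precip=float(arrs["precip"][i]),
                        par=float(arrs["par"][i]), co2=float(arrs["co2"][i]),
                    )
                )
            self._climate_by_year[key] = by_year

    def _prepare_dispersal(self) -> None:
        # dispersal radii in cells (200 m grid); the home cell is always a
        # full-strength source
        self._radii = {}
        for sp, tr in self.landscape.species.items():
            r_eff = int(round(tr.effective_dispersal / 200.0))
            r_max = max(1, int(round(tr.max_dispersal / 200.0)))
            self._radii[sp] = (r_eff, max(r_eff, r_max))

    def _schedule_sbw(self) -> None:
        self._sbw_years: dict[int, set[int]] = {}
        if not self.enable_sbw:
            return
        for code in sorted(self.landscape.ecoregions):
            params = self.landscape.ecoregions[code].sbw_params
            onsets = sbw_cycle(params, self.years, self._rng_sbw)
            active: set[int] = set()
            for onset in onsets:
                for k in range(params.outbreak_duration):
                    active.add(self.start_year + onset + k)
            self._sbw_years[code] = active

    # -- annual steps ---------------------------------------------------

    def _cell_rng(self, key: np.ndarray, year: int, row: int, col: int) -> "_LazyRng":
        return _LazyRng(key, year, row, col)

    def _seed_source_factors(self) -> dict[str, np.ndarray]:
        """Per-species grid of dispersal kernel factors (0 / tail / 1)."""
        shape = (self.landscape.n_rows, self.landscape.n_cols)
        mature = {sp: np.zeros(shape, dtype=bool) for sp in self.landscape.species}
        for cell in self.landscape.active_cells():
            for c in cell.cohorts:
                if c.age >= self.landscape.species[c.species].sexual_maturity:
                    mature[c.species][cell.row, cell.col] = True
        factors: dict[str, np.ndarray] = {}
        for sp, grid in mature.items():
            if not grid.any():
                factors[sp] = np.zeros(shape)
                continue
            r_eff, r_max = self._radii[sp]
            near = (
                ndimage.binary_dilation(grid, np.ones((2 * r_eff + 1,) * 2, bool))
                if r_eff > 0 else grid
            )
            far = ndimage.binary_dilation(grid, np.ones((2 * r_max + 1,) * 2, bool))
            factors[sp] = np.where(near, 1.0, np.where(far, DISPERSAL_TAIL_FACTOR, 0.0))
        return factors

    def _establishment(self, year: int) -> float:
        factors = self._seed_source_factors()
        species_table = self.landscape.species
        recruited = 0.0
        for cell in self.landscape.active_cells():
            disp = {
                sp: float(factors[sp][cell.row, cell.col])
                for sp in factors
                if factors[sp][cell.row, cell.col] > 0
            }
            burned = cell.time_since_fire == 0
            sources = SeedSources(
                dispersal_factor=disp,
                burned=burned,
                prefire_species=cell.prefire_species,
            )
            whc = self.landscape.ecoregions[cell.ecoregion_code].whc
            rng = self._cell_rng(self._est_key, year, cell.row, cell.col)
            new = establish(cell, sources, species_table, rng, whc, self.params)
            recruited += sum(c.biomass for c in new)
            if burned:
                cell.prefire_species = frozenset()
        return recruited

    # -- main loop ------------------------------------------------------

    def run(self) -> RunOutput:
        ls = self.landscape
        params = self.params
        species_table = ls.species
        eco = ls.ecoregions
        whc_by_code = {code: e.whc for code, e in eco.items()}
        key_by_code = {code: e.climate_key for code, e in eco.items()}
        active = ls.active_cells()
        area = ls.active_area_ha()
        cells_by_code: dict[int, list] = {}
        for cell in active:
            cells_by_code.setdefault(cell.ecoregion_code, []).append(cell)

        series_rows: list[dict] = []
        age_rows: list[dict] = []
        type_rows: list[dict] = []
        harvest_rows: list[dict] = []
        event_rows: list[dict] = []
        flux_rows: list[dict] = []
        alloc_state: dict[str, float] | None = None

        def report(year: int, step: int) -> None:
            groups = {"total": 0.0, "conifer": 0.0, "broadleaf": 0.0}
            for cell in active:
                for c in cell.cohorts:
                    groups["total"] += c.biomass
                    key = "conifer" if species_table[c.species].conifer else "broadleaf"
                    groups[key] += c.biomass
            for g, mg in groups.items():
                series_rows.append(
                    {"year": year, "step": step, "group": g,
                     "tC_per_ha": mg * self.carbon_fraction / area}
                )
            for k, v in landscape_age_shares(active).items():
                age_rows.append({"year": year, "age_class": k, "share": v})
            for k, v in landscape_type_shares(active).items():
                type_rows.append({"year": year, "forest_type": k, "share": v})

        report(self.start_year, 0)
        for k in range(self.years):
            year = self.start_year + k
            biomass_start = ls.total_biomass()
            gpp = npp = npp_applied = transp = 0.0
            # monthly growth
            records_by_code = {
                code: self._climate_by_year[key][year]
                for code, key in key_by_code.items()
            }
            for m in range(12):
                for code, cells in cells_by_code.items():
                    rec = records_by_code[code][m]
                    ftemp = {
                        sp: temperature_modifier(rec.tmean, tr)
                        for sp, tr in species_table.items()
                    }
                    whc = whc_by_code[code]
                    if all(v == 0.0 for v in ftemp.values()):
                        # dormant month: no photosynthesis or transpiration,
                        # only bucket recharge (identical to monthly_growth
                        # with zero demand)
                        precip = rec.precip
                        for cell in cells:
                            w = cell.soil_water + precip
                            cell.soil_water = w if w < whc else whc
                        continue
                    for cell in cells:
                        fluxes = monthly_growth(
                            cell, rec, species_table, whc, params, ftemp=ftemp
                        )
                        gpp += fluxes.gpp
                        npp += fluxes.npp
                        npp_applied += fluxes.npp_applied
                        transp += fluxes.transpiration
            # annual demography
            senescence = sum(annual_senescence(cell, params) for cell in active)
            mortality = 0.0
            for cell in active:
                rng = self._cell_rng(self._mort_key, year, cell.row, cell.col)
                mortality += sum(
                    c.biomass
                    for c in background_mortality(cell, species_table, rng, params)
                )
            # disturbances: wind -> fire -> SBW
            events = []
            if self.enable_wind:
                events += wind_step(ls, year, self._rng_wind)
            if self.enable_fire:
                events += fire_step(ls, year, self.climate_scenario, self._rng_fire, self.start_year)
            if self.enable_sbw:
                events += sbw_step(ls, year, self._sbw_years)
            disturbance_killed = sum(e.biomass_killed for e in events)
            for e in events:
                event_rows.append(
                    {"kind": e.kind, "year": e.year, "n_cells": len(e.cells),
                     "severity": e.severity, "biomass_killed": e.biomass_killed}
                )
            # harvest
            harvest_removed = planted = 0.0
            if self.scenario is not None and self.area_quota_ha > 0:
                records, alloc_state = annual_harvest(
                    ls, self.scenario, year, self.area_quota_ha,
                    self._rng_harvest, alloc_state,
                    seedling_biomass=params.seedling_biomass,
                )
                for rec in records:
                    harvest_removed += rec.total_removed
                    if rec.treatment == "cc_reforest":
                        planted += rec.cells * params.seedling_biomass
                    harvest_rows.append(
                        {"year": rec.year, "treatment": rec.treatment,
                         "cells": rec.cells, "area_ha": rec.area_ha,
                         "total_removed": rec.total_removed,
                         "merchantable": rec.merchantable,
                         "shortfall_cells": rec.shortfall_cells}
                    )
            # establishment, then aging
            recruited = self._establishment(year) + planted
            for cell in active:
                for c in cell.cohorts:
                    c.age += 1
                merge_age_bins(cell)
                cell.time_since_fire += 1
            biomass_end = ls.total_biomass()
            flux_rows.append(
                {"year": year, "biomass_start": biomass_start, "gpp": gpp,
                 "npp": npp, "npp_applied": npp_applied,
                 "transpiration": transp, "senescence": senescence,
                 "mortality": mortality, "disturbance_killed": disturbance_killed,
                 "harvest_removed": harvest_removed, "recruitment": recruited,
                 "biomass_end": biomass_end}
            )
            if (k + 1) % REPORT_STEP_YEARS == 0:
                report(year + 1, (k + 1) // REPORT_STEP_YEARS)

        return RunOutput(
            climate=self.climate_scenario,
            management=self.scenario.code if self.scenario else "S0",
            seed=self.seed,
            start_year=self.start_year,
            years=self.years,
            series=pd.DataFrame(series_rows),
            age_shares=pd.DataFrame(age_rows),
            type_shares=pd.DataFrame(type_rows),
            harvest=pd.DataFrame(
                harvest_rows,
                columns=["year", "treatment", "cells", "area_ha",
                         "total_removed", "merchantable", "shortfall_cells"],
            ),
            events=pd.DataFrame(
                event_rows,
                columns=["kind", "year", "n_cells", "severity", "biomass_killed"],
            ),
            fluxes=pd.DataFrame(flux_rows),
        )
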