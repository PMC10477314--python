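"""Stochastic wildfire, windthrow, and spruce-budworm outbreak regimes.

Fire: ignition counts are Poisson with a climate-scenario scaling on the
rate; fire sizes follow a truncated lognormal summarised by (min, mean,
max); spread grows a connected patch from the ignition, preferring cells
with older fuel (longer time since fire); severity (ordinal 1-5) against
species fire tolerance and cohort age decides which cohorts die.

Wind: small contiguous blowdown patches whose expected annual area fraction
equals the inverse of the ecoregion rotation period; damage increases with
cohort age class.

Spruce budworm (SBW): quasi-periodic outbreaks (normal inter-onset
intervals) that defoliate and kill host conifers in fixed vulnerability
order balsam fir > white spruce > black spruce; non-hosts are untouched.

Wind and SBW regimes are climate-invariant; only fire carries a climate
scaling, with climate change otherwise acting through composition and
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Cell,
    Cohort,
    FireRegimeParams,
    Landscape,
    SbwRegimeParams,
    SpeciesTraits,
)

#: Time since fire (years) at which fuel-age weighting saturates.
FUEL_AGE_NORM_YEARS = 200.0

#: Mean windthrow patch size, cells (one cell = 4 ha).
WIND_PATCH_MEAN_CELLS = 3.0

#: Windthrow kill fraction by relative age class (young, mid, old thirds of
#: the species lifespan); monotone increasing with tree size.
WIND_KILL_BY_AGECLASS = (0.15, 0.35, 0.60)

#: Residual cohort biomass (Mg) below which a damaged cohort is removed.
MIN_COHORT_BIOMASS = 0.01


@dataclass
class DisturbanceEvent:
    kind: str  # fire | wind | sbw
    year: int
    cells: list[tuple[int, int]]
    severity: int
    biomass_killed: float = 0.0

    def __post_init__(self) -> None:
        if self.biomass_killed < 0:
            raise ValueError("killed biomass must be >= 0")


def fire_size_lognormal_params(regime: FireRegimeParams) -> tuple[float, float]:
    """(mu, sigma) of the lognormal whose mean matches ``size_mean`` and
    whose 99th percentile sits at ``size_max``."""
    if regime.size_max <= regime.size_min or regime.size_mean <= 0:
        return math.log(max(regime.size_mean, 1.0)), 0.0
    z99 = 2.3263478740408408
    ratio = math.log(regime.size_max / regime.size_mean)
    disc = z99 * z99 - 2.0 * ratio
    if disc < 0:
        raise ValueError(
            "size_max too far above size_mean for a lognormal 99th-percentile fit"
        )
    sigma = z99 - math.sqrt(disc)
    mu = math.log(regime.size_mean) - 0.5 * sigma * sigma
    return mu, sigma


def draw_fire_size(regime: FireRegimeParams, rng: np.random.Generator) -> int:
    """Draw a target fire size (cells), truncated to [size_min, size_max]."""
    mu, sigma = fire_size_lognormal_params(regime)
    for _ in range(100):
        size = rng.lognormal(mu, sigma)
        if regime.size_min <= size <= regime.size_max:
            return max(1, int(round(size)))
    return int(round(min(max(size, regime.size_min), regime.size_max)))


def schedule_fires(
    landscape: Landscape,
    ecoregion_code: int,
    year: int,
    scenario: str,
    rng: np.random.Generator,
    start_year: int = 2010,
    cells: list[Cell] | None = None,
) -> list[tuple[Cell, int, int]]:
    """Draw this year's ignitions for one ecoregion.

    Returns (ignition cell, target size in cells, severity 1-5) triples; the
    ignition count is Poisson with rate ``ignition_rate`` times the
    scenario/period climate scaling.  ``cells`` may supply the ecoregion's
    active cells precomputed by the caller.
    """
    eco = landscape.ecoregions[ecoregion_code]
    regime = eco.fire_regime
    if cells is None:
        cells = [
            c for c in landscape.active_cells() if c.ecoregion_code == ecoregion_code
        ]
    if not cells or regime.ignition_rate <= 0:
        return []
    rate = regime.ignition_rate * regime.scaling(scenario, year - start_year)
    n = rng.poisson(rate)
    out = []
    for _ in range(n):
        cell = cells[rng.integers(len(cells))]
        size = draw_fire_size(regime, rng)
        severity = 1 + int(rng.choice(5, p=regime.severity_probs))
        out.append((cell, size, severity))
    return out


def spread_fire(
    landscape: Landscape,
    ignition: Cell,
    target_size: int,
    k_fuel_age: float,
    rng: np.random.Generator,
) -> list[Cell]:
    """Grow a connected burned patch from the ignition cell.

    Frontier cells join with probability proportional to
    ``exp(k_fuel_age * tsf_norm)`` where ``tsf_norm`` is time since fire
    normalized by :data:`FUEL_AGE_NORM_YEARS` and capped at 1, so older fuel
    spreads fire when ``k_fuel_age`` > 0.  Burned cells have their fire clock
    reset and remember their pre-fire species for post-fire regeneration.
    """
    if not ignition.active:
        raise ValueError("ignition cell is inactive")
    burned: list[Cell] = [ignition]
    burned_set = {(ignition.row, ignition.col)}
    frontier: dict[tuple[int, int], Cell] = {}

    def push_neighbours(cell: Cell) -> None:
        for nb in landscape.neighbours(cell.row, cell.col):
            key = (nb.row, nb.col)
            if nb.active and key not in burned_set and key not in frontier:
                frontier[key] = nb

    push_neighbours(ignition)
    while len(burned) < target_size and frontier:
        keys = list(frontier)
        weights = np.array(
            [
                math.exp(
                    k_fuel_age
                    * min(1.0, frontier[k].time_since_fire / FUEL_AGE_NORM_YEARS)
                )
                for k in keys
            ]
        )
        pick = keys[rng.choice(len(keys), p=weights / weights.sum())]
        cell = frontier.pop(pick)
        burned.append(cell)
        burned_set.add(pick)
        push_neighbours(cell)

    for cell in burned:
        cell.prefire_species = frozenset(cell.species_present())
        cell.time_since_fire = 0
    return burned


def fire_kills_cohort(
    severity: int, traits: SpeciesTraits, age: int
) -> bool:
    """Documented fire kill matrix.

    A cohort dies when ``severity - fire_tolerance`` is at least its
    age-class vulnerability offset: -1 for young cohorts (first 20% of the
    lifespan), 0 otherwise.  Severity 5 kills every cohort; severity 1 never
    kills a tolerance-5 species.
    """
    if not 1 <= severity <= 5:
        raise ValueError("fire severity must be ordinal 1-5")
    if severity == 5:
        return True
    offset = -1 if age <= 0.2 * traits.longevity else 0
    return severity - traits.fire_tolerance >= offset


def apply_fire(
    landscape: Landscape,
    burned: list[Cell],
    severity: int,
    species_table: dict[str, SpeciesTraits],
    year: int = 0,
) -> DisturbanceEvent:
    """Kill cohorts on the burned cells per the fire kill matrix."""
    killed_biomass = 0.0
    for cell in burned:
        survivors = []
        for c in cell.cohorts:
            if fire_kills_cohort(severity, species_table[c.species], c.age):
                killed_biomass += c.biomass
            else:
                survivors.append(c)
        cell.cohorts = survivors
    return DisturbanceEvent(
        kind="fire",
        year=year,
        cells=[(c.row, c.col) for c in burned],
        severity=severity,
        biomass_killed=killed_biomass,
    )


def fire_step(
    landscape: Landscape,
    year: int,
    scenario: str,
    rng: np.random.Generator,
    start_year: int = 2010,
) -> list[DisturbanceEvent]:
    """Schedule, spread, and apply all fires of one year."""
    events = []
    for code in sorted(landscape.ecoregions):
        regime = landscape.ecoregions[code].fire_regime
        for ignition, size, severity in schedule_fires(
            landscape, code, year, scenario, rng, start_year
        ):
            burned = spread_fire(landscape, ignition, size, regime.k_fuel_age, rng)
            events.append(apply_fire(landscape, burned, severity, landscape.species, year))
    return events


def _grow_uniform_patch(
    landscape: Landscape, seed: Cell, size: int, rng: np.random.Generator
) -> list[Cell]:
    patch = [seed]
    in_patch = {(seed.row, seed.col)}
    frontier: list[Cell] = []

    def push(cell: Cell) -> None:
        for nb in landscape.neighbours(cell.row, cell.col):
            if nb.active and (nb.row, nb.col) not in in_patch:
                frontier.append(nb)

    push(seed)
    while len(patch) < size and frontier:
        idx = int(rng.integers(len(frontier)))
        cell = frontier.pop(idx)
        if (cell.row, cell.col) in in_patch:
            continue
        patch.append(cell)
        in_patch.add((cell.row, cell.col))
        push(cell)
    return patch


def wind_kill_fraction(age: int, longevity: int) -> float:
    """Blowdown kill fraction; larger (older) trees are hit hardest."""
    rel = age / longevity if longevity > 0 else 0.0
    if rel < 1 / 3:
        return WIND_KILL_BY_AGECLASS[0]
    if rel < 2 / 3:
        return WIND_KILL_BY_AGECLASS[1]
    return WIND_KILL_BY_AGECLASS[2]


def wind_step(
    landscape: Landscape, year: int, rng: np.random.Generator
) -> list[DisturbanceEvent]:
    """One year of windthrow over all ecoregions.

    Per ecoregion the expected disturbed-area fraction is 1/rotation; the
    event count is Poisson with mean ``n_cells / (rotation * patch_mean)``
    and each event blows down a small contiguous patch (geometric size with
    mean :data:`WIND_PATCH_MEAN_CELLS`).
    """
    events: list[DisturbanceEvent] = []
    by_eco: dict[int, list[Cell]] = {}
    for cell in landscape.active_cells():
        by_eco.setdefault(cell.ecoregion_code, []).append(cell)
    for code in sorted(by_eco):
        eco = landscape.ecoregions[code]
        if not math.isfinite(eco.wind_rotation):
            continue
        cells = by_eco[code]
        lam = len(cells) / (eco.wind_rotation * WIND_PATCH_MEAN_CELLS)
        for _ in range(rng.poisson(lam)):
            seed = cells[rng.integers(len(cells))]
            size = int(rng.geometric(1.0 / WIND_PATCH_MEAN_CELLS))
            patch = _grow_uniform_patch(landscape, seed, size, rng)
            killed = 0.0
            for cell in patch:
                survivors = []
                for c in cell.cohorts:
                    frac = wind_kill_fraction(
                        c.age, landscape.species[c.species].longevity
                    )
                    loss = frac * c.biomass
                    c.biomass -= loss
                    killed += loss
                    if c.biomass >= MIN_COHORT_BIOMASS:
                        survivors.append(c)
                    else:
                        killed += c.biomass
                cell.cohorts = survivors
            events.append(
                DisturbanceEvent(
                    kind="wind",
                    year=year,
                    cells=[(c.row, c.col) for c in patch],
                    severity=0,
                    biomass_killed=killed,
                )
            )
    return events


def sbw_cycle(
    params: SbwRegimeParams, horizon: int, rng: np.random.Generator
) -> list[int]:
    """Outbreak onset years (offsets from 0) over a horizon.

    Inter-onset intervals are normal around the return interval, truncated
    to exceed the outbreak duration so outbreaks never overlap.
    """
    onsets: list[int] = []
    t = 0.0
    while True:
        interval = rng.normal(params.return_interval_mean, params.return_interval_sd)
        while interval <= params.outbreak_duration:
            interval = rng.normal(
                params.return_interval_mean, params.return_interval_sd
            )
        t += interval
        if t >= horizon:
            return onsets
        onsets.append(int(round(t)))


def sbw_annual_kill_fraction(params: SbwRegimeParams, species: str) -> float:
    """Per-outbreak-year kill fraction so the compound loss over the outbreak
    duration equals the per-outbreak host mortality."""
    m = params.host_mortality.get(species)
    if m is None:
        return 0.0
    return 1.0 - (1.0 - m) ** (1.0 / params.outbreak_duration)


def apply_sbw(
    cell: Cell,
    params: SbwRegimeParams,
    year: int = 0,
) -> DisturbanceEvent:
    """Apply one outbreak year of defoliation mortality to a cell's hosts."""
    killed = 0.0
    survivors: list[Cohort] = []
    for c in cell.cohorts:
        frac = sbw_annual_kill_fraction(params, c.species)
        if frac > 0.0:
            loss = frac * c.biomass
            c.biomass -= loss
            killed += loss
        if c.biomass >= MIN_COHORT_BIOMASS or frac == 0.0:
            survivors.append(c)
        else:
            killed += c.biomass
    cell.cohorts = survivors
    return DisturbanceEvent(
        kind="sbw",
        year=year,
        cells=[(cell.row, cell.col)],
        severity=0,
        biomass_killed=killed,
    )


def sbw_step(
    landscape: Landscape,
    year: int,
    outbreak_years: dict[int, set[int]],
) -> list[DisturbanceEvent]:
    """Apply SBW mortality for every ecoregion whose outbreak schedule marks
    this year as an outbreak year.  ``outbreak_years`` maps ecoregion code to
    the set of active outbreak years (absolute)."""
    events: list[DisturbanceEvent] = []
    for cell in landscape.active_cells():
        active = outbreak_years.get(cell.ecoregion_code)
        if active and year in active and cell.cohorts:
            ev = apply_sbw(cell, landscape.ecoregions[cell.ecoregion_code].sbw_params, year)
            if ev.biomass_killed > 0:
                events.append(ev)
    return events
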