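"""Monthly, climate-driven cohort growth and annual demography.

A simplified monthly canopy process model: per cohort, potential gross
production is maximum net photosynthesis scaled by foliage mass and reduced
by multiplicative temperature, light, water, and CO2 modifiers; maintenance
respiration is a temperature-scaled fraction of the same photosynthetic
basis, so heavily shaded or water-starved cohorts run a negative monthly
balance and eventually die of depleted reserves.  Light moves through
stacked canopy layers (tallest cohort on top) by Beer-Lambert extinction;
water comes from a single-bucket soil balance per cell.

Establishment and background (age/stress) mortality run on an annual clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import Cell, Cohort, DomainError, SpeciesTraits
from .climate import BASELINE_CO2_PPM, ClimateRecord

#: Forest-floor relative light at which establishment is half-suppressed,
#: by shade-tolerance class (1 = intolerant, needs open conditions).
SHADE_LIGHT_HALF = {1: 0.50, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.02}

#: Dispersal kernel value between the effective and maximum distance.
DISPERSAL_TAIL_FACTOR = 0.15


@dataclass
class GrowthParams:
    """Tunables of the growth engine (units in comments).

    Defaults are calibrated so an unshaded black-spruce stand under the
    packaged boreal climatology rises along a sigmoid to an equilibrium of
    roughly 150-200 Mg per 4-ha cell (~20-25 tC/ha) within 100-150 years.
    """

    foliage_fraction: float = 0.10     # foliage share of cohort biomass
    foliage_cell_max: float = 8.0      # Mg foliage per cell; caps leaf area
    lai_per_foliage: float = 0.6       # LAI units per Mg foliage
    k_extinction: float = 0.5          # Beer-Lambert extinction coefficient
    transp_per_gpp: float = 40.0       # mm transpired per Mg potential GPP
    co2_beta: float = 0.30             # log CO2 fertilization slope
    co2_ref_ppm: float = BASELINE_CO2_PPM
    senescence_rate: float = 0.025     # fraction of biomass lost per year
    stress_months_lethal: int = 24     # consecutive negative months to die
    hazard_max: float = 0.30           # annual mortality hazard at longevity
    senescence_onset: float = 0.8      # hazard ramps over last 20% of lifespan
    seedling_biomass: float = 0.5      # Mg per new cohort
    establishment_prob: float = 0.25   # base annual establishment probability
    postfire_serotiny_prob: float = 0.8


DEFAULT_GROWTH_PARAMS = GrowthParams()


def temperature_modifier(t: float, traits: SpeciesTraits) -> float:
    """Piecewise-parabolic photosynthesis temperature response in [0, 1].

    Zero at and beyond the species' photosynthesis limits, 1 at the optimum:
    ``1 - ((t - topt)/(topt - tmin))^2`` below the optimum and the mirrored
    form with tmax above it.
    """
    tmin, topt, tmax = traits.psn_tmin, traits.psn_topt, traits.psn_tmax
    if not (tmin < topt < tmax):
        raise ValueError("malformed temperature traits")
    if t <= tmin or t >= tmax:
        return 0.0
    half = (topt - tmin) if t <= topt else (tmax - topt)
    f = 1.0 - ((t - topt) / half) ** 2
    return min(1.0, max(0.0, f))


def co2_modifier(co2: float, beta: float = 0.30, ref: float = BASELINE_CO2_PPM) -> float:
    """Saturating (logarithmic) CO2 enhancement, normalized to 1 at 389 ppm."""
    if co2 <= 0:
        raise ValueError("co2 must be > 0")
    return max(0.0, 1.0 + beta * math.log(co2 / ref))


def light_modifier(par: float, half_sat: float) -> float:
    """Michaelis-Menten light response of photosynthesis."""
    if par < 0:
        raise ValueError("PAR must be >= 0")
    return par / (par + half_sat) if par > 0 else 0.0


@dataclass(frozen=True)
class LayerLight:
    par_top: float    # PAR incident at the top of the layer
    absorbed: float   # PAR absorbed by the layer


def canopy_light(
    layer_lai: list[float], incident_par: float, k: float
) -> tuple[list[LayerLight], float]:
    """Beer-Lambert attenuation through stacked canopy layers.

    ``layer_lai`` is ordered tallest layer first.  Returns per-layer incident
    and absorbed PAR plus the PAR transmitted to the forest floor; absorbed
    plus transmitted equals the incident flux exactly.
    """
    if k <= 0:
        raise ValueError("extinction coefficient must be > 0")
    layers: list[LayerLight] = []
    par = incident_par
    for lai in layer_lai:
        if lai < 0:
            raise ValueError("negative leaf area")
        out = par * math.exp(-k * lai)
        layers.append(LayerLight(par_top=par, absorbed=par - out))
        par = out
    return layers, par


def soil_water_step(
    w: float, precip: float, demand: float, whc: float
) -> tuple[float, float, float]:
    """One month of the bucket water balance.

    Supply is capped by stored water plus precipitation; the bucket refills
    to at most the holding capacity and the excess drains.  Returns
    ``(new_storage, supplied, drainage)``.
    """
    if min(w, precip, demand, whc) < 0 or w > whc + 1e-9:
        raise ValueError("water balance inputs out of range")
    avail = w + precip
    supplied = min(demand, avail)
    remaining = avail - supplied
    w_new = min(whc, remaining)
    drainage = remaining - w_new
    return w_new, supplied, drainage


@dataclass
class GrowthFluxes:
    """Cell-month carbon and water fluxes (Mg per cell, mm)."""

    gpp: float
    respiration: float
    npp: float
    transpiration: float
    allocation: list[tuple[str, int, float]] = field(default_factory=list)
    npp_applied: float = 0.0  # npp after flooring biomass at zero


def cell_foliage(cell: Cell, params: GrowthParams) -> list[float]:
    """Per-cohort foliage mass (Mg), proportionally capped at the cell
    maximum so total leaf area saturates in closed stands."""
    raw = [params.foliage_fraction * c.biomass for c in cell.cohorts]
    total = sum(raw)
    if total > params.foliage_cell_max > 0:
        scale = params.foliage_cell_max / total
        raw = [f * scale for f in raw]
    return raw


def transmitted_light_fraction(cell: Cell, params: GrowthParams) -> float:
    """Fraction of incident PAR reaching the forest floor."""
    foliage = cell_foliage(cell, params)
    lai = params.lai_per_foliage * sum(foliage)
    return math.exp(-params.k_extinction * lai)


def monthly_growth(
    cell: Cell,
    record: ClimateRecord,
    species_table: dict[str, SpeciesTraits],
    whc: float,
    params: GrowthParams = DEFAULT_GROWTH_PARAMS,
    ftemp: dict[str, float] | None = None,
) -> GrowthFluxes:
    """Grow every cohort of a cell for one month; update biomass in place.

    ``ftemp`` optionally supplies precomputed per-species temperature
    modifiers for this month (the landscape loop shares them across cells of
    an ecoregion).  Negative monthly balances draw down the cohort's carbon
    reserve; any positive month refills it.
    """
    if not cell.active:
        raise DomainError("cannot grow an inactive cell")
    if not cell.cohorts:
        w_new, _, _ = soil_water_step(cell.soil_water, record.precip, 0.0, whc)
        cell.soil_water = w_new
        return GrowthFluxes(0.0, 0.0, 0.0, 0.0)

    cell.sort_cohorts()
    traits_list = []
    for c in cell.cohorts:
        tr = species_table.get(c.species)
        if tr is None:
            raise KeyError(f"no traits for species {c.species!r}")
        traits_list.append(tr)

    foliage = cell_foliage(cell, params)
    f_co2 = co2_modifier(record.co2, params.co2_beta, params.co2_ref_ppm)

    # Beer-Lambert attenuation inlined top-down (same closed form as
    # canopy_light); each cohort sees the PAR incident at its layer top
    k = params.k_extinction
    lai_per_fol = params.lai_per_foliage
    par_cur = record.par
    pot_gpp = []
    resp = []
    for c, tr, fol in zip(cell.cohorts, traits_list, foliage):
        ft = ftemp[c.species] if ftemp is not None else temperature_modifier(record.tmean, tr)
        if ft == 0.0 and fol == 0.0:
            pot_gpp.append(0.0)
            resp.append(0.0)
            continue
        basis = tr.amax * fol * ft
        fl = par_cur / (par_cur + tr.half_sat_light) if par_cur > 0 else 0.0
        pot_gpp.append(basis * fl * f_co2)
        resp.append(tr.maint_resp_frac * basis)
        par_cur *= math.exp(-k * lai_per_fol * fol)

    demand = params.transp_per_gpp * sum(pot_gpp)
    w_new, supplied, _ = soil_water_step(cell.soil_water, record.precip, demand, whc)
    cell.soil_water = w_new
    ratio = supplied / demand if demand > 0 else 1.0

    gpp_tot = resp_tot = npp_tot = applied_tot = 0.0
    allocation: list[tuple[str, int, float]] = []
    for c, tr, pg, rs in zip(cell.cohorts, traits_list, pot_gpp, resp):
        f_water = ratio ** tr.water_stress_sensitivity if ratio < 1.0 else 1.0
        gpp = pg * f_water
        npp = gpp - rs
        applied = max(npp, -c.biomass)
        c.biomass += applied
        if npp < -1e-12:
            c.stress_months += 1
        elif npp > 1e-12:
            c.stress_months = 0
        c.carbon_reserve = max(
            0.0, 1.0 - c.stress_months / params.stress_months_lethal
        )
        gpp_tot += gpp
        resp_tot += rs
        npp_tot += npp
        applied_tot += applied
        allocation.append((c.species, c.age, applied))

    return GrowthFluxes(
        gpp=gpp_tot,
        respiration=resp_tot,
        npp=npp_tot,
        transpiration=supplied,
        allocation=allocation,
        npp_applied=applied_tot,
    )


def annual_senescence(cell: Cell, params: GrowthParams = DEFAULT_GROWTH_PARAMS) -> float:
    """Annual litterfall/turnover: a fixed fraction of every cohort's
    biomass leaves the living pool.  Returns the total biomass shed (Mg)."""
    shed = 0.0
    for c in cell.cohorts:
        loss = params.senescence_rate * c.biomass
        c.biomass -= loss
        shed += loss
    return shed


@dataclass
class SeedSources:
    """Seed-source summary for one cell at one annual step.

    ``dispersal_factor`` maps species to the kernel value of the nearest
    mature seed source: 1 within the effective dispersal distance,
    :data:`DISPERSAL_TAIL_FACTOR` out to the maximum distance, absent
    otherwise.  ``burned`` marks a fire in the current year; the species
    standing in the cell before that fire support serotiny/resprouting.
    """

    dispersal_factor: dict[str, float] = field(default_factory=dict)
    burned: bool = False
    prefire_species: frozenset[str] = frozenset()


def establishment_probability(
    species: str,
    traits: SpeciesTraits,
    sources: SeedSources,
    floor_light: float,
    relative_soil_water: float,
    params: GrowthParams = DEFAULT_GROWTH_PARAMS,
) -> float:
    """Annual probability that ``species`` establishes a new cohort.

    Seed path: base probability x dispersal kernel x shade acceptance
    (Michaelis form of forest-floor light against a tolerance-dependent
    half-saturation) x a square-root water factor.  Post-fire paths: a
    serotinous species present before the fire establishes with a fixed high
    probability; a resprouter re-establishes with its sprouting probability.
    """
    if sources.burned and species in sources.prefire_species:
        if traits.postfire_regen.value == "serotiny":
            return params.postfire_serotiny_prob * math.sqrt(relative_soil_water)
        if traits.postfire_regen.value == "resprout":
            return traits.sprout_probability
    factor = sources.dispersal_factor.get(species, 0.0)
    if factor <= 0.0:
        return 0.0
    half = SHADE_LIGHT_HALF[traits.shade_tolerance]
    f_shade = floor_light / (floor_light + half)
    return params.establishment_prob * factor * f_shade * math.sqrt(relative_soil_water)


def establish(
    cell: Cell,
    sources: SeedSources,
    species_table: dict[str, SpeciesTraits],
    rng,
    whc: float,
    params: GrowthParams = DEFAULT_GROWTH_PARAMS,
) -> list[Cohort]:
    """Annual establishment draw for every candidate species in a cell.

    A species already present as a first-bin cohort cannot re-establish.
    New cohorts enter the first age bin at the seedling biomass.
    """
    if not cell.active:
        raise DomainError("cannot establish on an inactive cell")
    floor_light = transmitted_light_fraction(cell, params)
    rel_water = min(1.0, cell.soil_water / whc) if whc > 0 else 0.0
    present_young = {c.species for c in cell.cohorts if c.age_bin == 1}
    candidates = set(sources.dispersal_factor)
    if sources.burned:
        candidates |= set(sources.prefire_species)
    new: list[Cohort] = []
    for sp in sorted(candidates):
        if sp in present_young:
            continue
        traits = species_table[sp]
        p = establishment_probability(sp, traits, sources, floor_light, rel_water, params)
        if p > 0.0 and rng.random() < p:
            cohort = Cohort(species=sp, age=1, biomass=params.seedling_biomass)
            cell.cohorts.append(cohort)
            new.append(cohort)
    if new:
        cell.sort_cohorts()
    return new


def annual_hazard(
    age: int,
    longevity: int,
    params: GrowthParams = DEFAULT_GROWTH_PARAMS,
) -> float:
    """Background age-related mortality hazard for one year.

    Zero through the first 80% of the lifespan, then a quadratic ramp to
    ``hazard_max``; certain death at the longevity limit.
    """
    if age >= longevity:
        return 1.0
    onset = params.senescence_onset * longevity
    if age < onset:
        return 0.0
    frac = (age - onset) / (longevity - onset)
    return params.hazard_max * frac * frac


def background_mortality(
    cell: Cell,
    species_table: dict[str, SpeciesTraits],
    rng,
    params: GrowthParams = DEFAULT_GROWTH_PARAMS,
) -> list[Cohort]:
    """Annual age- and stress-driven cohort death; removes killed cohorts
    from the cell and returns them."""
    killed: list[Cohort] = []
    survivors: list[Cohort] = []
    for c in cell.cohorts:
        traits = species_table[c.species]
        h = annual_hazard(c.age, traits.longevity, params)
        if c.carbon_reserve <= 0.0 or h >= 1.0 or (h > 0.0 and rng.random() < h):
            killed.append(c)
        else:
            survivors.append(c)
    cell.cohorts = survivors
    return killed
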