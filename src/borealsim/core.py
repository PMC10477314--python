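"""Domain types for the simulated landscape.

A landscape is a regular grid of 4-ha cells.  Each active cell belongs to an
ecoregion (homogeneous soil texture and climate forcing) and holds a list of
species cohorts.  A cohort is all trees of one species within one age class;
its biomass pools above- and below-ground dry matter together, expressed in
Mg per cell.  Stand-level accessors here (stand age, biomass carbon) are used
by every downstream module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

CELL_AREA_HA = 4.0  # 200 m x 200 m grid resolution
AGE_BIN_YEARS = 10  # cohort age-class width
DEFAULT_CARBON_FRACTION = 0.5  # carbon per unit dry biomass


class SoilTexture(str, Enum):
    CLAY = "clay"
    CLAY_LOAM = "clay_loam"
    LOAM = "loam"
    SAND = "sand"
    SANDY_LOAM = "sandy_loam"
    SAND_CLAY_LOAM = "sand_clay_loam"


#: Bucket-model water holding capacity (mm) by soil texture.
TEXTURE_WHC_MM: dict[SoilTexture, float] = {
    SoilTexture.CLAY: 150.0,
    SoilTexture.CLAY_LOAM: 130.0,
    SoilTexture.LOAM: 120.0,
    SoilTexture.SAND_CLAY_LOAM: 100.0,
    SoilTexture.SANDY_LOAM: 90.0,
    SoilTexture.SAND: 60.0,
}


class PostfireRegen(str, Enum):
    SEROTINY = "serotiny"
    RESPROUT = "resprout"
    NONE = "none"


class DomainError(ValueError):
    """Raised when an operation is applied outside its domain (e.g. an
    inactive cell)."""


@dataclass(frozen=True)
class SpeciesTraits:
    """Life-history and growth parameters for one tree species.

    Photosynthesis temperature limits (``psn_tmin`` < ``psn_topt`` <
    ``psn_tmax``, degC) bound the growing season; ``amax`` is the maximum net
    photosynthesis proxy (Mg assimilate per Mg foliage per month) standing in
    for a foliar-nitrogen calibration; ``half_sat_light`` is the PAR level at
    which the light response is half-saturated.  Dispersal distances are in
    metres; ``min_exploitable_age`` and ``economic_rank`` (1 = most valuable)
    drive harvest stand ranking.
    """

    name: str
    conifer: bool
    longevity: int
    sexual_maturity: int
    shade_tolerance: int
    fire_tolerance: int
    effective_dispersal: float
    max_dispersal: float
    sprout_probability: float
    postfire_regen: PostfireRegen
    psn_tmin: float
    psn_topt: float
    psn_tmax: float
    amax: float
    half_sat_light: float
    maint_resp_frac: float
    water_stress_sensitivity: float
    economic_rank: int
    min_exploitable_age: int
    merchantable_fraction: float

    def __post_init__(self) -> None:
        if not (self.psn_tmin < self.psn_topt < self.psn_tmax):
            raise ValueError(
                f"{self.name}: need psn_tmin < psn_topt < psn_tmax, got "
                f"{self.psn_tmin}, {self.psn_topt}, {self.psn_tmax}"
            )
        if self.longevity <= 0:
            raise ValueError(f"{self.name}: longevity must be positive")
        if not self.sexual_maturity < self.longevity:
            raise ValueError(f"{self.name}: sexual_maturity must be < longevity")
        for fname in ("sprout_probability", "maint_resp_frac", "merchantable_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {fname}={v} outside [0, 1]")
        if not 1 <= self.shade_tolerance <= 5 or not 1 <= self.fire_tolerance <= 5:
            raise ValueError(f"{self.name}: tolerances must be ordinal 1-5")
        if self.water_stress_sensitivity < 0:
            raise ValueError(f"{self.name}: water_stress_sensitivity must be >= 0")
        if self.effective_dispersal > self.max_dispersal:
            raise ValueError(f"{self.name}: effective_dispersal > max_dispersal")


@dataclass
class FireRegimeParams:
    """Stochastic fire regime for one ecoregion.

    ``ignition_rate`` is the expected number of ignitions per year in the
    ecoregion; fire sizes (cells) follow a truncated lognormal summarised by
    (min, mean, max); ``k_fuel_age`` couples spread probability to fuel age
    (time since last fire); ``climate_scaling`` maps a climate scenario name
    to an end-of-century multiplier on the ignition rate (ramped linearly
    from 1.0 at the simulation start).
    """

    ignition_rate: float
    size_min: int = 1
    size_mean: float = 8.0
    size_max: int = 60
    severity_probs: tuple[float, ...] = (0.10, 0.20, 0.35, 0.25, 0.10)
    k_fuel_age: float = 1.0
    climate_scaling: dict[str, float] = field(
        default_factory=lambda: {"baseline": 1.0, "rcp26": 1.8, "rcp45": 3.0, "rcp85": 6.7}
    )
    scaling_ramp_years: int = 90

    def __post_init__(self) -> None:
        if not (self.size_min <= self.size_mean <= self.size_max):
            raise ValueError("need size_min <= size_mean <= size_max")
        if any(m <= 0 for m in self.climate_scaling.values()):
            raise ValueError("climate scaling multipliers must be > 0")
        if abs(sum(self.severity_probs) - 1.0) > 1e-9 or len(self.severity_probs) != 5:
            raise ValueError("severity_probs must be 5 probabilities summing to 1")

    def scaling(self, scenario: str, years_elapsed: float) -> float:
        end = self.climate_scaling.get(scenario, 1.0)
        ramp = min(1.0, max(0.0, years_elapsed / self.scaling_ramp_years))
        return 1.0 + (end - 1.0) * ramp


@dataclass
class SbwRegimeParams:
    """Spruce budworm outbreak regime.

    Outbreak onsets recur at roughly ``return_interval_mean`` years (normal,
    truncated positive); each outbreak lasts ``outbreak_duration`` years and
    kills the given per-outbreak fraction of host biomass, ordered by
    vulnerability: balsam fir > white spruce > black spruce.
    """

    return_interval_mean: float = 32.0
    return_interval_sd: float = 6.0
    outbreak_duration: int = 8
    host_mortality: dict[str, float] = field(
        default_factory=lambda: {
            "balsam_fir": 0.72,
            "white_spruce": 0.46,
            "black_spruce": 0.28,
        }
    )

    def __post_init__(self) -> None:
        if not self.return_interval_mean > self.outbreak_duration:
            raise ValueError("return interval must exceed outbreak duration")
        m = self.host_mortality
        if any(not 0.0 <= v <= 1.0 for v in m.values()):
            raise ValueError("host mortality fractions must lie in [0, 1]")
        if not (
            m.get("balsam_fir", 1.0)
            > m.get("white_spruce", 0.0)
            > m.get("black_spruce", 0.0)
        ):
            raise ValueError(
                "host mortality must be ordered balsam fir > white spruce > black spruce"
            )


@dataclass
class Ecoregion:
    """Spatial unit of homogeneous soil texture and climate forcing."""

    code: int
    soil_texture: SoilTexture
    fire_regime: FireRegimeParams
    wind_rotation: float = 3922.0
    sbw_params: SbwRegimeParams = field(default_factory=SbwRegimeParams)
    climate_key: str = "default"
    whc: float | None = None  # mm; derived from texture when omitted

    def __post_init__(self) -> None:
        if self.whc is None:
            self.whc = TEXTURE_WHC_MM[SoilTexture(self.soil_texture)]
        if self.whc <= 0:
            raise ValueError("whc must be > 0")
        if self.wind_rotation <= 0:
            raise ValueError("wind rotation must be > 0")


@dataclass
class Cohort:
    """All trees of one species and age class within a cell.

    ``biomass`` is combined above+below-ground dry matter (Mg per cell);
    ``carbon_reserve`` is a dimensionless stress buffer in [0, 1] that is
    drawn down during consecutive negative-productivity months and refilled
    by any positive month.
    """

    species: str
    age: int
    biomass: float
    carbon_reserve: float = 1.0
    stress_months: int = 0

    def __post_init__(self) -> None:
        if self.biomass < 0:
            raise ValueError("cohort biomass must be >= 0")
        if self.age < 0:
            raise ValueError("cohort age must be >= 0")

    @property
    def age_bin(self) -> int:
        """10-year age class index (ages 1-10 -> bin 1, 11-20 -> bin 2, ...)."""
        return max(1, (self.age + AGE_BIN_YEARS - 1) // AGE_BIN_YEARS)


@dataclass
class Cell:
    """One 4-ha grid cell.

    Inactive cells (water, wetland, non-commercial cover) hold no cohorts and
    are never grown, disturbed, or harvested.
    """

    row: int
    col: int
    ecoregion_code: int
    management_area: str = "MA1"
    active: bool = True
    cohorts: list[Cohort] = field(default_factory=list)
    time_since_fire: int = 100
    soil_water: float = 0.0
    area: float = CELL_AREA_HA
    last_harvest_year: int | None = None
    prefire_species: frozenset[str] = frozenset()

    def sort_cohorts(self) -> None:
        """Order cohorts tallest first: oldest, then largest biomass."""
        self.cohorts.sort(key=lambda c: (-c.age, -c.biomass, c.species))

    def species_present(self) -> set[str]:
        return {c.species for c in self.cohorts}


@dataclass
class Landscape:
    """Grid of cells plus the ecoregion and species tables they reference."""

    cells: list[list[Cell]]
    ecoregions: dict[int, Ecoregion]
    species: dict[str, SpeciesTraits]
    rng_seed: int = 0

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def cell(self, row: int, col: int) -> Cell:
        return self.cells[row][col]

    def iter_cells(self) -> Iterator[Cell]:
        for row in self.cells:
            yield from row

    def active_cells(self) -> list[Cell]:
        return [c for c in self.iter_cells() if c.active]

    def active_area_ha(self) -> float:
        return sum(c.area for c in self.iter_cells() if c.active)

    def neighbours(self, row: int, col: int) -> list[Cell]:
        """4-connected neighbours, clipped at the grid border."""
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r, c = row + dr, col + dc
            if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                out.append(self.cells[r][c])
        return out

    def total_biomass(self) -> float:
        """Total living biomass on the landscape, Mg dry matter."""
        return sum(c.biomass for cell in self.iter_cells() for c in cell.cohorts)


def stand_age(cell: Cell) -> int:
    """Stand age of a cell: the age of its oldest cohort, 0 when empty.

    Raises :class:`DomainError` for inactive cells, which have no stand.
    """
    if not cell.active:
        raise DomainError(f"cell ({cell.row}, {cell.col}) is inactive")
    if not cell.cohorts:
        return 0
    return max(c.age for c in cell.cohorts)


def total_biomass_carbon(
    cell: Cell, carbon_fraction: float = DEFAULT_CARBON_FRACTION
) -> float:
    """Biomass carbon density of a cell, tC per ha.

    Sums cohort dry biomass, converts with ``carbon_fraction`` (default 0.5),
    and divides by the cell area; additive over cohorts by construction.
    """
    if not 0.0 < carbon_fraction <= 1.0:
        raise ValueError("carbon_fraction must lie in (0, 1]")
    total = 0.0
    for c in cell.cohorts:
        if c.biomass < 0:
            raise ValueError(
                f"negative cohort biomass in cell ({cell.row}, {cell.col})"
            )
        total += c.biomass
    return total * carbon_fraction / cell.area


@dataclass(frozen=True)
class Violation:
    row: int
    col: int
    rule: str
    message: str


def validate_landscape(landscape: Landscape) -> list[Violation]:
    """Check every landscape invariant; return one entry per violation.

    An empty report means the landscape is valid.  Checked rules: active
    cells reference a known ecoregion; inactive cells carry no cohorts;
    cohort species exist in the species table with age within longevity and
    non-negative biomass; soil water stays within the ecoregion's holding
    capacity; cell area is the fixed 4 ha.
    """
    report: list[Violation] = []
    for cell in landscape.iter_cells():
        loc = (cell.row, cell.col)
        if not cell.active:
            if cell.cohorts:
                report.append(
                    Violation(*loc, "inactive_empty", "inactive cell holds cohorts")
                )
            continue
        if cell.area != CELL_AREA_HA:
            report.append(
                Violation(*loc, "cell_area", f"cell area {cell.area} != {CELL_AREA_HA} ha")
            )
        eco = landscape.ecoregions.get(cell.ecoregion_code)
        if eco is None:
            report.append(
                Violation(
                    *loc, "unknown_ecoregion", f"ecoregion code {cell.ecoregion_code}"
                )
            )
        else:
            if not 0.0 <= cell.soil_water <= eco.whc + 1e-9:
                report.append(
                    Violation(
                        *loc,
                        "soil_water_range",
                        f"soil water {cell.soil_water} outside [0, {eco.whc}]",
                    )
                )
        for cohort in cell.cohorts:
            traits = landscape.species.get(cohort.species)
            if traits is None:
                report.append(
                    Violation(*loc, "unknown_species", f"species {cohort.species}")
                )
                continue
            if cohort.age > traits.longevity:
                report.append(
                    Violation(
                        *loc,
                        "age_exceeds_longevity",
                        f"{cohort.species} age {cohort.age} > longevity "
                        f"{traits.longevity}",
                    )
                )
            if cohort.biomass < 0 or not math.isfinite(cohort.biomass):
                report.append(
                    Violation(
                        *loc, "biomass_range", f"{cohort.species} biomass {cohort.biomass}"
                    )
                )
    return report


def landscape_biomass_carbon_per_ha(
    landscape: Landscape, carbon_fraction: float = DEFAULT_CARBON_FRACTION
) -> float:
    """Mean biomass carbon density over active cells, tC per ha."""
    area = landscape.active_area_ha()
    if area == 0:
        return 0.0
    total = sum(
        c.biomass for cell in landscape.active_cells() for c in cell.cohorts
    )
    return total * carbon_fraction / area


def merge_age_bins(cell: Cell) -> None:
    """Merge same-species cohorts that share a 10-year age class.

    Biomass is summed; the merged cohort keeps the older age and the more
    stressed reserve state, so merging never creates or destroys biomass.
    """
    merged: dict[tuple[str, int], Cohort] = {}
    for c in cell.cohorts:
        key = (c.species, c.age_bin)
        if key in merged:
            m = merged[key]
            m.biomass += c.biomass
            m.age = max(m.age, c.age)
            m.carbon_reserve = min(m.carbon_reserve, c.carbon_reserve)
            m.stress_months = max(m.stress_months, c.stress_months)
        else:
            merged[key] = c
    cell.cohorts = list(merged.values())
    cell.sort_cohorts()
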