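"""Harvest prescriptions, scenario area allocation, and AAC calibration.

Stand-scale prescriptions span clear cut (CC, 100% canopy removal
intensity), CC with protection of regeneration and soils (CPRS, 95% CRI,
cohorts aged 1-20 conserved), and partial cuts removing 75/50/25% of the
eligible canopy.  A management scenario allocates the annually harvested
area across six treatment columns (CC + natural regeneration, CC +
reforestation, CPRS, PC75, PC50, PC25); stands are ranked by the dominant
species' economic value with age as tie-break, and area quotas are
calibrated by bisection so first-period merchantable harvest meets the
allowable annual cut (AAC).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .core import CELL_AREA_HA, Cell, Cohort, Landscape, SpeciesTraits

TREATMENTS = ("cc_regen", "cc_reforest", "cprs", "pc75", "pc50", "pc25")

#: Years a harvested stand stays ineligible for re-harvest (one report step).
REENTRY_YEARS = 20


@dataclass(frozen=True)
class Prescription:
    """A stand-scale silvicultural treatment.

    ``cri`` is the fraction of eligible canopy biomass removed; cohorts aged
    at most ``conserve_age_max`` are never touched (the CPRS regeneration
    protection rule).
    """

    name: str
    cri: float
    conserve_age_max: int = 0
    triggers_reforestation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.cri <= 1.0:
            raise ValueError("CRI must lie in (0, 1]")
        if self.conserve_age_max < 0:
            raise ValueError("conserve_age_max must be >= 0")


PRESCRIPTIONS: dict[str, Prescription] = {
    "CC": Prescription("CC", cri=1.00),
    "CPRS": Prescription("CPRS", cri=0.95, conserve_age_max=20),
    "PC75": Prescription("PC75", cri=0.75),
    "PC50": Prescription("PC50", cri=0.50),
    "PC25": Prescription("PC25", cri=0.25),
}

TREATMENT_PRESCRIPTION: dict[str, str] = {
    "cc_regen": "CC",
    "cc_reforest": "CC",
    "cprs": "CPRS",
    "pc75": "PC75",
    "pc50": "PC50",
    "pc25": "PC25",
}

#: Historic planted species ratio after CC/CPRS in the Quebec boreal.
DEFAULT_PLANTING_MIX: dict[str, float] = {
    "black_spruce": 0.70,
    "jack_pine": 0.25,
    "larch": 0.03,
    "white_spruce": 0.02,
}


@dataclass
class ScenarioConfig:
    """One management scenario: treatment area shares plus planting rules."""

    code: str
    area_shares: dict[str, float]
    aac_target: float = 0.0  # Mg merchantable per year
    planting_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTING_MIX)
    )

    def __post_init__(self) -> None:
        unknown = set(self.area_shares) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments: {sorted(unknown)}")
        for t in TREATMENTS:
            self.area_shares.setdefault(t, 0.0)
        total = sum(self.area_shares.values())
        if self.code == "S0":
            if total != 0.0:
                raise ValueError("S0 must have zero harvest shares")
        else:
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{self.code}: area shares sum to {total}, not 1")
        if abs(sum(self.planting_mix.values()) - 1.0) > 1e-6:
            raise ValueError("planting mix must sum to 1")
        if self.code == "S2":
            hi = (
                self.area_shares["cc_regen"]
                + self.area_shares["cc_reforest"]
                + self.area_shares["cprs"]
            )
            if hi < 0.90:
                raise ValueError(
                    "business-as-usual (S2) requires CC+CPRS on >= 90% of the area"
                )

    @property
    def mean_cri(self) -> float:
        if all(v == 0 for v in self.area_shares.values()):
            return 0.0
        return sum(
            share * PRESCRIPTIONS[TREATMENT_PRESCRIPTION[t]].cri
            for t, share in self.area_shares.items()
        )


def _norm(shares: dict[str, float]) -> dict[str, float]:
    total = sum(shares.values())
    return {k: v / total for k, v in shares.items()} if total else shares


def default_scenarios(aac_target: float = 0.0) -> dict[str, ScenarioConfig]:
    """The packaged S0-S6 scenario table.

    Printed share rows that sum to 99.9 or 100.2% are normalized.  The
    business-as-usual row (S2) uses a configurable stand-in split dominated
    by CPRS and CC (25% CC, 70% CPRS, 5% PC).
    """
    rows: dict[str, dict[str, float]] = {
        "S0": {},
        "S1": {"cc_regen": 50.0, "cprs": 50.0},
        "S2": {
            "cc_regen": 12.5, "cc_reforest": 12.5, "cprs": 70.0,
            "pc75": 5 / 3, "pc50": 5 / 3, "pc25": 5 / 3,
        },
        "S3": {
            "cc_regen": 25.0, "cc_reforest": 25.0, "cprs": 25.0,
            "pc75": 8.3, "pc50": 8.3, "pc25": 8.3,
        },
        "S4": {t: 16.7 for t in TREATMENTS},
        "S5": {
            "cc_regen": 8.3, "cc_reforest": 8.3, "cprs": 8.3,
            "pc75": 25.0, "pc50": 25.0, "pc25": 25.0,
        },
        "S6": {"pc75": 100 / 3, "pc50": 100 / 3, "pc25": 100 / 3},
    }
    return {
        code: ScenarioConfig(code=code, area_shares=_norm(shares), aac_target=aac_target)
        for code, shares in rows.items()
    }


@dataclass
class HarvestRecord:
    """Annual log line for one treatment."""

    year: int
    treatment: str
    cells: int
    area_ha: float
    total_removed: float        # Mg dry biomass
    merchantable: float         # Mg
    removed_by_species: dict[str, float] = field(default_factory=dict)
    shortfall_cells: int = 0    # quota cells left unmet (no eligible stands)

    def __post_init__(self) -> None:
        if self.merchantable > self.total_removed + 1e-9:
            raise ValueError("merchantable cannot exceed total removal")


def dominant_species(cell: Cell) -> str | None:
    """Species with the largest total biomass in the cell."""
    if not cell.cohorts:
        return None
    totals: dict[str, float] = {}
    for c in cell.cohorts:
        totals[c.species] = totals.get(c.species, 0.0) + c.biomass
    return max(sorted(totals), key=lambda sp: totals[sp])


def rank_stands(
    landscape: Landscape,
    species_table: dict[str, SpeciesTraits],
    management_area: str | None = None,
    year: int | None = None,
) -> list[Cell]:
    """Deterministic harvest queue.

    Stands whose dominant species has not reached its minimum exploitable
    age are excluded, as are stands harvested within the re-entry window.
    Ordering: dominant-species economic rank (1 first), then stand age
    descending, then grid index.
    """
    from .core import stand_age

    eligible = []
    for cell in landscape.active_cells():
        if management_area is not None and cell.management_area != management_area:
            continue
        if (
            year is not None
            and cell.last_harvest_year is not None
            and year - cell.last_harvest_year < REENTRY_YEARS
        ):
            continue
        dom = dominant_species(cell)
        if dom is None:
            continue
        traits = species_table[dom]
        dom_age = max(c.age for c in cell.cohorts if c.species == dom)
        if dom_age < traits.min_exploitable_age:
            continue
        eligible.append(
            (traits.economic_rank, -stand_age(cell), cell.row, cell.col, cell)
        )
    eligible.sort(key=lambda t: t[:4])
    return [t[4] for t in eligible]


def apply_prescription(
    cell: Cell, prescription: Prescription
) -> tuple[float, dict[str, float]]:
    """Remove exactly ``cri`` of the eligible canopy biomass from a cell.

    Cohorts at or below the conservation age are untouched; removal proceeds
    from the oldest cohort downward (overstory removal), taking a partial
    amount from the cohort at the removal boundary.  Returns the total
    removed and a per-species breakdown; cohorts reduced to (near) zero are
    deleted.
    """
    if prescription.name not in PRESCRIPTIONS:
        raise ValueError(f"unknown prescription {prescription.name!r}")
    cell.sort_cohorts()
    eligible = [c for c in cell.cohorts if c.age > prescription.conserve_age_max]
    eligible_biomass = sum(c.biomass for c in eligible)
    to_remove = prescription.cri * eligible_biomass
    removed_by_species: dict[str, float] = {}
    remaining = to_remove
    for c in eligible:  # already oldest-first
        if remaining <= 1e-12:
            break
        take = min(c.biomass, remaining)
        c.biomass -= take
        remaining -= take
        removed_by_species[c.species] = removed_by_species.get(c.species, 0.0) + take
    cell.cohorts = [
        c for c in cell.cohorts if c.biomass > 1e-9 or c.age <= prescription.conserve_age_max
    ]
    return to_remove - remaining, removed_by_species


def merchantable(
    removed_by_species: dict[str, float],
    species_table: dict[str, SpeciesTraits],
) -> float:
    """Commercially usable share of a removal, per-species fractions applied."""
    total = 0.0
    for sp, mg in removed_by_species.items():
        if mg < 0:
            raise ValueError("removed biomass must be >= 0")
        total += species_table[sp].merchantable_fraction * mg
    return total


def reforest(
    cell: Cell,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    seedling_biomass: float = 0.3,
) -> Cohort:
    """Plant one cohort on a just-harvested cell, species drawn from the
    scenario's planting mix; the planted cohort enters the first age bin."""
    species = list(scenario.planting_mix)
    probs = np.array([scenario.planting_mix[s] for s in species])
    pick = species[int(rng.choice(len(species), p=probs / probs.sum()))]
    cohort = Cohort(species=pick, age=1, biomass=seedling_biomass)
    cell.cohorts.append(cohort)
    cell.sort_cohorts()
    return cohort


def annual_harvest(
    landscape: Landscape,
    scenario: ScenarioConfig,
    year: int,
    area_quota_ha: float,
    rng: np.random.Generator,
    allocation_state: dict[str, float] | None = None,
    seedling_biomass: float = 0.3,
) -> tuple[list[HarvestRecord], dict[str, float]]:
    """Harvest one year's area quota, split across treatments by the
    scenario's shares.

    Fractional cell entitlements accumulate in ``allocation_state`` (pass
    the returned state back each year) so realized treatment shares track
    the configured shares over time despite the 4-ha cell granularity.
    Shortfalls (quota cells with no eligible stand left) are reported on the
    records, never silently absorbed.
    """
    if area_quota_ha < 0:
        raise ValueError("area quota must be >= 0")
    state = dict(allocation_state or {t: 0.0 for t in TREATMENTS})
    records: list[HarvestRecord] = []
    if area_quota_ha == 0 or all(v == 0 for v in scenario.area_shares.values()):
        return records, state

    total_cells = area_quota_ha / CELL_AREA_HA
    queue = rank_stands(landscape, landscape.species, year=year)
    qi = 0
    for treatment in TREATMENTS:
        state[treatment] = state.get(treatment, 0.0) + scenario.area_shares[treatment] * total_cells
        n_cells = int(state[treatment])
        if n_cells == 0:
            continue
        prescription = PRESCRIPTIONS[TREATMENT_PRESCRIPTION[treatment]]
        harvested = 0
        total_removed = 0.0
        by_species: dict[str, float] = {}
        while harvested < n_cells and qi < len(queue):
            cell = queue[qi]
            qi += 1
            removed, removed_sp = apply_prescription(cell, prescription)
            cell.last_harvest_year = year
            if treatment == "cc_reforest":
                reforest(cell, scenario, rng, seedling_biomass)
            total_removed += removed
            for sp, mg in removed_sp.items():
                by_species[sp] = by_species.get(sp, 0.0) + mg
            harvested += 1
        state[treatment] -= harvested
        records.append(
            HarvestRecord(
                year=year,
                treatment=treatment,
                cells=harvested,
                area_ha=harvested * CELL_AREA_HA,
                total_removed=total_removed,
                merchantable=merchantable(by_species, landscape.species),
                removed_by_species=by_species,
                shortfall_cells=n_cells - harvested,
            )
        )
    return records, state


@dataclass
class CalibrationResult:
    area_quota_ha: float
    achieved_merchantable: float  # mean Mg/yr over the calibration period
    converged: bool
    iterations: int


def calibrate_to_aac(
    landscape: Landscape,
    scenario: ScenarioConfig,
    aac_target: float,
    climate_streams: dict[str, "object"],
    sim_years: int = 20,
    tol: float = 0.01,
    max_iter: int = 18,
    seed: int = 0,
) -> CalibrationResult:
    """Bisection on the annual area quota so that first-period mean annual
    merchantable harvest matches the AAC target within ``tol`` (relative).

    The evaluation runs a deterministic harvest + growth simulation under
    the supplied (baseline) climate with natural disturbances disabled.
    When even harvesting the whole eligible landscape cannot supply the
    target, the maximum feasible quota is returned with ``converged=False``;
    the same flag marks non-convergence at the iteration cap (the 4-ha cell
    granularity can make a 1% bracket unattainable on small landscapes).
    """
    from .simulate import Simulation  # deferred: simulate imports this module

    if aac_target < 0:
        raise ValueError("aac_target must be >= 0")
    if aac_target == 0:
        return CalibrationResult(0.0, 0.0, True, 0)

    def evaluate(quota: float) -> float:
        sim = Simulation(
            landscape=copy.deepcopy(landscape),
            climate_streams=climate_streams,
            scenario=scenario,
            area_quota_ha=quota,
            years=sim_years,
            enable_wind=False,
            enable_fire=False,
            enable_sbw=False,
            seed=seed,
        )
        out = sim.run()
        if out.harvest.empty:
            return 0.0
        return float(out.harvest["merchantable"].sum()) / sim_years

    lo, hi = 0.0, landscape.active_area_ha()
    achieved_hi = evaluate(hi)
    if achieved_hi < aac_target * (1 - tol):
        return CalibrationResult(hi, achieved_hi, False, 1)
    best = (hi, achieved_hi)
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        achieved = evaluate(mid)
        if abs(achieved - aac_target) < abs(best[1] - aac_target):
            best = (mid, achieved)
        if abs(achieved - aac_target) <= tol * aac_target:
            return CalibrationResult(mid, achieved, True, it)
        if achieved < aac_target:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best[0], best[1], False, max_iter)
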