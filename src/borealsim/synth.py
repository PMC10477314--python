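"""Synthetic inputs: landscapes, climatologies, and species traits.

Generates desk-scale stand-ins for the three Quebec management units (MU1
west, MU2 centre, MU3 east): ecoregion mosaics with the published area
shares and soil textures, initial species-age compositions with the stated
dominant age classes (20-40 yr in MU1, 120-200 yr in MU2/MU3), boreal
monthly climatologies on the west-to-east precipitation gradient (~1000 ->
~800 mm) with a ~2 degC north-south offset between ecoregion bands, and a
complete trait table for the six commercial species plus trembling aspen.

The packaged trait values are plausible boreal stand-ins, not reproductions
of any calibrated parameter set; landscape totals are therefore only
meaningful in relative (scenario-contrast) terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Cell,
    Cohort,
    Ecoregion,
    FireRegimeParams,
    Landscape,
    PostfireRegen,
    SbwRegimeParams,
    SoilTexture,
    TEXTURE_WHC_MM,
    SpeciesTraits,
)
from .climate import ClimateRecord

#: Default desk-scale landscape size (cells of 4 ha -> 10,000 ha).
DEFAULT_N_CELLS = 2500

#: Baseline annual burned-area fraction targeted by the packaged fire
#: regime; sits inside the historical Quebec range of 0.04-0.26 %/yr.
DEFAULT_BURN_FRACTION = 0.0015

#: Wind rotation (years) equal to the inverse of the 1971-2000 historical
#: disturbance rate of 0.0255% of area per year.
DEFAULT_WIND_ROTATION = 1.0 / 0.000255

_MONTH_TMEAN = [-18.0, -16.0, -9.0, -1.0, 6.0, 12.0, 16.0, 14.5, 9.0, 2.0, -6.0, -14.0]
_MONTH_PRECIP_W = [0.06, 0.05, 0.06, 0.07, 0.08, 0.10, 0.11, 0.11, 0.10, 0.09, 0.09, 0.08]
_MONTH_PAR = [80.0, 150.0, 280.0, 420.0, 560.0, 650.0, 680.0, 600.0, 450.0, 280.0, 130.0, 70.0]

FIR_BIRCH = "balsam_fir_white_birch"
SPRUCE_MOSS = "spruce_moss"


@dataclass
class MuTemplate:
    """Template for one management unit.

    ``ecoregion_shares`` follow the published per-code area percentages
    (rows summing to 99-101% as printed are normalized on use);
    ``initial_age_range`` is the dominant initial age interval;
    ``annual_precip_mm`` places the unit on the west-to-east gradient; the
    SBW return interval shortens eastward where outbreaks recur fastest.
    """

    name: str
    ecoregion_shares: dict[int, float]
    soil_textures: dict[int, SoilTexture]
    domains: dict[int, str]
    initial_age_range: tuple[int, int]
    annual_precip_mm: float
    sbw_return_interval: float
    species_weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species_weights:
            self.species_weights = {
                SPRUCE_MOSS: {
                    "black_spruce": 0.62, "jack_pine": 0.14, "balsam_fir": 0.06,
                    "white_spruce": 0.03, "larch": 0.03, "white_birch": 0.06,
                    "trembling_aspen": 0.06,
                },
                FIR_BIRCH: {
                    "black_spruce": 0.38, "balsam_fir": 0.22, "white_birch": 0.16,
                    "jack_pine": 0.08, "trembling_aspen": 0.08, "white_spruce": 0.06,
                    "larch": 0.02,
                },
            }

    def normalized_shares(self) -> dict[int, float]:
        total = sum(self.ecoregion_shares.values())
        return {k: v / total for k, v in self.ecoregion_shares.items()}


MU_TEMPLATES: dict[str, MuTemplate] = {
    "MU1": MuTemplate(
        name="MU1",
        ecoregion_shares={11: 12, 16: 6, 17: 1, 21: 72, 24: 2, 26: 6, 27: 2},
        soil_textures={
            11: SoilTexture.CLAY, 16: SoilTexture.CLAY_LOAM, 17: SoilTexture.LOAM,
            21: SoilTexture.CLAY, 24: SoilTexture.SAND_CLAY_LOAM,
            26: SoilTexture.CLAY_LOAM, 27: SoilTexture.LOAM,
        },
        domains={
            11: FIR_BIRCH, 16: FIR_BIRCH, 17: FIR_BIRCH,
            21: SPRUCE_MOSS, 24: SPRUCE_MOSS, 26: SPRUCE_MOSS, 27: SPRUCE_MOSS,
        },
        initial_age_range=(20, 40),
        annual_precip_mm=1000.0,
        sbw_return_interval=55.0,
    ),
    "MU2": MuTemplate(
        name="MU2",
        ecoregion_shares={101: 3, 102: 35, 201: 4, 202: 57},
        soil_textures={
            101: SoilTexture.SAND, 102: SoilTexture.SANDY_LOAM,
            201: SoilTexture.SAND, 202: SoilTexture.SANDY_LOAM,
        },
        domains={101: FIR_BIRCH, 102: FIR_BIRCH, 201: SPRUCE_MOSS, 202: SPRUCE_MOSS},
        initial_age_range=(120, 200),
        annual_precip_mm=900.0,
        sbw_return_interval=40.0,
    ),
    "MU3": MuTemplate(
        name="MU3",
        ecoregion_shares={101: 2, 102: 30, 201: 4, 202: 64},
        soil_textures={
            101: SoilTexture.SAND, 102: SoilTexture.SANDY_LOAM,
            201: SoilTexture.SAND, 202: SoilTexture.SANDY_LOAM,
        },
        domains={101: FIR_BIRCH, 102: FIR_BIRCH, 201: SPRUCE_MOSS, 202: SPRUCE_MOSS},
        initial_age_range=(120, 200),
        annual_precip_mm=800.0,
        sbw_return_interval=32.0,
    ),
}


def default_traits() -> dict[str, SpeciesTraits]:
    """Trait table for the six commercial species plus trembling aspen.

    Conifers carry cool photosynthesis optima (16-18 degC) while the
    broadleaved pioneers run warmer and faster, so warming scenarios shift
    composition toward birch and aspen.  Jack pine (and semi-serotinous
    black spruce) regenerate from serotinous cones after fire; birch and
    aspen resprout.  Economic rank 1 is the most valuable.
    """
    rows = [
        # name, conifer, longevity, mat, shade, fire, eff, max, sprout, regen,
        # tmin, topt, tmax, amax, half_sat, mrf, wss, rank, min_age, merch
        ("black_spruce", True, 200, 30, 4, 2, 80, 200, 0.0, "serotiny",
         1.0, 16.0, 30.0, 0.38, 120.0, 0.24, 1.0, 1, 90, 0.85),
        ("jack_pine", True, 150, 20, 1, 4, 60, 150, 0.0, "serotiny",
         2.0, 18.0, 32.0, 0.42, 330.0, 0.30, 0.8, 2, 80, 0.85),
        ("balsam_fir", True, 120, 25, 5, 1, 80, 160, 0.0, "none",
         1.0, 16.0, 30.0, 0.38, 80.0, 0.22, 1.2, 3, 70, 0.85),
        ("white_spruce", True, 180, 30, 3, 2, 100, 200, 0.0, "none",
         1.0, 17.0, 31.0, 0.38, 180.0, 0.26, 1.0, 2, 90, 0.85),
        ("larch", True, 150, 30, 1, 2, 80, 200, 0.0, "none",
         1.0, 17.0, 31.0, 0.40, 330.0, 0.30, 0.9, 4, 80, 0.85),
        ("white_birch", False, 120, 20, 2, 2, 200, 400, 0.5, "resprout",
         3.0, 21.0, 34.0, 0.48, 250.0, 0.28, 1.0, 5, 60, 0.70),
        ("trembling_aspen", False, 100, 15, 1, 2, 300, 1000, 0.9, "resprout",
         3.0, 22.0, 35.0, 0.52, 330.0, 0.30, 1.1, 5, 60, 0.70),
    ]
    out = {}
    for (name, conifer, longevity, mat, shade, fire, eff, mx, sprout, regen,
         tmin, topt, tmax, amax, hs, mrf, wss, rank, min_age, merch) in rows:
        out[name] = SpeciesTraits(
            name=name, conifer=conifer, longevity=longevity, sexual_maturity=mat,
            shade_tolerance=shade, fire_tolerance=fire, effective_dispersal=eff,
            max_dispersal=mx, sprout_probability=sprout,
            postfire_regen=PostfireRegen(regen), psn_tmin=tmin, psn_topt=topt,
            psn_tmax=tmax, amax=amax, half_sat_light=hs, maint_resp_frac=mrf,
            water_stress_sensitivity=wss, economic_rank=rank,
            min_exploitable_age=min_age, merchantable_fraction=merch,
        )
    return out


def initial_biomass(age: float, asymptote: float = 100.0, scale: float = 50.0) -> float:
    """Age-biomass ramp for initial stands, saturating near 100 Mg/cell."""
    return asymptote * (1.0 - math.exp(-age / scale))


def generate_climatology(
    template: MuTemplate, rng: np.random.Generator | None = None
) -> dict[str, list[ClimateRecord]]:
    """Monthly baseline climatology per ecoregion climate key.

    Annual precipitation sits on the documented west-to-east gradient
    (wetter MU1); the southern (fir-birch) ecoregion band runs ~2 degC
    warmer than the northern (spruce-moss) band; winters stay well below
    freezing.  A small reproducible per-ecoregion jitter keeps ecoregions
    distinct.
    """
    rng = rng or np.random.default_rng(0)
    out: dict[str, list[ClimateRecord]] = {}
    for code in sorted(template.ecoregion_shares):
        offset = 1.0 if template.domains[code] == FIR_BIRCH else -1.0
        jitter = float(rng.normal(0.0, 0.15))
        records = [
            ClimateRecord(
                year=2010,
                month=m + 1,
                tmean=_MONTH_TMEAN[m] + offset + jitter,
                precip=template.annual_precip_mm * _MONTH_PRECIP_W[m],
                par=_MONTH_PAR[m],
                co2=389.0,
            )
            for m in range(12)
        ]
        out[f"{template.name}_{code}"] = records
    return out


def generate_landscape(
    template: MuTemplate,
    n_cells: int = DEFAULT_N_CELLS,
    rng: np.random.Generator | int | None = None,
    inactive_fraction: float = 0.05,
    burn_fraction: float = DEFAULT_BURN_FRACTION,
    fire_size_mean: float = 8.0,
    wind_rotation: float = DEFAULT_WIND_ROTATION,
    dominant_age_prob: float = 0.65,
) -> Landscape:
    """Generate a landscape emulating one management unit.

    Ecoregions are laid out as contiguous bands with the template's area
    shares (within 2% at the default size); initial stand ages put at least
    half the cells in the template's dominant interval; compositions are
    drawn from the bioclimatic-domain species pool with black spruce
    dominance; about ``inactive_fraction`` of cells are inactive (water or
    non-commercial cover).  The per-ecoregion fire ignition rate is derived
    from the target annual burned fraction and mean fire size.
    """
    if n_cells < 100:
        raise ValueError("n_cells must be >= 100 to honour the area shares")
    seed = rng if isinstance(rng, (int, np.integer)) else 0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    traits = default_traits()
    shares = template.normalized_shares()
    codes = sorted(shares)

    n_rows = int(math.floor(math.sqrt(n_cells)))
    n_cols = int(math.ceil(n_cells / n_rows))

    # contiguous ecoregion bands over the flattened row-major index
    bounds = np.cumsum([shares[c] for c in codes]) * n_cells
    cell_codes = np.empty(n_rows * n_cols, dtype=int)
    cell_codes[:] = codes[-1]
    start = 0
    for code, b in zip(codes, bounds):
        stop = int(round(b))
        cell_codes[start:stop] = code
        start = stop

    eco_counts = {c: int((cell_codes[:n_cells] == c).sum()) for c in codes}
    ecoregions = {
        code: Ecoregion(
            code=code,
            soil_texture=template.soil_textures[code],
            fire_regime=FireRegimeParams(
                ignition_rate=burn_fraction * eco_counts[code] / fire_size_mean,
                size_mean=fire_size_mean,
            ),
            wind_rotation=wind_rotation,
            sbw_params=SbwRegimeParams(
                return_interval_mean=template.sbw_return_interval
            ),
            climate_key=f"{template.name}_{code}",
        )
        for code in codes
    }

    lo, hi = template.initial_age_range
    cells: list[list[Cell]] = []
    for r in range(n_rows):
        row_cells: list[Cell] = []
        for c in range(n_cols):
            flat = r * n_cols + c
            code = int(cell_codes[flat])
            inactive = flat >= n_cells or rng.random() < inactive_fraction
            if inactive:
                row_cells.append(Cell(r, c, ecoregion_code=code, active=False))
                continue
            eco = ecoregions[code]
            weights = template.species_weights[template.domains[code]]
            pool = sorted(weights)
            probs = np.array([weights[s] for s in pool])
            dom = pool[int(rng.choice(len(pool), p=probs / probs.sum()))]
            if rng.random() < dominant_age_prob:
                age = int(rng.integers(lo, hi + 1))
            else:
                age = int(rng.integers(10, 201))
            age = min(age, traits[dom].longevity - 10)
            biomass = initial_biomass(age)
            cohorts = [Cohort(species=dom, age=age, biomass=0.75 * biomass)]
            if rng.random() < 0.6:
                others = [s for s in pool if s != dom]
                oprobs = np.array([weights[s] for s in others])
                sec = others[int(rng.choice(len(others), p=oprobs / oprobs.sum()))]
                sec_age = max(10, int(age * rng.uniform(0.4, 1.0)))
                sec_age = min(sec_age, traits[sec].longevity - 10)
                cohorts.append(Cohort(species=sec, age=sec_age, biomass=0.25 * biomass))
            else:
                cohorts[0].biomass = biomass
            cell = Cell(
                r, c,
                ecoregion_code=code,
                management_area="MA1" if c < n_cols // 2 else "MA2",
                cohorts=cohorts,
                time_since_fire=age,
                soil_water=TEXTURE_WHC_MM[template.soil_textures[code]],
            )
            cell.sort_cohorts()
            row_cells.append(cell)
        cells.append(row_cells)
    return Landscape(cells=cells, ecoregions=ecoregions, species=traits, rng_seed=int(seed))
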