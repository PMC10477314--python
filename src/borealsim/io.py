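"""Plain-text landscape, trait, and climate exchange formats.

Rasters use the 6-line ASCII Grid dialect (ncols/nrows/xllcorner/yllcorner/
cellsize/NODATA_value header followed by whitespace-separated rows).  Tables
are tab-separated with a documented header row.  A landscape round-trips
through a directory of: ecoregion map, management-area map, initial-community
map, community table (map code -> species/age/biomass triples), species
trait table, and ecoregion parameter table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Cell,
    Cohort,
    Ecoregion,
    FireRegimeParams,
    Landscape,
    PostfireRegen,
    SbwRegimeParams,
    SoilTexture,
    SpeciesTraits,
)

NODATA = -9999

TRAIT_COLUMNS = [
    "name", "conifer", "longevity", "sexual_maturity", "shade_tolerance",
    "fire_tolerance", "effective_dispersal", "max_dispersal",
    "sprout_probability", "postfire_regen", "psn_tmin", "psn_topt", "psn_tmax",
    "amax", "half_sat_light", "maint_resp_frac", "water_stress_sensitivity",
    "economic_rank", "min_exploitable_age", "merchantable_fraction",
]

CLIMATE_COLUMNS = ["ecoregion_key", "year", "month", "tmean", "precip", "par", "co2"]


def write_ascii_grid(path: str | Path, grid: np.ndarray, cellsize: float = 200.0) -> None:
    """Write an integer raster in ASCII Grid format."""
    grid = np.asarray(grid)
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for row in grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> np.ndarray:
    """Read an ASCII Grid raster written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, dtype=int)
    data = np.atleast_2d(data)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != expected:
        raise ValueError(f"grid shape {data.shape} does not match header {expected}")
    return data


def write_traits(path: str | Path, species: dict[str, SpeciesTraits]) -> None:
    rows = []
    for tr in species.values():
        row = {c: getattr(tr, c) for c in TRAIT_COLUMNS if c not in ("conifer", "postfire_regen")}
        row["conifer"] = int(tr.conifer)
        row["postfire_regen"] = tr.postfire_regen.value
        rows.append(row)
    pd.DataFrame(rows)[TRAIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_traits(path: str | Path) -> dict[str, SpeciesTraits]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    out: dict[str, SpeciesTraits] = {}
    for rec in df.to_dict("records"):
        rec["conifer"] = bool(rec["conifer"])
        rec["postfire_regen"] = PostfireRegen(rec["postfire_regen"])
        for k in ("longevity", "sexual_maturity", "shade_tolerance", "fire_tolerance",
                  "economic_rank", "min_exploitable_age"):
            rec[k] = int(rec[k])
        out[rec["name"]] = SpeciesTraits(**rec)
    return out


def write_ecoregions(path: str | Path, ecoregions: dict[int, Ecoregion]) -> None:
    """Serialize the ecoregion table, fire/wind/SBW parameters inlined as JSON."""
    rows = []
    for eco in ecoregions.values():
        fr = eco.fire_regime
        rows.append({
            "code": eco.code,
            "soil_texture": SoilTexture(eco.soil_texture).value,
            "whc": eco.whc,
            "wind_rotation": eco.wind_rotation,
            "climate_key": eco.climate_key,
            "fire_ignition_rate": fr.ignition_rate,
            "fire_size_min": fr.size_min,
            "fire_size_mean": fr.size_mean,
            "fire_size_max": fr.size_max,
            "fire_severity_probs": json.dumps(list(fr.severity_probs)),
            "fire_k_fuel_age": fr.k_fuel_age,
            "fire_climate_scaling": json.dumps(fr.climate_scaling),
            "fire_scaling_ramp_years": fr.scaling_ramp_years,
            "sbw_return_interval_mean": eco.sbw_params.return_interval_mean,
            "sbw_return_interval_sd": eco.sbw_params.return_interval_sd,
            "sbw_outbreak_duration": eco.sbw_params.outbreak_duration,
            "sbw_host_mortality": json.dumps(eco.sbw_params.host_mortality),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ecoregions(path: str | Path) -> dict[int, Ecoregion]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, Ecoregion] = {}
    for rec in df.to_dict("records"):
        fire = FireRegimeParams(
            ignition_rate=rec["fire_ignition_rate"],
            size_min=int(rec["fire_size_min"]),
            size_mean=rec["fire_size_mean"],
            size_max=int(rec["fire_size_max"]),
            severity_probs=tuple(json.loads(rec["fire_severity_probs"])),
            k_fuel_age=rec["fire_k_fuel_age"],
            climate_scaling=json.loads(rec["fire_climate_scaling"]),
            scaling_ramp_years=int(rec["fire_scaling_ramp_years"]),
        )
        sbw = SbwRegimeParams(
            return_interval_mean=rec["sbw_return_interval_mean"],
            return_interval_sd=rec["sbw_return_interval_sd"],
            outbreak_duration=int(rec["sbw_outbreak_duration"]),
            host_mortality=json.loads(rec["sbw_host_mortality"]),
        )
        code = int(rec["code"])
        out[code] = Ecoregion(
            code=code,
            soil_texture=SoilTexture(rec["soil_texture"]),
            fire_regime=fire,
            wind_rotation=rec["wind_rotation"],
            sbw_params=sbw,
            climate_key=rec["climate_key"],
            whc=rec["whc"],
        )
    return out


def save_landscape(directory: str | Path, landscape: Landscape) -> None:
    """Write a landscape as rasters + tables under ``directory``.

    Every distinct cohort configuration receives one community map code; the
    community table lists, per code, one row per species/age/biomass triple.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nrows, ncols = landscape.n_rows, landscape.n_cols
    eco_grid = np.full((nrows, ncols), NODATA, dtype=int)
    comm_grid = np.full((nrows, ncols), NODATA, dtype=int)
    mgmt_codes: dict[str, int] = {}
    mgmt_grid = np.full((nrows, ncols), NODATA, dtype=int)
    comm_index: dict[tuple, int] = {}
    comm_rows: list[dict] = []
    water_rows: list[dict] = []
    for cell in landscape.iter_cells():
        if not cell.active:
            continue
        eco_grid[cell.row, cell.col] = cell.ecoregion_code
        mgmt_codes.setdefault(cell.management_area, len(mgmt_codes) + 1)
        mgmt_grid[cell.row, cell.col] = mgmt_codes[cell.management_area]
        key = tuple(sorted((c.species, c.age, round(c.biomass, 6)) for c in cell.cohorts))
        if key not in comm_index:
            code = len(comm_index) + 1
            comm_index[key] = code
            for sp, age, biomass in key:
                comm_rows.append(
                    {"map_code": code, "species": sp, "age": age, "biomass": biomass}
                )
            if not key:
                comm_rows.append(
                    {"map_code": code, "species": "", "age": 0, "biomass": 0.0}
                )
        comm_grid[cell.row, cell.col] = comm_index[key]
        water_rows.append(
            {"row": cell.row, "col": cell.col,
             "time_since_fire": cell.time_since_fire, "soil_water": cell.soil_water}
        )
    write_ascii_grid(directory / "ecoregions.asc", eco_grid)
    write_ascii_grid(directory / "management.asc", mgmt_grid)
    write_ascii_grid(directory / "communities.asc", comm_grid)
    pd.DataFrame(comm_rows).to_csv(directory / "communities.tsv", sep="\t", index=False)
    pd.DataFrame(water_rows).to_csv(directory / "cell_state.tsv", sep="\t", index=False)
    write_traits(directory / "species_traits.tsv", landscape.species)
    write_ecoregions(directory / "ecoregion_params.tsv", landscape.ecoregions)
    meta = {
        "rng_seed": landscape.rng_seed,
        "management_codes": mgmt_codes,
    }
    (directory / "landscape.json").write_text(json.dumps(meta, indent=1))


def load_landscape(directory: str | Path) -> Landscape:
    directory = Path(directory)
    eco_grid = read_ascii_grid(directory / "ecoregions.asc")
    mgmt_grid = read_ascii_grid(directory / "management.asc")
    comm_grid = read_ascii_grid(directory / "communities.asc")
    comm_df = pd.read_csv(directory / "communities.tsv", sep="\t")
    state_df = pd.read_csv(directory / "cell_state.tsv", sep="\t")
    species = read_traits(directory / "species_traits.tsv")
    ecoregions = read_ecoregions(directory / "ecoregion_params.tsv")
    meta = json.loads((directory / "landscape.json").read_text())
    mgmt_names = {v: k for k, v in meta["management_codes"].items()}

    comm_map: dict[int, list[tuple[str, int, float]]] = {}
    for rec in comm_df.to_dict("records"):
        comm_map.setdefault(int(rec["map_code"]), [])
        if isinstance(rec["species"], str) and rec["species"]:
            comm_map[int(rec["map_code"])].append(
                (rec["species"], int(rec["age"]), float(rec["biomass"]))
            )
    state = {
        (int(r["row"]), int(r["col"])): (int(r["time_since_fire"]), float(r["soil_water"]))
        for r in state_df.to_dict("records")
    }

    nrows, ncols = eco_grid.shape
    cells: list[list[Cell]] = []
    for r in range(nrows):
        row_cells = []
        for c in range(ncols):
            if eco_grid[r, c] == NODATA:
                row_cells.append(Cell(r, c, ecoregion_code=0, active=False))
                continue
            tsf, water = state[(r, c)]
            cohorts = [
                Cohort(species=sp, age=age, biomass=bm)
                for sp, age, bm in comm_map[int(comm_grid[r, c])]
            ]
            cell = Cell(
                r, c,
                ecoregion_code=int(eco_grid[r, c]),
                management_area=mgmt_names[int(mgmt_grid[r, c])],
                cohorts=cohorts,
                time_since_fire=tsf,
                soil_water=water,
            )
            cell.sort_cohorts()
            row_cells.append(cell)
        cells.append(row_cells)
    return Landscape(
        cells=cells, ecoregions=ecoregions, species=species,
        rng_seed=int(meta["rng_seed"]),
    )


def write_climate_table(path: str | Path, frames: dict[str, pd.DataFrame]) -> None:
    """Write climate streams as one delimited table (see CLIMATE_COLUMNS)."""
    parts = []
    for key, df in frames.items():
        part = df.copy()
        part.insert(0, "ecoregion_key", key)
        parts.append(part[CLIMATE_COLUMNS])
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_climate_table(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    return {
        str(key): part.drop(columns="ecoregion_key").reset_index(drop=True)
        for key, part in df.groupby("ecoregion_key", sort=False)
    }
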