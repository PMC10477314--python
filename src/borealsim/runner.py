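"""Factorial scenario orchestration: climate x management x replicate.

Replicate r of every scenario uses seed ``base_seed + r`` and an identical
initial landscape, so contrasts between management scenarios within a
climate are paired (variance reduction).  Outputs land in one directory per
run plus a machine-readable manifest.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import copy

import pandas as pd

from .analysis import delta_series
from .climate import SCENARIOS, build_scenario_stream
from .harvest import ScenarioConfig, default_scenarios, calibrate_to_aac
from .simulate import RunOutput, Simulation
from .synth import MU_TEMPLATES, generate_climatology, generate_landscape, DEFAULT_N_CELLS


@dataclass
class RunConfig:
    """Configuration of one scenario matrix."""

    template: str = "MU2"
    n_cells: int = DEFAULT_N_CELLS
    climates: tuple[str, ...] = ("baseline",)
    managements: tuple[str, ...] = ("S0",)
    enable_wind: bool = True
    enable_fire: bool = True
    enable_sbw: bool = True
    years: int = 300
    replicates: int = 3
    base_seed: int = 0
    area_quota_ha: float = 0.0
    aac_target: float = 0.0  # when > 0, quota is calibrated per scenario
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.template not in MU_TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.years < 20 or self.years % 20:
            raise ValueError("years must be >= 20 and divisible by the 20-yr step")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        bad = set(self.climates) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown climate scenarios: {sorted(bad)}")
        known = set(default_scenarios())
        bad = set(self.managements) - known
        if bad:
            raise ValueError(f"unknown management scenarios: {sorted(bad)}")


def build_climate_streams(
    template_name: str, climate: str, seed: int = 0
) -> dict[str, "object"]:
    """Full 2010-2310 streams per ecoregion climate key for one scenario."""
    import numpy as np

    template = MU_TEMPLATES[template_name]
    clim = generate_climatology(template, np.random.default_rng(seed))
    return {
        key: build_scenario_stream(records, climate, ecoregion_key=key)
        for key, records in clim.items()
    }


def run_matrix(config: RunConfig) -> dict[tuple[str, str, int], RunOutput]:
    """Run every (climate, management, replicate) combination.

    Failures in individual runs are recorded in the manifest and do not
    discard completed runs.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    scenarios = default_scenarios(config.aac_target)
    outputs: dict[tuple[str, str, int], RunOutput] = {}
    failures: list[dict] = []

    streams_by_climate = {
        cl: build_climate_streams(config.template, cl, config.base_seed)
        for cl in config.climates
    }
    baseline_streams = (
        streams_by_climate.get("baseline")
        or build_climate_streams(config.template, "baseline", config.base_seed)
    )

    for rep in range(config.replicates):
        seed = config.base_seed + rep
        base_landscape = generate_landscape(
            MU_TEMPLATES[config.template], config.n_cells, seed
        )
        quotas: dict[str, float] = {}
        for mgmt in config.managements:
            scen = scenarios[mgmt]
            if mgmt == "S0":
                quotas[mgmt] = 0.0
            elif config.aac_target > 0:
                cal = calibrate_to_aac(
                    copy.deepcopy(base_landscape), scen, config.aac_target,
                    baseline_streams, seed=seed,
                )
                quotas[mgmt] = cal.area_quota_ha
            else:
                quotas[mgmt] = config.area_quota_ha
        for climate in config.climates:
            for mgmt in config.managements:
                key = (climate, mgmt, rep)
                try:
                    sim = Simulation(
                        landscape=copy.deepcopy(base_landscape),
                        climate_streams=streams_by_climate[climate],
                        scenario=scenarios[mgmt],
                        area_quota_ha=quotas[mgmt],
                        years=config.years,
                        enable_wind=config.enable_wind,
                        enable_fire=config.enable_fire,
                        enable_sbw=config.enable_sbw,
                        seed=seed,
                    )
                    out = sim.run()
                    outputs[key] = out
                    if out_dir:
                        _write_run(out_dir, key, out)
                except Exception as exc:  # keep completed runs
                    failures.append(
                        {"run": list(key), "error": str(exc),
                         "traceback": traceback.format_exc()}
                    )
    if out_dir:
        manifest = {
            "config": asdict(config),
            "runs": [list(k) for k in outputs],
            "quotas_last_replicate": quotas if config.managements else {},
            "failures": failures,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if failures and not outputs:
        raise RuntimeError(f"all runs failed; first error: {failures[0]['error']}")
    return outputs


def _run_dirname(key: tuple[str, str, int]) -> str:
    climate, mgmt, rep = key
    return f"{climate}_{mgmt}_r{rep}"


def _write_run(out_dir: Path, key: tuple[str, str, int], out: RunOutput) -> None:
    d = out_dir / _run_dirname(key)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("series", "age_shares", "type_shares", "harvest", "events", "fluxes"):
        getattr(out, name).to_csv(d / f"{name}.csv", index=False)


def compare_to_natural(
    outputs: dict[tuple[str, str, int], RunOutput],
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Biomass-carbon delta tables vs the same-climate no-harvest run.

    Requires the S0 run of every climate present; deltas are computed per
    replicate on matched seeds and then averaged.  Returns one tidy frame
    per climate (management, year, delta mean/min/max in tC per ha).
    """
    climates = {k[0] for k in outputs}
    tables: dict[str, pd.DataFrame] = {}
    for climate in sorted(climates):
        reps = sorted({k[2] for k in outputs if k[0] == climate})
        naturals = {
            r: outputs.get((climate, "S0", r)) for r in reps
        }
        if any(v is None for v in naturals.values()):
            raise ValueError(f"no-harvest (S0) run missing for climate {climate!r}")
        rows = []
        for (cl, mgmt, rep), out in sorted(outputs.items()):
            if cl != climate:
                continue
            delta = delta_series(
                out.carbon_series("total"), naturals[rep].carbon_series("total")
            )
            for y, v in zip(delta.years, delta.values):
                rows.append(
                    {"management": mgmt, "replicate": rep,
                     "year": int(y), "delta_tC_per_ha": float(v)}
                )
        df = pd.DataFrame(rows)
        agg = df.groupby(["management", "year"], as_index=False).agg(
            delta_mean=("delta_tC_per_ha", "mean"),
            delta_min=("delta_tC_per_ha", "min"),
            delta_max=("delta_tC_per_ha", "max"),
        )
        tables[climate] = agg
        if out_dir:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            agg.to_csv(Path(out_dir) / f"delta_{climate}.csv", index=False)
    return tables
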