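"""Monthly climate forcing per ecoregion, 2010-2310.

Four scenarios are supported: a stationary baseline (historic monthly means,
CO2 fixed at 389 ppm) and three transient pathways (rcp26, rcp45, rcp85)
that are defined to 2100 and extended to 2310 with post-2100 continuation
rules: the low and mid pathways hold their 2091-2100 monthly climatology
constant (concentration stabilization), while the high pathway continues its
2081-2100 linear decadal trend in temperature and precipitation until 2250
and then plateaus.  CO2 follows packaged decadal pathway tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCENARIOS = ("baseline", "rcp26", "rcp45", "rcp85")
START_YEAR = 2010
END_YEAR = 2310  # inclusive
N_YEARS = END_YEAR - START_YEAR + 1  # 301
BASELINE_CO2_PPM = 389.0

# Decadal CO2 concentrations (ppm), value applying to [decade, decade+10).
# Transient pathways: rises to ~421/538/936 ppm by 2100; post-2100 the low
# pathway declines slowly, the mid pathway stabilizes by 2150, and the high
# pathway keeps rising to ~1962 ppm at 2250 before holding constant.
_CO2_2100 = {"rcp26": 421.0, "rcp45": 538.0, "rcp85": 936.0}
_CO2_DECADES_TO_2100 = {
    "rcp26": [389, 412, 431, 441, 443, 442, 437, 431, 426, 421],
    "rcp45": [389, 411, 435, 461, 487, 508, 524, 531, 533, 538],
    "rcp85": [389, 415, 449, 489, 541, 604, 677, 758, 845, 936],
}


def _build_co2_table() -> dict[str, dict[int, float]]:
    table: dict[str, dict[int, float]] = {"baseline": {}}
    decades = list(range(START_YEAR, END_YEAR + 1, 10))
    for d in decades:
        table["baseline"][d] = BASELINE_CO2_PPM
    for scen, to2100 in _CO2_DECADES_TO_2100.items():
        vals = dict(zip(range(2010, 2110, 10), (float(v) for v in to2100)))
        for d in range(2110, END_YEAR + 1, 10):
            if scen == "rcp26":
                # slow drawdown toward ~360 ppm at 2300
                vals[d] = max(360.0, 421.0 - (d - 2100) * (61.0 / 200.0))
            elif scen == "rcp45":
                # stabilizes at 543 ppm by 2150
                vals[d] = min(543.0, 538.0 + (d - 2100) * (5.0 / 50.0))
            else:
                # continued rise to 1962 ppm at 2250, then constant
                vals[d] = min(1962.0, 936.0 + (d - 2100) * ((1962.0 - 936.0) / 150.0))
        table[scen] = vals
    return table


CO2_DECADAL_PPM = _build_co2_table()


def co2_at(scenario: str, year: int) -> float:
    """Piecewise-constant decadal CO2 concentration (ppm) for a scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if not START_YEAR <= year <= END_YEAR:
        raise ValueError(f"year {year} outside [{START_YEAR}, {END_YEAR}]")
    decade = year - (year - START_YEAR) % 10
    return CO2_DECADAL_PPM[scenario][decade]


@dataclass(frozen=True)
class ClimateRecord:
    """One month of forcing: mean temperature (degC), precipitation (mm),
    photosynthetically active radiation, and CO2 (ppm)."""

    year: int
    month: int
    tmean: float
    precip: float
    par: float
    co2: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError("month must be 1-12")
        if self.precip < 0 or self.par < 0 or self.co2 <= 0:
            raise ValueError("precip/par must be >= 0 and co2 > 0")


@dataclass
class ClimateStream:
    """Ordered monthly records for one ecoregion under one scenario."""

    scenario: str
    ecoregion_key: str
    data: pd.DataFrame  # columns: year, month, tmean, precip, par, co2

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        self.data = self.data.reset_index(drop=True)

    def validate(self, start: int = START_YEAR, end: int = END_YEAR) -> None:
        """Assert the stream covers [start, end] monthly with no gaps."""
        d = self.data
        expected = (end - start + 1) * 12
        if len(d) != expected:
            raise ValueError(f"expected {expected} records, found {len(d)}")
        key = d["year"].to_numpy() * 12 + (d["month"].to_numpy() - 1)
        want = np.arange(start * 12, (end + 1) * 12)
        if not np.array_equal(key, want):
            raise ValueError("records are not strictly ordered monthly with no gaps")

    def records(self) -> list[ClimateRecord]:
        return [ClimateRecord(**rec) for rec in self.data.to_dict("records")]

    def year_slice(self, year: int) -> pd.DataFrame:
        return self.data[self.data["year"] == year]


def climatology_frame(monthly: list[ClimateRecord]) -> pd.DataFrame:
    if len(monthly) != 12 or sorted(r.month for r in monthly) != list(range(1, 13)):
        raise ValueError("climatology needs exactly one record per month 1-12")
    rows = [
        {"month": r.month, "tmean": r.tmean, "precip": r.precip, "par": r.par}
        for r in sorted(monthly, key=lambda r: r.month)
    ]
    return pd.DataFrame(rows)


def build_baseline_stream(
    monthly_climatology: list[ClimateRecord],
    years: range = range(START_YEAR, END_YEAR + 1),
    ecoregion_key: str = "default",
) -> ClimateStream:
    """Repeat the historic monthly climatology for every year; CO2 fixed at
    the 2010 baseline concentration of 389 ppm."""
    clim = climatology_frame(monthly_climatology)
    n = len(years)
    data = pd.DataFrame(
        {
            "year": np.repeat(list(years), 12),
            "month": np.tile(np.arange(1, 13), n),
            "tmean": np.tile(clim["tmean"].to_numpy(), n),
            "precip": np.tile(clim["precip"].to_numpy(), n),
            "par": np.tile(clim["par"].to_numpy(), n),
            "co2": BASELINE_CO2_PPM,
        }
    )
    return ClimateStream(scenario="baseline", ecoregion_key=ecoregion_key, data=data)


def synthetic_rcp_fragment(
    monthly_climatology: list[ClimateRecord],
    scenario: str,
    delta_t_2100: float | None = None,
    precip_change_frac_2100: float = 0.07,
    ecoregion_key: str = "default",
) -> ClimateStream:
    """Build a 2010-2100 transient fragment: baseline plus linear anomaly
    ramps reaching the scenario's end-of-century warming (defaults +1, +2,
    +5 degC for rcp26/rcp45/rcp85) and a modest precipitation increase."""
    if scenario not in ("rcp26", "rcp45", "rcp85"):
        raise ValueError("fragment scenarios are rcp26/rcp45/rcp85")
    if delta_t_2100 is None:
        delta_t_2100 = {"rcp26": 1.0, "rcp45": 2.0, "rcp85": 5.0}[scenario]
    clim = climatology_frame(monthly_climatology)
    years = np.arange(START_YEAR, 2101)
    frac = (years - START_YEAR) / (2100 - START_YEAR)
    rows = []
    for year, f in zip(years, frac):
        co2 = co2_at(scenario, int(year))
        for m in range(12):
            rows.append(
                {
                    "year": int(year),
                    "month": m + 1,
                    "tmean": clim["tmean"].iloc[m] + delta_t_2100 * f,
                    "precip": clim["precip"].iloc[m] * (1 + precip_change_frac_2100 * f),
                    "par": clim["par"].iloc[m],
                    "co2": co2,
                }
            )
    return ClimateStream(scenario=scenario, ecoregion_key=ecoregion_key, data=pd.DataFrame(rows))


def _monthly_means(data: pd.DataFrame, year_lo: int, year_hi: int) -> pd.DataFrame:
    sel = data[(data["year"] >= year_lo) & (data["year"] <= year_hi)]
    return sel.groupby("month", as_index=True)[["tmean", "precip", "par"]].mean()


def extend_rcp(fragment: ClimateStream, scenario: str | None = None) -> ClimateStream:
    """Extend a 2010-2100 monthly fragment to 2310.

    2010-2100 records pass through unchanged.  rcp26/rcp45: every post-2100
    year repeats the 2091-2100 monthly climatology.  rcp85: per-month linear
    trends fitted over 2081-2100 continue until 2250, then hold constant;
    precipitation is floored at zero.  CO2 always follows the decadal
    pathway table.
    """
    scenario = scenario or fragment.scenario
    if scenario not in ("rcp26", "rcp45", "rcp85"):
        raise ValueError("extension applies to rcp scenarios only")
    fragment.validate(START_YEAR, 2100)
    base = fragment.data.copy()

    clim_last = _monthly_means(base, 2091, 2100)
    rows = []
    if scenario == "rcp85":
        # per-month OLS slope over 2081-2100
        sel = base[(base["year"] >= 2081) & (base["year"] <= 2100)]
        slopes: dict[int, dict[str, float]] = {}
        for m, part in sel.groupby("month"):
            yrs = part["year"].to_numpy(dtype=float)
            slopes[int(m)] = {
                var: float(np.polyfit(yrs, part[var].to_numpy(dtype=float), 1)[0])
                for var in ("tmean", "precip")
            }
    for year in range(2101, END_YEAR + 1):
        co2 = co2_at(scenario, year)
        for m in range(1, 13):
            t0 = clim_last.loc[m, "tmean"]
            p0 = clim_last.loc[m, "precip"]
            par = clim_last.loc[m, "par"]
            if scenario == "rcp85":
                dy = min(year, 2250) - 2095.5  # trend anchored at 2091-2100 mean
                t = t0 + slopes[m]["tmean"] * dy
                p = max(0.0, p0 + slopes[m]["precip"] * dy)
            else:
                t, p = t0, p0
            rows.append(
                {"year": year, "month": m, "tmean": t, "precip": p, "par": par, "co2": co2}
            )
    out = pd.concat([base, pd.DataFrame(rows)], ignore_index=True)
    stream = ClimateStream(scenario=scenario, ecoregion_key=fragment.ecoregion_key, data=out)
    stream.validate()
    return stream


def build_scenario_stream(
    monthly_climatology: list[ClimateRecord],
    scenario: str,
    ecoregion_key: str = "default",
) -> ClimateStream:
    """Full 2010-2310 stream for any scenario from a monthly climatology."""
    if scenario == "baseline":
        return build_baseline_stream(monthly_climatology, ecoregion_key=ecoregion_key)
    frag = synthetic_rcp_fragment(monthly_climatology, scenario, ecoregion_key=ecoregion_key)
    return extend_rcp(frag)
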