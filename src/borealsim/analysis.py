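"""Post-processing of simulation output.

Scenario contrasts follow the delta convention
``delta[i, j] = S[i, j] - S[i, 0]``: the biomass-carbon series of management
scenario j under climate i minus the matching no-harvest series under the
same climate.  Cells are classified into ten composition labels built from
three species groups (black spruce | other conifers | broadleaves) plus an
OPEN label for empty cells, and into three age classes (young <= 40 yr,
mature 40-100 yr, old growth > 100 yr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Cell, stand_age

CLIMATE_INDEX = {"baseline": 1, "rcp26": 2, "rcp45": 3, "rcp85": 4}

FOREST_TYPES = (
    "BSPF", "OCPF", "BPF", "BSJP", "BSBF", "BSOC",
    "OCMF", "BMF", "BsBMF", "OCBMF", "OPEN",
)

#: Species-group membership used by the composition labels.
SPECIES_GROUPS: dict[str, str] = {
    "black_spruce": "bs",
    "jack_pine": "oc",
    "balsam_fir": "oc",
    "white_spruce": "oc",
    "larch": "oc",
    "white_birch": "bl",
    "trembling_aspen": "bl",
}

DEFAULT_PURITY_THRESHOLD = 0.75


@dataclass(frozen=True)
class ScenarioIndex:
    """(climate, management) pair: climate i in 1-4, management j in 0-6."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i not in (1, 2, 3, 4):
            raise ValueError("climate index must be 1-4")
        if self.j not in range(7):
            raise ValueError("management index must be 0-6")


@dataclass
class CarbonSeries:
    """Landscape biomass carbon (tC/ha) per 20-yr step for one scenario."""

    climate: str
    management: str  # S0..S6
    years: np.ndarray
    values: np.ndarray  # tC per ha

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must align")


def delta_series(mgmt: CarbonSeries, natural: CarbonSeries) -> CarbonSeries:
    """Pointwise difference of a management series against the same-climate
    no-harvest series; rejects mismatched climates or time grids."""
    if mgmt.climate != natural.climate:
        raise ValueError(
            f"climate mismatch: {mgmt.climate} vs {natural.climate}"
        )
    if natural.management != "S0":
        raise ValueError("reference series must be the no-harvest scenario S0")
    if not np.array_equal(mgmt.years, natural.years):
        raise ValueError("time grids differ")
    return CarbonSeries(
        climate=mgmt.climate,
        management=mgmt.management,
        years=mgmt.years.copy(),
        values=mgmt.values - natural.values,
    )


def group_shares(cell: Cell) -> dict[str, float]:
    """Biomass shares of the three species groups within a cell."""
    totals = {"bs": 0.0, "oc": 0.0, "bl": 0.0}
    for c in cell.cohorts:
        totals[SPECIES_GROUPS[c.species]] += c.biomass
    total = sum(totals.values())
    if total == 0:
        return totals
    return {k: v / total for k, v in totals.items()}


def classify_composition(
    shares: dict[str, float],
    oc_dominant_species: str | None = None,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> str:
    """Label a (bs, oc, bl) biomass-share composition.

    Rule table: an empty composition is OPEN; a group holding at least the
    purity threshold gives the pure class (BSPF / OCPF / BPF); otherwise the
    two largest groups decide, with ties broken in the fixed order bs > oc >
    bl.  A black spruce + other-conifer mixture is refined by the dominant
    other-conifer species (jack pine -> BSJP, balsam fir -> BSBF, else
    BSOC); other-conifer-led and broadleaf-led mixtures with each other's
    group give OCBMF and BMF respectively when conifer-led mixtures pair
    with black spruce (OCMF) or broadleaves.
    """
    if not 0.5 < purity_threshold <= 1.0:
        raise ValueError("purity threshold must lie in (0.5, 1]")
    total = shares.get("bs", 0.0) + shares.get("oc", 0.0) + shares.get("bl", 0.0)
    if total <= 0.0:
        return "OPEN"
    bs = shares.get("bs", 0.0) / total
    oc = shares.get("oc", 0.0) / total
    bl = shares.get("bl", 0.0) / total
    if bs >= purity_threshold:
        return "BSPF"
    if oc >= purity_threshold:
        return "OCPF"
    if bl >= purity_threshold:
        return "BPF"
    order = sorted(
        (("bs", bs), ("oc", oc), ("bl", bl)),
        key=lambda kv: (-kv[1], ("bs", "oc", "bl").index(kv[0])),
    )
    first, second = order[0][0], order[1][0]
    pair = {first, second}
    if pair == {"bs", "oc"}:
        if first == "oc":
            return "OCMF"
        if oc_dominant_species == "jack_pine":
            return "BSJP"
        if oc_dominant_species == "balsam_fir":
            return "BSBF"
        return "BSOC"
    if pair == {"bs", "bl"}:
        return "BsBMF"
    # {oc, bl}
    return "OCBMF" if first == "oc" else "BMF"


def classify_forest_type(
    cell: Cell, purity_threshold: float = DEFAULT_PURITY_THRESHOLD
) -> str:
    """Composition label of one cell (see :func:`classify_composition`)."""
    shares = group_shares(cell)
    oc_totals: dict[str, float] = {}
    for c in cell.cohorts:
        if SPECIES_GROUPS[c.species] == "oc":
            oc_totals[c.species] = oc_totals.get(c.species, 0.0) + c.biomass
    oc_dom = max(sorted(oc_totals), key=lambda sp: oc_totals[sp]) if oc_totals else None
    return classify_composition(shares, oc_dom, purity_threshold)


def age_class(age: float) -> str:
    """Young (<= 40), mature (40, 100], or old growth (> 100)."""
    if age < 0:
        raise ValueError("stand age must be >= 0")
    if age <= 40:
        return "young"
    if age <= 100:
        return "mature"
    return "old"


def composition_delta(
    mgmt_shares: dict[str, float], natural_shares: dict[str, float]
) -> dict[str, float]:
    """Per-class share differences (management minus natural); the
    differences sum to zero when both share vectors sum to the same total."""
    if set(mgmt_shares) != set(natural_shares):
        raise ValueError("share vectors must cover the same classes")
    return {k: mgmt_shares[k] - natural_shares[k] for k in mgmt_shares}


def landscape_type_shares(cells: list[Cell], purity_threshold: float = DEFAULT_PURITY_THRESHOLD) -> dict[str, float]:
    """Area-based forest-type shares over active cells (each cell one label)."""
    counts = dict.fromkeys(FOREST_TYPES, 0)
    n = 0
    for cell in cells:
        if not cell.active:
            continue
        counts[classify_forest_type(cell, purity_threshold)] += 1
        n += 1
    if n == 0:
        return {k: 0.0 for k in counts}
    return {k: v / n for k, v in counts.items()}


def landscape_age_shares(cells: list[Cell]) -> dict[str, float]:
    """Area-based age-class shares over active forested cells."""
    counts = {"young": 0, "mature": 0, "old": 0}
    n = 0
    for cell in cells:
        if not cell.active or not cell.cohorts:
            continue
        counts[age_class(stand_age(cell))] += 1
        n += 1
    if n == 0:
        return {k: 0.0 for k in counts}
    return {k: v / n for k, v in counts.items()}


def write_forest_type_map(path, landscape, purity_threshold: float = DEFAULT_PURITY_THRESHOLD) -> None:
    """Write the per-cell forest-type labels as an integer raster plus a
    label legend sidecar (``<path>.legend.tsv``)."""
    from . import io as bio

    codes = {label: i + 1 for i, label in enumerate(FOREST_TYPES)}
    grid = np.full((landscape.n_rows, landscape.n_cols), bio.NODATA, dtype=int)
    for cell in landscape.active_cells():
        grid[cell.row, cell.col] = codes[classify_forest_type(cell, purity_threshold)]
    bio.write_ascii_grid(path, grid)
    legend = pd.DataFrame(
        {"code": list(codes.values()), "forest_type": list(codes.keys())}
    )
    legend.to_csv(f"{path}.legend.tsv", sep="\t", index=False)


def summarize_run(
    series_frames: list[pd.DataFrame],
    value_cols: tuple[str, ...] = ("tC_per_ha",),
) -> pd.DataFrame:
    """Aggregate per-replicate tidy step tables into mean and range columns.

    Every input frame must share the same (step) key columns; a gap in any
    replicate's steps is an error.
    """
    if not series_frames:
        raise ValueError("no replicate frames supplied")
    keys = [c for c in series_frames[0].columns if c not in value_cols]
    ref = series_frames[0][keys].reset_index(drop=True)
    for frame in series_frames[1:]:
        if not frame[keys].reset_index(drop=True).equals(ref):
            raise ValueError("replicate frames cover different steps")
    stacked = pd.concat(
        [f.assign(_rep=i) for i, f in enumerate(series_frames)], ignore_index=True
    )
    agg = stacked.groupby(keys, sort=False)[list(value_cols)].agg(["mean", "min", "max"])
    agg.columns = ["_".join(col) for col in agg.columns]
    return agg.reset_index()
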