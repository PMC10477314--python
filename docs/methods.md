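# Methods

`borealsim` is a desk-scale, cohort-based forest landscape carbon model for
eastern-Canadian boreal management units. It couples a monthly, climate-driven
stand growth model with stochastic wildfire, windthrow, and spruce-budworm
(SBW) disturbance regimes and an annual harvest scheduler, and analyses
management scenarios as biomass-carbon differences against a no-harvest
baseline. This note records the model equations, the parameter choices that
matter, what the synthetic inputs do and do not emulate, and the numerical
conventions.

## Landscape representation

The landscape is a regular grid of 4-ha cells (200 m resolution). Each active
cell belongs to an ecoregion (one soil texture, one climate stream) and holds
a list of cohorts — all trees of one species in one 10-year age class, with a
single pooled above+below-ground biomass in Mg dry matter per cell. Inactive
cells (water, wetland, non-commercial cover) are never grown, disturbed, or
harvested. Biomass converts to carbon with a configurable fraction (default
0.5, the standard dry-biomass carbon content), reported as tC ha⁻¹ over the
active area. Stand age is the age of the oldest cohort. There is no sub-cell
spatial structure.

## Monthly growth

Growth runs on a monthly clock; demography (establishment, mortality, aging)
is annual; state is reported every 20 simulated years.

Per cohort *i* in a cell, potential gross production for a month is

    GPP_i = amax_i · F_i · f_T(t) · f_L(PAR_i) · f_C(CO2)

with `amax` the species' maximum net photosynthesis proxy (Mg assimilate per
Mg foliage per month), `F_i` foliage mass, and the modifiers:

- **Temperature** `f_T`: piecewise parabola, 0 at the species'
  photosynthesis limits `psn_tmin`/`psn_tmax`, 1 at `psn_topt`
  (`1 − ((t − topt)/(topt − tmin))²` below the optimum, mirrored above).
- **Light** `f_L`: Michaelis form `PAR_i/(PAR_i + half_sat)` on the PAR
  incident at the cohort's canopy layer. Layers stack tallest (oldest,
  largest) first and attenuate by Beer–Lambert extinction
  (`k = 0.5`) through each layer's leaf area; absorbed plus transmitted
  light equals the incident flux exactly.
- **CO₂** `f_C`: saturating logarithmic enhancement
  `1 + 0.30 · ln(CO2/389)`, normalized to 1 at the 389 ppm baseline.
- **Water**: transpiration demand is proportional to potential production
  (40 mm per Mg); a single-bucket soil water balance per cell (capacity from
  soil texture: clay 150 mm … sand 60 mm) supplies
  `min(demand, storage + precipitation)`, and each cohort's production is
  scaled by `(supplied/demand)^s` with a species water-stress sensitivity
  `s`.

Foliage is a fixed fraction (0.10) of cohort biomass, proportionally capped
at 8 Mg per cell so the leaf-area index saturates near 4.8 in closed stands.
Maintenance respiration is `maint_resp_frac · amax_i · F_i · f_T` — scaled by
temperature but not by light or water — so shaded or drought-stressed cohorts
run negative monthly balances. Net production adds to cohort biomass (floored
at zero); each negative month draws down a carbon reserve that any positive
month refills, and 24 consecutive negative months kill the cohort.
Respiration fractions fall with shade tolerance (0.22 for balsam fir to 0.30
for the intolerant pioneers), which sets each species' light compensation
point and lets tolerant understory persist where pioneers starve.

The defaults give open-grown saplings a relative growth rate near 10 %/yr
and closed stands an equilibrium around 150–250 Mg per cell (≈20–30 tC ha⁻¹)
under the packaged baseline climate, with an annual senescence (litterfall /
turnover) of 2.5 % of biomass.

## Annual demography

**Establishment.** A species can establish where a mature cohort (age ≥
sexual maturity) stands within its dispersal range: full kernel weight
within the effective distance, 0.15 out to the maximum distance (distances
rounded to grid cells; the home cell always counts). The annual probability
is `0.25 · kernel · f_shade · sqrt(soil water fraction)`, where `f_shade` is
a Michaelis form of forest-floor relative light against a half-saturation
that falls from 0.50 (shade tolerance 1) to 0.02 (tolerance 5). After a
fire, serotinous species present pre-fire establish with probability 0.8 and
resprouters with their sprouting probability, regardless of seed rain. New
cohorts enter the first age bin at 0.5 Mg.

**Background mortality.** Zero hazard through the first 80 % of the species
lifespan, then a quadratic ramp to 0.30 yr⁻¹, with certain death at the
longevity limit; stress death via the carbon reserve as above.

## Disturbance regimes

Order within a year: wind → fire → SBW → harvest (the ordering is a fixed
convention). Wind and SBW parameters carry no climate-scenario dimension;
only fire does — climate change reaches the other regimes indirectly through
composition and structure.

**Fire.** Per ecoregion and year, ignition counts are Poisson with rate
`ignition_rate × scaling(scenario, year)`; the scaling ramps linearly from 1
to an end-of-century multiplier (baseline 1, rcp26 1.8, rcp45 3.0,
rcp85 6.7 — the severe-scenario default pushes the packaged 0.15 %/yr
baseline burn rate toward ~1 %/yr by 2100). Fire sizes follow a lognormal
whose mean matches `size_mean` and whose 99th percentile sits at `size_max`,
truncated to `[size_min, size_max]`. Spread grows a connected patch from the
ignition, weighting frontier cells by `exp(k_fuel_age · tsf/200)` (time
since fire capped at 200 yr), and resets the burned cells' fire clocks. A
cohort dies when `severity − fire_tolerance` reaches its age-class offset:
−1 in the first 20 % of the lifespan (young cohorts are easier to kill), 0
otherwise; severity 5 kills everything. The packaged baseline regime
(ignition rate = 0.0015 × ecoregion cells / mean size 8) targets an annual
burned fraction of 0.15 %, inside the 0.04–0.26 % historical Quebec range;
truncation pulls realized sizes slightly below the nominal mean, so realized
rates sit near 0.15 % from below.

**Wind.** Expected disturbed fraction is 1/rotation per year: event counts
are Poisson with mean `n_cells/(rotation × 3)`, each event a small
contiguous patch (geometric size, mean 3 cells). Kill fractions rise with
relative age: 0.15 / 0.35 / 0.60 over the young / mid / old thirds of the
lifespan. The default rotation, 3922 yr, is the inverse of the 0.0255 %/yr
historical (1971–2000) disturbance rate.

**Spruce budworm.** Outbreak onsets recur with normal inter-onset intervals
(mean = the regional return interval, sd 6 yr, truncated to exceed the 8-yr
outbreak duration). During an outbreak, host cohorts lose a constant annual
fraction chosen so the compound loss equals the per-outbreak host mortality:
balsam fir 0.72 > white spruce 0.46 > black spruce 0.28 (inside the
literature's 42–50 % average stand-mortality envelope, with the fixed
vulnerability ordering). Non-hosts are untouched. The eastern unit (MU3)
uses the historical 32-yr return interval; the central and western templates
use longer stand-ins (40, 55 yr) since outbreaks recur fastest eastward.

## Harvest

Prescriptions: clear cut (CC, 100 % canopy removal intensity), CPRS (95 %
CRI, cohorts aged 1–20 conserved), and partial cuts PC75/PC50/PC25. Removal
is exact: the CRI fraction of eligible (unprotected) biomass, taken from the
oldest cohorts downward with a partial take at the boundary cohort. Stands
rank by the dominant species' economic value, ties broken by stand age
descending then grid index; stands below the dominant species' minimum
exploitable age are excluded, and a harvested stand is ineligible for 20
years. An annual area quota splits across the six treatment columns of the
scenario table (CC+regeneration, CC+reforestation, CPRS, PC75, PC50, PC25)
with fractional cell entitlements carried between years, so realized shares
track the configuration despite 4-ha granularity; unmet quota cells are
reported as shortfalls. Cells cut under CC+reforestation are replanted with
one species drawn from the historic mix (70 % black spruce, 25 % jack pine,
3 % larch, 2 % white spruce). Harvested biomass converts to merchantable
volume by species fractions (conifers 0.85, broadleaves 0.70 — configurable
stand-ins). The business-as-usual scenario (S2) shares are a configurable
stand-in dominated by CC systems (CC 25 % / CPRS 70 % / PC 5 %); any S2
table with CC+CPRS ≥ 90 % validates. Scenario rows printed as 99.9–100.2 %
are normalized.

Allowable-annual-cut calibration bisects the area quota until first-period
(default 20-yr) mean annual merchantable harvest is within 1 % of the
target, evaluated by a deterministic growth+harvest simulation under
baseline climate. Cell granularity can make the 1 % bracket unattainable on
small landscapes, and a landscape that cannot supply the target at any
quota returns the maximum feasible quota — both cases are flagged rather
than silently accepted. Calibration is assumed to target merchantable (not
total) biomass, since allowable cut is a merchantable-volume concept.

## Climate forcing

Streams are monthly per ecoregion, 2010–2310. The baseline repeats the
historic monthly climatology with CO₂ fixed at 389 ppm. Transient scenarios
are defined to 2100 and extended with explicit continuation rules: rcp26 and
rcp45 hold the 2091–2100 monthly climatology constant (concentration
stabilization), rcp85 continues its 2081–2100 per-month linear trends to
2250 and then plateaus. Whether the original extrapolation extended the
meteorology or only the concentrations is not documented anywhere we could
ground it, so these rules are declared stand-ins chosen for the simplest
monthly-resolved construction. CO₂ follows packaged decadal pathway tables
(to ~421/543/1962 ppm at stabilization for the three pathways). Synthetic
transient inputs for testing are baseline plus linear anomaly ramps (+1, +2,
+5 °C by 2100) with a 7 % precipitation increase.

## Synthetic inputs

The generator emulates the three management units' published structure: the
ecoregion area shares and soil textures per unit (rows printed as 99–101 %
are normalized), dominant initial age classes (20–40 yr in MU1, 120–200 yr
in MU2/MU3, ≥ 50 % of cells by construction at the 0.65 default), black
spruce dominance with bioclimatic-domain species pools, ~5 % inactive cells,
and monthly climatologies on the west-to-east precipitation gradient
(1000 → 800 mm, the wetter-west orientation being the documented choice) with
a ~2 °C offset between the southern fir–birch and northern spruce–moss
bands. Initial cohort biomass follows an age ramp saturating near 100 Mg per
cell. Trait values are plausible boreal stand-ins, not reproductions of any
calibrated set; conifer photosynthesis optima sit at 16–18 °C against 21–22 °C
for the broadleaved pioneers, so warming shifts composition toward birch and
aspen.

What the synthetic landscape does **not** emulate: the real spatial mosaic,
real climate extracts, absolute landscape sizes (default 2,500 cells =
10,000 ha versus 0.6–1.2 Mha), nutrient limitation, paludification, soil and
deadwood carbon, or harvested-wood-product accounting. Passing tests
therefore demonstrate regime-level and directional behaviour — mass balance,
regime recovery, scenario orderings — not absolute carbon stocks of any real
territory.

## Numerical conventions and determinism

- All stochastic components draw from independent child streams of one seed
  (wind, fire, SBW schedule, harvest). Establishment and mortality use
  counter-based streams keyed by (cell, year), so a local state change never
  shifts another cell's draws and matched-seed scenario contrasts stay
  paired. Identical seed and inputs give bit-identical outputs.
- Scenario contrasts pair replicate r of every scenario on seed
  `base_seed + r` over an identical initial landscape (a variance-reduction
  choice; the original design used unpaired replicates).
- Cohorts of one species merge within 10-yr age bins (biomass summed, older
  age kept); cohorts reduced below 0.01 Mg by partial kills are removed with
  the residual booked to the killing flux.
- The annual flux log closes exactly: biomass(t+1) = biomass(t) + applied
  net production − senescence − mortality − disturbance kill − harvest
  removal + recruitment, to accumulation rounding (≤ 1e-6 Mg absolute).
- Sub-annual ordering: 12 growth months, senescence, background mortality,
  wind, fire, SBW, harvest, establishment/reforestation, aging and bin
  merge, fire-clock increment.
- Months whose temperature modifier is zero for every species short-circuit
  to bucket recharge only; this is exactly the general step at zero demand.

## Problem sizes

Tests and the acceptance script run at desk scale by design: landscapes of
100–10,000 cells, horizons of 20–100 years for scenario contrasts (10 paired
replicates), and long thin simulations (800–5,000 years on static
landscapes) for disturbance-rate recovery. The default generator size is
2,500 cells; all claims are regime-level or directional at these sizes.

## Known limitations

- The growth engine is a simplified monthly canopy model; no numeric
  agreement with any full ecophysiological stand simulator is claimed.
- Even-aged initial stands senesce in synchronized waves at the longevity
  limit, a desk-scale artefact of the age-ramp initialization.
- Windthrow does not interact with partial-cut edges; regeneration failure
  to open woodland is not modelled; harvest ignores roads, costs, and
  adjacency.
- The AAC calibration's 1 % bracket is often unattainable below ~400 cells;
  the flag must be checked rather than the quota trusted blindly.
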