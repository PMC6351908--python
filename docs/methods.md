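# Methods

This note documents the models, parameter choices and numerical conventions
behind `lapmd`, and what the synthetic toy city does and does not emulate.

## Emission inventory

Emissions are tabulated per land-use source category and calendar year, in
two groups that are reported (and percentaged) separately: stationary
(point + area) sources and vehicle-based transportation sources.

* **Mass balance (SO₂ from fuel):** `E = 2 · S · ω · ε · (1 − η) · 10³` kg/yr.
  The factor 2 is the molecular ratio M(SO₂)/M(S) = 64/32. Defaults: sulfur
  conversion rate ε = 0.8 for coal and 1.0 for oil, configurable per fuel;
  desulfurization η = 0 for urban residential burning (no control equipment
  on household stoves), per-plot values for key industrial plots, treated as
  a category average where only an average is known.
* **Emission factors:** stationary `E[ton] = activity[ton] × EF[kg/ton] /
  10³`; traffic `E[kg] = P · M · EF[g/km] · 10⁻³` per vehicle class. Vehicle
  EF tables sometimes circulate with a "kg/ton" column header; the formula
  requires g/(km·vehicle) and that is the unit this package uses. The
  PM₁₀/SO₂ ratio identity `E_PM10/E_SO2 = EF_PM10/EF_SO2` is unit-independent
  and is used as a cross-check.
* **Shares** are kept at full precision internally and rounded (2 decimals
  by default) only in report tables. Group totals are exact row sums; where
  a published source table's printed total differs from its row sum in the
  last digit (the bundled 2010 transportation PM₁₀ table: rows sum to
  8805.23 t, printed 8805.24 t), the exact sum is reported.

**Rasterization** spreads each category's annual mass uniformly over the
cells carrying that land-use code: `q = E / n_cells`. Key plots can instead
be placed as explicit `(row, col, tonnage)` point sources; the placements
must sum to the category's inventoried emission (checked at 10⁻⁶ relative),
so rasterization conserves mass by construction. Roads are treated like
area sources over transportation-land cells — no per-road apportionment is
attempted. Where placements put more than one emitting category in a cell,
the cell's source height ΔH is the emission-weighted mean of the category
heights.

## Meteorology

* **Wind rose:** eight 45° sectors, sector 0 centred on north, clockwise.
  "Direction" is the direction the wind blows *from*; transport is toward
  the opposite bearing. A direction exactly on a sector boundary belongs to
  the lower-indexed sector. Days with speed < 0.5 m/s (configurable) are
  excluded as calm and reported as a calm fraction; frequencies are
  normalized over non-calm days and therefore sum to exactly 1. Per-sector
  mean speeds use sorted summation so the rose is exactly invariant under
  permutation of the input records.
* **Stability:** one Pasquill class per day from a documented lookup:
  insolation banded by the noon solar elevation (> 60° strong, 35–60°
  moderate, 15–35° slight, otherwise weak; computed from date and site
  latitude via the standard declination approximation when not supplied),
  downgraded one band when cloud cover exceeds 1/2; overcast (≥ 7/8) is
  neutral D regardless; the class then follows a speed × insolation table
  with stable E/F reserved for weak insolation at light winds. Each sector's
  representative class is the mode of its daily classes (ties break toward
  the more unstable class), giving the single σ-model per sector that a
  long-term average needs.
* **Dispersion parameters:** pure power laws σ = a·(x/1000)^b per class.
  σy uses the common 0.894 exponent; σz uses the standard power-law fits to
  the Pasquill–Gifford curves with their small additive offsets dropped, so
  both parameters are strictly positive and monotone for all x > 0 (the
  offsets matter only at sub-100 m ranges, below the model's resolution).
  The coefficient table is data, not code, and can be swapped per run.

## Dispersion model

Long-term, annual-average, multi-source. Assumptions: pollutants disperse
as Gaussian plumes smeared uniformly over each 45° sector (the
climatological sector-average approximation); the wind climate is stationary
within the year; no chemistry, deposition mechanics, plume rise or terrain
flow — only a scalar attenuation factor T per pollutant (default 1 = no
decay), configurable from the parameter file.

Numerical conventions:

* Distances are planar, between cell centres; the downwind distance is
  floored at `min_distance` (default: half the cell size).
* A source's own cell would have an undefined bearing; under the default
  `min_distance` rule it receives the frequency-weighted sum over all
  sectors evaluated at the distance floor (`zero` skips it instead).
* **Height convention** (default `absolute`): effective height = stack
  height ΔH + source ground elevation H above sea level, the model's native
  definition (a 30 m chimney at 200 m elevation has h = 230 m). This
  convention suppresses concentrations from elevated sources everywhere,
  including at receptors that are themselves elevated, so a `relative`
  option is provided (ΔH + H_source − H_receptor, floored at ΔH). Near sea
  level the two agree; the toy city is near sea level.
* Unit chain: ton/yr → g/s via 3.1536 × 10⁷ s/yr; output in mg/m³. All
  conversions live in `lapmd.units`.
* The crosswind-integrated flux identity `c · πxΔα/180 = Q/(2πūσyσz)·
  exp(−h²/2σz²)·T` holds to machine precision by construction and is exposed
  as a verification utility. The stronger claim that the field integrates
  back to Q over all space is *not* enforced: the discrete sector-uniform
  profile with T ≠ 1 cannot satisfy it, and the model is used comparatively
  (reference vs target), where the common normalization cancels.

The vectorized grid engine is verified against an independent brute-force
per-cell oracle (plain scalar loops re-deriving every receptor value) at
10⁻¹⁰ relative tolerance on grids up to 50×50.

## Assessment

Default level schemes: six levels per pollutant with edges
0.005/0.01/0.02/0.06/0.1 mg/m³ (SO₂) and 0.005/0.02/0.04/0.07/0.14 mg/m³
(PM₁₀); a 3-level scheme following the two ambient-standard limit values is
available as an alternative. Intervals are lower-closed — a value exactly on
an edge belongs to the higher level. Areas are cell counts × cell area,
reported in hm², and sum exactly to the grid (or category) total. Planning
polygons are rasterized by cell-centre containment (deterministic; later
polygons overwrite earlier ones where they overlap). Scenario comparison
reports per-level area change, mean change and the cellwise difference
raster; it judges nothing — interpretation of "environmentally friendly" is
left to the analyst.

## Toy city

The generator emulates the *structure* of a coastal, coal-burning,
mid-size-city assessment: a 40×40 grid at 300 m (the resolution at which
city-scale strategic assessments trade accuracy for coverage), an urban
core with four key plots (30 m stacks, per-plot coal 2–8 × 10⁵ t/yr, sulfur
content 0.6–1.2%, η = 0.6), residential and agricultural area sources with
literature-typical factors (e.g. crop residue: 0.4 kg SO₂/t, 10 kg PM₁₀/t;
rural residential PM₁₀ 3.74 kg/t), a nine-class vehicle fleet, a prevailing
easterly sector (35% of days), truncated-normal speeds (3.2 ± 1.4 m/s) and
Beta(2,2) cloud cover. The `target` scenario applies planning-style
adjustments to the same draws: industrial fuel × 0.7, straw burning × 0.1,
vehicle EFs × 0.6 with small-car/mini growth, urban growth, rural decline.

It does **not** emulate real geography, seasonal or diurnal meteorology,
monitoring data, or any particular city's magnitudes. Passing tests on the
toy city therefore demonstrate correctness of the arithmetic, conservation
properties, determinism and the engine/oracle agreement — not predictive
skill on real data, which depends on the quality of local inventories and
meteorology.

All generators are driven by `numpy.random.default_rng` seeded from a single
spec seed, so every layer is reproducible byte-for-byte; problem sizes used
in the bundled verification runs (40×40 toy grid, 30×30 and 50×50 oracle
grids, 365-day met year) were chosen as the smallest configurations that
exercise every code path at the model's native resolution.

## Known limitations

* Annual averages only; no episodic or hourly capability.
* The sector-average profile is discontinuous at sector boundaries —
  inherent to the climatological approximation.
* The absolute height convention couples ground elevation into the vertical
  term; use `relative` for terrain with meaningful relief.
* Emissions are uniform within a land-use class; within-class heterogeneity
  (e.g. traffic volume differences between roads) is not represented.
* The daily-resolution stability scheme cannot resolve the diurnal
  stable/unstable cycle; E/F classes stand in for the stable fraction of
  weak-insolation days.
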