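# Methods

## Model structure

The package computes an annual Ecoclimatic Index (EI) per location from
monthly climate normals. The chain is deterministic:

    monthly normals → 52-week series → PET → soil-moisture bucket
                   → TI, MI → GI_A → stresses → SI → EI = GI_A · SI

All weekly indices live in [0, 1]; GI_A and EI are scaled 0–100. The key
assumption inherited from climate-matching models of this family is that
climate alone limits distribution: no biotic interactions, dispersal,
soil type, land use or irrigation.

## Monthly-to-weekly interpolation

The year is 365 days cut into 52 equal weeks (365/52 d); there is no
short stub week, so stress accumulation sees 52 equal periods.

*Intensive* quantities (temperature, relative humidity) are interpolated
circularly: piecewise-linear through the 12 month-midpoint anchors
(standard month lengths), sampled at week midpoints. This preserves
constants and is linear in its input.

*Extensive* quantities (precipitation and PET, mm/month) are
redistributed by calendar overlap: week w receives
Σ_m total_m · overlap(week_w, month_m)/len(month_m). This was chosen over
interpolating a daily rate and rescaling because it is simultaneously
exactly mass-conserving (annual total preserved to rounding) and linear —
a post-hoc rescale would conserve but lose linearity, which the test
suite asserts as a structural property. The cost is a piecewise-constant
weekly rate within each month; for monthly normals feeding threshold
sums this resolution is appropriate.

## Potential evapotranspiration and the bucket

PET is Thornthwaite's temperature-only formulation: heat index
I = Σ_{T_m>0} (T_m/5)^1.514, exponent
a = 6.75e−7·I³ − 7.71e−5·I² + 1.792e−2·I + 0.49239,
PET_m = 16·(10·T_m/I)^a mm/month for T_m > 0, else 0; identically zero
when every month is at or below freezing. No day-length correction is
applied — at the precision of a trapezoidal moisture response driving
thresholds at 0.007–0.9 of bucket capacity, the latitude correction
changes little, and omitting it keeps the formula closed-form and
independently re-implementable in tests. Relative humidity is carried in
the data model (it is a standard input to this model family) but unused
by the default PET; the PET function is the single place to substitute a
humidity-aware formulation.

The bucket has capacity 100 mm (conventional soil-moisture storage for
this model family; configurable). Weekly recursion
S_w = clip(S_{w−1} + P_w − PET_w, 0, capacity), soil-moisture fraction
sm_w = S_w/capacity. The annual cycle is spun up from a half-full store,
looping the year with S_0 ← S_52 until |ΔS_0| < 1e−6 mm (at most 50
cycles — in practice 1–3 because the clipped recursion is contractive).
Starting half-full makes the knife-edge case P ≡ PET resolve to
mid-range moisture rather than an arbitrary bound. No runoff, drainage,
snow or irrigation is modelled.

## Growth indices

TI and MI are trapezoids over four thresholds with a closed-zero
convention: the response is exactly 0 *at* the limiting thresholds (x = a
or x = d) and degenerate equal thresholds act as step edges, the
limiting-threshold zero taking precedence. TI is evaluated on the weekly
mean temperature (Tmin_w + Tmax_w)/2 rather than a sub-weekly
temperature scheme: determinate, testable, and isolated behind
`temperature_index` if a day-degree variant is ever wanted.
GI_A = 100 · mean(TI_w · MI_w).

## Stresses

Each stress is linear: rate · Σ_w max(0, signed exceedance), clipped to
[0, 1]. Cold is driven by weekly Tmin below its threshold, heat by
weekly Tmax above, wet by sm above, dry by sm below (disabled for date
palm: rate 0). Rates are stored as non-negative magnitudes; the stress
kind fixes the direction, which removes sign conventions from the
arithmetic. The commercial engines in this family use an exponentially
ramping accumulation; with only a threshold and a weekly rate specified
per stress, linear accumulation is the minimal faithful reading, and the
two agree exactly on the decisive outcome (stress ≥ 1 ⇒ EI = 0).
Saturation is clipped at 1 rather than letting stress exceed 100%
internally; downstream EI is identical under either convention. Stress
components are reported to users ×100; internal arithmetic is [0, 1].
No stress-interaction terms.

## EI classification

EI = GI_A · SI. Class bands default to 0 / 10 / 20 (unsuitable exactly
at 0; marginal ≤ 10; suitable ≤ 20; highly suitable above), a common
convention in this literature; the bands are configurable and echoed
into output metadata. Classification is applied after rounding EI to
6 decimals so floating-point jitter cannot flip a boundary cell.

## Scenarios

Each GCM is reduced to two scalars at 2100 — a temperature offset
(+2.11 °C CS, +4.31 °C MR) and an annual-precipitation factor (0.86 CS,
0.99 MR) — interpolated linearly in time from the 2000 baseline for
intermediate horizons (2030/2050/2070), the minimal assumption given
only endpoint deltas. Application is spatially uniform: Tmin and Tmax
shift together (diurnal range preserved), precipitation scales, RH is
held constant. This deliberately stands in for gridded GCM anomaly
fields; the interface takes a whole grid so per-cell delta rasters are a
straightforward extension.

## Occurrence handling

Cleaning drops records missing either coordinate, drops out-of-range
coordinates (counted separately), then collapses duplicates — records
equal after rounding lat/lon to 4 decimal places (~11 m; configurable) —
keeping the first. Validation assigns each presence to its nearest grid
cell (ties to the lower index), excludes points outside the grid with a
warning, and reports the fraction on EI > 0 cells, mean EI at presence,
and omission at the marginal band. The fit score,
coverage − 0.5 · (suitable-area fraction), is a deliberately simple aid
to manual iterative parameter fitting, not an optimizer: it rewards
covering the presences with the smallest suitable footprint.

## Synthetic data

The generator emulates the *structure* of the study's inputs, not any
real field. Archetype stations are sinusoidal seasonal cycles around
fixed constants chosen so each archetype forces a known regime under the
date-palm parameters: hot_desert holds monthly means inside the 20–39 °C
optimum with scarce winter-peaked rain (moisture-limited but suitable);
cool_temperate never reaches the 14 °C limiting low (EI = 0 through the
temperature index); wet_tropical keeps the bucket above the 0.9 wet
threshold most weeks; mediterranean is intermediate. The synthetic world
is a lat/lon grid with annual mean 28 − 0.6·|lat| °C, seasonal amplitude
0.25·|lat| (phase-flipped between hemispheres), zonal precipitation
bands (wet equator, dry subtropics near |lat| 25°, moderate
mid-latitudes), and small seeded Gaussian noise (0.3 °C, 5% precip).
These constants make band edges computable: the warmest-month mean is
28 − 0.35·|lat|, so temperature-permitted range ends near |lat| 40°, and
a +ΔT warming moves that edge by ΔT/0.35 degrees at most. Occurrence
catalogues are importance-sampled ∝ EI over cells, jittered within the
cell, then contaminated with blanked coordinates and appended exact
duplicates at stated fractions.

What passing tests on this world do **not** show: realistic spatial
autocorrelation, orography, coastlines, observation bias in real
occurrence databases, or agreement with any published map. They show the
engine's arithmetic, invariants and monotonicities, and that the
analysis chain recovers structure it generated.

All randomness uses numpy's PCG64 `default_rng` with an explicit seed in
every API; there is no global random state.

## Numerical choices

- Bucket spin-up tolerance 1e−6 mm; growth/stress oracle agreement
  asserted to 1e−12 in tests.
- Annual precipitation conservation asserted to 1e−6 relative.
- Degenerate trapezoid thresholds: limiting-zero wins at exact
  threshold equality.
- Grid cells failing physical invariants (tmax < tmin, RH outside
  [0, 100], negative precipitation) are masked with a logged warning at
  read time rather than rejected.

## Known limitations

- No day-degree development, diapause, light index, stress
  interactions, or irrigation scenarios.
- PET ignores humidity and day length; arid-zone PET is likely
  underestimated at high latitudes in summer.
- Uniform scenario deltas cannot produce regionally heterogeneous
  change; gains/losses on the synthetic world reflect the generator's
  zonal structure only.
- The weekly series comes from normals, so interannual variability and
  extreme years are absent; stress thresholds act on the climatological
  mean cycle.
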