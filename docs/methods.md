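# Methods

`zevequity` chains six model stages into one deterministic pipeline that
quantifies how the air-quality benefits of zero-emission-vehicle (ZEV)
adoption are distributed between disadvantaged communities (DACs) and
non-DACs, and across racial/ethnic groups. This note records the models,
their assumptions, the tunable parameters, and the numerical choices.

## 1. Synthetic study region

The pipeline is exercised on a synthetic region rather than proprietary
registration, travel-demand and met archives. The generator
(`zevequity.region`) emulates the *statistical structure* those data sources
contribute, not any real geography:

- **Geometry.** A g × g grid of square tracts in planar meters (default
  400 tracts over 20 km × 20 km). No geographic projection is used;
  dispersion needs only planar distances.
- **Disadvantage gradient.** The pollution-burden score mixes a
  deterministic west-to-east ramp (weight `disadvantage_gradient`, default
  0.7) with i.i.d. uniform noise; at weight 0 the scores are spatially
  uncorrelated. The population-characteristics score is positively coupled
  to burden. Demographic fractions are Dirichlet-like draws whose means are
  tilted exponentially with burden (Hispanic and African-American shares up,
  White and AAPI shares down), mirroring the empirical coupling between
  disadvantage percentile and race/ethnicity in California.
- **Road network.** Arterials on every tract boundary edge (2 lanes) plus
  one vertical and one horizontal freeway corridor (4 lanes) through tract
  interiors, connected by ramps. With `truck_corridor_bias > 0` the
  corridors are aligned with the highest-burden column/row band, reproducing
  the tendency of truck routes to cross disadvantaged neighborhoods.
- **Fleet history.** Per tract × year (2015–2020) × technology
  (ICEV/PHEV/BEV) counts. Each tract's ZEV total follows a logistic curve
  whose 2015 level and growth rate decrease with burden percentile in
  proportion to `ownership_disparity`. The disparity acts mostly through
  the starting level with only a mild growth-rate gradient: a strong rate
  gradient would compound over a 15-year projection into an implausibly
  extreme 2035 disparity, whereas under near-uniform growth, logistic
  saturation plus the county rescale narrows *relative* disparity by the
  horizon — the pattern real adoption projections show. Baseline
  magnitudes put the county fleet ZEV share near 0.7% in 2015 and ~2.5% in
  2020 — the scale of the California light-duty fleet in those years. The
  BEV:PHEV split is fixed at 60:40.
- **Trips.** 50,000 daily trips by default: light-duty origins
  proportional to population, destinations by gravity kernel
  (attraction × exp(−d/6 km)), bimodal AM/PM departure-hour profile, class
  mix 94/4/2% LDV/MDV/HDV. Attraction is population tilted exponentially
  toward high-burden tracts — employment and industrial activity
  concentrate in disadvantaged corridors, which is what makes vehicles
  owned elsewhere drive through and into them (the intercommunity-trip
  mechanism behind eVMT shares tracking household shares far more closely
  than ownership shares). Truck origins *and* destinations use a stronger
  tilt scaled by `truck_corridor_bias` (freight depots sit in the
  disadvantaged band). Routes are static free-flow shortest paths; trucks
  additionally see arterial travel times inflated by
  `1 + 8·truck_corridor_bias` so they concentrate on the freeway
  corridors. There is no congestion feedback: route choice is an input to
  the equity analysis, not its subject.
- **Meteorology.** `met_days` days (default 2) in each of January, April,
  July and October. Wind speeds are lognormal with month-specific
  parameters, floored at 0.5 m/s; directions are month-prevailing with
  Gaussian spread; Pasquill stability classes are drawn from a fixed
  hour-of-day table (stable E/F at night, unstable A–C midday) with a
  summer midday instability boost. The table is module-level configuration.
- **Emission rates.** EMFAC-like magnitudes per pollutant (PM2.5, NOx,
  CO2) × fine category (two per weight class) × process. ZEV rows are zero
  for running/start/idling and identical to ICEV for brake/tire wear.

Every artifact is a pure function of `RegionSpec.seed`; independent
generator stages draw from independently seeded streams so regenerating one
artifact never perturbs another.

What the generator does **not** emulate: calibrated demand magnitudes,
congestion-equilibrium route choice, street-level geometry, real
meteorological sequences, or speed/temperature-dependent emission rates.
Passing tests therefore demonstrate correctness of the *methods* and the
robustness of the directional equity findings under the configured
couplings — not calibrated concentration magnitudes for any real county.
Simulated concentrations are two to three orders of magnitude below urban
observations simply because the synthetic trip table is (deliberately)
orders of magnitude smaller than a real county's.

## 2. DAC designation

Overall tract score = pollution burden × population characteristics,
expressed as an average-rank percentile across scored tracts. A tract is a
DAC when its percentile is strictly above 100·(1 − 0.25), or when it lacks
a population-characteristics score and its burden alone ranks in the top
5%. Strict inequality makes "top 25%" exact under distinct scores (n = 100
distinct scores → exactly 25 DACs). Legacy and tribal-land designation
categories have no synthetic analogue and are not modeled.

## 3. Adoption curves and projection

Ownership equity is summarized with Lorenz (concentration) curves:
cumulative vehicle ownership against cumulative population with tracts
ordered from most to least disadvantaged, plus the ordinate at the top-25%
abscissa and a concentration index 1 − 2·AUC (positive = disadvantaged own
less).

Projection uses the logistic growth model

    N(t) = K / (1 + ((K − N0)/N0) e^(−r t)),  t in years since 2015.

Per-tract choices, where the underlying design space was genuinely open:

- **K** is the tract's total light-duty fleet (saturation = full
  electrification of the tract fleet).
- **N0** is the first nonzero observation; an all-zero history gets a
  0.5-vehicle pseudo-count and a `no_adoption` flag, keeping the curve
  defined while pinning projections near zero.
- **r** is fit by least squares on the count scale (counts are small and
  zero-inflated; a log scale would overweight early years) via bounded
  scalar minimization on r ∈ [1e-4, 5] with xatol 1e-12.

Projected 2035 counts are rescaled by a single county factor to a 50%
light-duty fleet penetration; tracts pushed past their fleet are capped and
the shortfall is redistributed proportionally among uncapped tracts until
the county ratio converges to 1e-9.

## 4. Trip assignment

For each origin tract with LDV ownership fraction p and n LDV trips,
exactly round(p·n) trips are flagged ZEV, drawn uniformly without
replacement (exact-count sampling matches the tract proportion and removes
one variance source relative to per-trip Bernoulli flags). Medium- and
heavy-duty trips are flagged at county-level fractions, since tract-level
truck ownership does not exist. ICEVs and ZEVs are assumed to drive
identical miles. Each trip contributes `expansion_factor` vehicles to every
route link in its departure hour (default 1: the synthetic demand is not a
population sample; set 10 for a 10% sample). A truck counts as 3.5
passenger cars in PCE volume. eVMT attributes each route link's mileage to
the tract containing the link midpoint (half-open-cell rule for boundary
midpoints).

## 5. Emissions

Fine-category rates collapse to weight-class rates by fleet-share
weighting: ER_class = Σ_k ER_cat(k)·VP(k). Four processes: running exhaust
and brake/tire wear scale with VMT; start exhaust is charged on the first
route link at the departure hour; idling (default 1 minute, configurable —
no empirical anchor) on the last link. With-ZEV scenarios zero the three
tailpipe processes for flagged vehicles but keep full brake/tire wear;
PHEVs are treated as zero-tailpipe, matching the binary ICEV/ZEV flagging.
The without-ZEV baseline treats the entire fleet as combustion. Annual
totals scale the typical-day grams by 365 and convert to metric tons,
grouped by the DAC flag of each link's tract. CO2 is carried through the
inventory and annual totals but not dispersed.

## 6. Dispersion

Steady-state Gaussian line sources with total ground reflection; plume
spreads follow Briggs open-country curves by Pasquill class (A–F). The
class-curve approach replaces surface-energy-balance met preprocessing
while preserving the steady-state Gaussian structure; the curve table is
config-exposed. Parameters:

| parameter | default | meaning |
|---|---|---|
| release height H | 0.5 m | near-ground vehicle exhaust |
| receptor height | 1.5 m | breathing height |
| lane width | 3.75 m | lane sub-line offset for multi-lane links |
| cutoff | 1,500 m | receptor–segment distance beyond which contribution is exactly zero |
| wind floor | 0.5 m/s | Gaussian kernel diverges as u → 0 |

Each link becomes `lanes` parallel sub-lines carrying 1/lanes of the
emissions. The line integral uses adaptive trapezoid refinement: node count
doubles (from 8) until successive estimates agree to 0.1% relative or
1e-6 µg/m³ absolute, erroring at 2^16 nodes. `transfer_matrix` runs the
same refinement vectorized over all in-range (sub-line, receptor) pairs per
met hour and stores concentrations per unit line strength; actual fields
are transfer × per-pollutant emission strength, exact by linearity, and the
matrix is reused across all scenarios and replicates of a region.

Receptors sit at tract centroids (one per tract in the synthetic region,
standing in for block-group centroids). Hourly fields average to daily,
then to the annual average daily concentration over all simulated days;
tract exposure is the mean over the tract's receptors. NOx is reported as
NO2-equivalent ppb (× 24.45/46.01 at 25 °C, 1 atm — a stated convention,
since mass-to-mixing-ratio conversion is otherwise ambiguous). No
chemistry, deposition, meander, downwash, or background concentrations:
all reported exposures are traffic-attributable primary concentrations.

## 7. Equity report

DAC vs non-DAC shares of households, ZEV ownership and eVMT; geometric-mean
(q25–q75) exposures per scenario (geometric means exclude exact zeros, with
the count logged, rather than adding an arbitrary pseudo-concentration);
absolute and relative reductions (reduction ÷ no-ZEV baseline, %); and the
benefit gap 100·(rel_nonDAC − rel_DAC)/rel_nonDAC — positive when DACs
receive relatively less benefit. "More absolute reduction" and "fewer
relative benefits" are deliberately distinct metrics: both are computed and
labeled, because with higher DAC baselines both can hold at once. Racial
apportionment weights each tract quantity by its demographic fractions.
Robustness checks: a paired t-test on with/without tract exposures
(flagged degenerate when all differences are zero, e.g. the null scenario)
and Pearson correlations of tract-level reductions between the first and
each repeated random trip selection, computed within DAC and non-DAC
subsets.

## 8. Problem sizes and determinism

The reference configuration used throughout the tests and the acceptance
script is 400 tracts, ~960 links, 50,000 trips, 8 met days (2 per sampled
month, 192 hours) and one receptor per tract, chosen so a full two-scenario
study completes in about a minute per seed on a single core while retaining
enough tracts per group (≈100 DAC / 300 non-DAC) for stable group
statistics. Directional findings (higher DAC baseline exposure, ≥ absolute
DAC reduction, lower DAC relative reduction, narrowing gap at the horizon)
are asserted by majority over 10 region seeds rather than per-seed, since
individual realizations can break ties.

All randomness flows from explicit seeds (region seed; assignment seed;
replicate seeds are consecutive offsets). Reruns with identical
configuration produce byte-identical artifacts and reports; the run
manifest records config hash and output checksums to make this checkable.

## 9. Known limitations

- Static free-flow routing; no congestion equilibrium or induced demand.
- One departure-hour attribution per trip; no within-trip time propagation.
- Briggs class curves are coarser than Monin–Obukhov-based plume spreads;
  near-calm hours are handled by the wind floor rather than meander.
- Single receptor per tract makes tract exposure equal to its centroid
  value; fine intra-tract gradients are unresolved.
- Emission magnitudes are representative, not calibrated; absolute tons and
  concentrations should be read as internally consistent model units.
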