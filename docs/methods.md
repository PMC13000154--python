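# Methods

This note documents the statistical model behind `shatterscan`, the choices
made where several defensible conventions exist, and what the synthetic
ensembles do and do not establish about real climate-model output.

## Drought definition and area series

A grid cell is under drought in a year when its annual surface soil moisture
falls **strictly below** the local percentile threshold (default p = 20) of
the sample pooled over all ensemble members and all reference years
(default 1850–1899). "Falls below" motivates the strict inequality: values
exactly at the threshold — possible in integer-valued test fixtures — are
not drought. The percentile estimator is linear interpolation between order
statistics (numpy's default, "type 7"); it is continuous in the data and
reproducible across platforms. On the reference sample itself the per-cell
drought frequency is therefore ≈ p% up to estimator discreteness, and on
stationary synthetic data the expected drought area is ≈ p% in every year —
both are asserted by tests.

Drought area is an **area-weighted** percentage: cell weights are
proportional to true spherical cell area (sin-latitude bound differences,
i.e. cos-latitude for narrow bands). Whether the underlying study weighted
cells by area or counted them equally is not derivable from its text; area
weighting is the physically natural reading of "fraction of area", and an
`equal_cell_weights` switch is provided. Regional series can be expressed
relative to the region's own area or to the total breadbasket area; in the
latter convention the six regional series sum exactly to the global series.

Drought intensity is the area-weighted mean of `(x − μ₀)/σ₀` over drought
cells, with μ₀ and σ₀ from the same pooled preindustrial sample as the
threshold. Years with no drought cells yield a missing value (not zero);
a drought cell with σ₀ = 0 is a hard error because the standardization is
undefined there.

## Record statistics

Within each member, the running maximum of the drought-area series is
initialized at the first tracked year, which can never itself be an event —
a "previous record" must exist. A year is record-breaking when it strictly
exceeds the running maximum, and record-shattering when it exceeds it by at
least the margin (default 5 percentage points of the scope's area, compared
with ≥; sensitivity margins 2.5 and 7.5 behave monotonically: event sets are
nested as the margin grows, a property the suite checks exactly on
thousands of random series). The running maximum updates whenever a year
exceeds it, event or not. Records are tracked from 1850 even when
probabilities are only reported later, so "previous maximum" always refers
to the whole record.

For iid continuous series the probability of a record-breaking year at
tracking year *n* is 1/*n*, and the expected number of records over *N*
years is Σ_{n=2..N} 1/n ≈ 5.10 for N = 250. The margin-0 detector
reproduces both on simulated iid series within Monte-Carlo standard errors;
this closed-form law is the package's strongest external oracle.

Annual probabilities divide event counts in a 31-year window (±15 years) by
`31 × members`. By default only center years whose full window lies inside
the data span are reported (1865–2084 for 1850–2099 data); a truncated-edge
mode divides by the actual window-years × members instead, because plotted
probability curves conventionally extend past the last full-window center.
Period probabilities (e.g. 2026–2055, 2026–2099) are the fraction of
members with at least one in-period event; multi-model summaries are the
unweighted mean over per-model values plus the min–max inter-model range.

## Detrending experiments

Pooled moving statistics are computed per cell from all members jointly
inside 31-year windows. At the series edges windows are clipped to the data
span (shrinking to a minimum of 16 years) rather than leaving edge years
untransformed — this keeps the full 1850–2099 record usable; a
"full windows only" analysis can simply discard the outer 15 years. The
implementation uses centered cumulative sums and matches a per-window loop
oracle to float precision. The pooled SD uses the sample (n−1) convention,
as do all SDs in the package.

The three experiments (detrend mean / SD / both, formulas in the README)
re-anchor the pooled moments at the preindustrial values μ₀, σ₀ computed
from the same pool as the drought baseline. Two caveats are deliberate and
documented rather than hidden:

* SD-detrending preserves the **mean evolution**, not the per-window pooled
  mean to machine precision: the per-year moving mean is added back, but a
  recomputed window mean mixes neighboring windows and retains a rescaled
  anomaly term of order σ₀/√(members·window). Tests assert preservation at
  that noise scale.
* `detrend_both` is idempotent only up to window re-estimation noise; the
  suite bounds the change of a second application.

A moving SD at or below 1e-12·σ₀ raises an error naming the year and cell
(noise-free constant fixtures trigger it) instead of silently inflating
anomalies.

After any detrending experiment, drought thresholds are refit on the
transformed series' own preindustrial pool. Since detrending pins 1850–1899
to the preindustrial moments, this is nearly identical to reusing original
thresholds, but it keeps every experiment self-consistent ("recompute the
probability from the modified series"); reusing the original baseline
remains possible by passing it explicitly.

Change decomposition: Δarea = mean(future period) − mean(1850–1899),
computed per member, averaged per model, then summarized across models. The
mean-trend contribution is the Δ that survives the *detrend SD* experiment
(which removes variability change only); the variability contribution is
the Δ surviving *detrend mean*. The contributions are not forced to add up
to the original Δ — record statistics and percentile thresholds are
nonlinear — and the detrend-both Δ is ≈ 0 by construction.

## Leave-one-region attribution

A region's trend contribution is P(≥1 global record-shattering event) under
"keep this region's series, detrend-both everywhere else" minus the same
probability under detrend-all. Cells outside every breadbasket are never
touched (they never enter area computations). Contributions of different
regions need not sum to the original-minus-stationary gap; tests assert only
sign and magnitude patterns on ensembles of known construction: drying
regions carry essentially all of the probability excess, stationary regions
≈ 0, and a wetting region can contribute slightly negatively.

## Coincidence analysis

Global record-shattering events in 2000–2099 (the full century, for sample
size) are partitioned by the number of regions simultaneously flagged in the
same member-year: "0 regions", one-region categories (Europe only / USA
only / Brazil only / "Rest only" = Argentina, China or India alone),
"2 regions" … "6 regions". The categories are mutually exclusive and the
fractions sum to 100% by construction (asserted to machine precision).
Regional flags are either regional record-shattering events
(regional-denominator series, 5-point regional margin — switchable, since
the denominator convention for the regional flags is not pinned down by the
study text) or *moderately extreme* droughts: regional area strictly above
the 80th percentile of the member's own trailing 31 years (Y−30..Y, current
year included in its own reference pool, exactly as defined). The ±15-year
association uses global events in 2000–2085 so the full window fits the
study period.

## Synthetic ensembles

The generator produces
`x(m,y,c) = μ_b(c) + τ_r(y) + s_r(y)·σ_b(c)·ε(m,y,c)` with per-region mean
offset τ and SD multiplier s (zero/one outside regions), and ε a zero-mean
unit-variance Gaussian process: exponential spatial correlation in
great-circle-approximated degree distance (default e-folding 5°), AR(1) in
time (default φ = 0.3) applied to the spatially correlated innovations
before trend/scale injection with a stationary start, so the marginal
variance is 1 in every year. Soil moisture is not floored at zero: drought
classification is percentile-based, so absolute units are immaterial.
Member streams are derived from `SeedSequence((seed, member))`, so
enlarging the ensemble never reshuffles existing members, and identical
(config, seed) pairs are bit-identical.

Defaults of the demo scenario (the package's standing study conditions):
1850–2099, baseline mean 30 and SD 2 (soil-moisture units, ~kg m⁻² scale),
12×24 grid between 60°S–60°N with six box regions at roughly the real
breadbaskets' latitudes, drying of −0.025 units yr⁻¹ from 2000 in USA,
Brazil and Europe (≈1.25 σ_b by 2099, a strong but scenario-plausible
forced signal), SD multiplier rising to ≈1.2 by 2099 in the USA, and three
"models" differing only by member count (n±5) and noise stream. Real
soil-moisture fields add seasonality, land–sea asymmetry, non-Gaussian
tails, regionally varying persistence and inter-model structural
differences that this emulator does not represent: passing tests establish
the *statistical machinery* (thresholds, records, detrending algebra,
attribution logic), not the realism of any particular CMIP6 model. The
study's published headline numbers come from multi-terabyte CMIP6 SMILEs
and are not reproducible at this scale; the desk-scale scenario reproduces
their qualitative structure (probability amplification of order ten,
mean-trend dominance, drying-region attribution asymmetry).

## Numerical and interface choices

* Annual means of monthly input use equal month weights (the "average over
  each calendar year" is not stated as day-weighted); incomplete years are
  an error naming the year.
* Conservative regridding factors rectilinear overlaps into sin-latitude ×
  longitude interval intersections; a constant field is reproduced exactly
  and the global area-weighted mean is conserved where the destination
  covers the source. Masks regrid by the ≥50% area-overlap rule.
* Longitudes are normalized to [−180, 180); all year ranges are inclusive
  on both ends; NetCDF I/O is NetCDF3 via xarray's scipy backend.
* Evaluation diagnostics (1980–2009 baseline, 1980–2024 window) apply no
  detrending, use per-member OLS trends scaled to % per decade with the
  member SD as the model-level spread, and are invariant to adding a
  constant to all soil-moisture values.

## Known limitations

* Regridding assumes rectilinear lat/lon grids; curvilinear ocean-model
  grids are out of scope.
* No calendar handling beyond "one value per year" (monthly input must be
  complete calendar years); no 360-day/noleap conversions.
* The coincidence partition requires at least one global event in the
  analysis period and reports an explicit error otherwise rather than NaN
  fractions.
* Attribution probabilities are step functions of 1/members; with small
  demo ensembles, contributions of trend-free regions fluctuate at that
  granularity, which is why multi-seed averages are used when asserting the
  drying/stationary asymmetry.
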