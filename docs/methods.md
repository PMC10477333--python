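# Methods

`cropcarb` quantifies how much climate-smart cropland practices — winter
cover crops, conservation tillage, hay/pasture rotations, manure
amendments, and set-aside of cropland into grass — have contributed to
national soil organic carbon (SOC) stock changes in the top 30 cm of
mineral soil, and propagates three sources of uncertainty into the annual
national estimates. Because the survey microdata such an assessment rests
on are confidential, the package ships a synthetic-data module that
generates every input with the statistical structure the analysis assumes;
all quantitative claims the tests make are therefore claims about that
synthetic world, not about any real inventory.

## The surrogate soil carbon model

The simulator is a three-pool (active / slow / passive) first-order
decomposition model in the CENTURY tradition, run on a daily step with a
365-day calendar. Pool *i* loses carbon at rate

    k_i * m_T * m_W * m_till     (m_till on the active and slow pools only)

with temperature response `m_T = q10^((T − T_ref)/10)` capped at `t_cap`,
moisture response `m_W = w/(w + w_half)` on the bucket-model relative
water `w ∈ [0,1]`, and tillage multipliers NT = 1.00, RT = 1.15,
FT = 1.30. The decayed flux splits into respiration (0.55 for every pool)
and transfers whose clay dependence follows the CENTURY pattern
(active→passive `0.004 + 0.03·clay`, slow→passive `0.003 + 0.009·clay`,
remainders to slow / back to active). Crop-derived inputs enter the active
pool. Carbon is conserved exactly at every step: Δtotal = inputs −
respiration to 1e−9 relative, which the tests verify on random states.

Defaults: `k_active = 7.3`, `k_slow = 0.2`, `k_passive = 0.0045` yr⁻¹;
`q10 = 2`, `T_ref = 20 °C`, cap 2.0; `w_half = 0.3`. Annual C inputs
(t C ha⁻¹ yr⁻¹): corn 3.8, soybean 2.2, wheat 2.8, hay 3.2, pasture 3.0,
grass 4.2 (perennials allocate heavily below ground, which is why retired
land is a sink), cover-crop winter addition 0.8 spread over a 120-day
window, manure C from manure N at C:N = 15. Annual-crop inputs respond to
available N with a saturating multiplier (35 % of the input modulated,
half-saturation 60 kg N ha⁻¹); perennial inputs are flat. When a remotely
sensed production signal is available, a per-location-year multiplier —
the growing-season mean of the gap-filled daily index
(`growing_season_index`, Savitzky–Golay-style local polynomial fill of
~8-day observations) — scales annual-crop inputs instead; the synthetic
world uses the per-crop defaults. This simulator
is an explicitly pluggable surrogate: the pipeline only consumes annual
Dec-31 stocks, so a richer daily ecosystem model could stand behind the
same interface.

**Equilibrium.** Initial pools are the exact fixed point of the daily
affine update `x' = Mx + u` under climatological mean modifiers and native
grass inputs, solved analytically from `(I − M)x = u`. The brute-force
oracle iterates the identical daily map (composed exactly into one-year
matrices) for 6000 years; analytic and iterated states agree to < 0.5 %
under temperate forcing. Under extreme cold/dry forcing the passive pool's
e-folding time exceeds 6000 years and *no* finite spin-up converges — the
acceptance test draws are restricted accordingly.

**Staged history.** After equilibrium under native vegetation, each
location runs low-input agriculture (inputs scaled by 0.5, full tillage)
from 1910 to 1949 on the weather climatology, a linear productivity ramp
(0.5 → 1.0) from 1950 to 1978, then survey-driven management 1979–2015 on
generated daily weather. Annual stocks are reported for 1979–2015 and the
assessment window is 1995–2015. Cover crops terminated by tillage incur a
30-day full-tillage decomposition pulse in spring; herbicide termination
does not.

## The synthetic survey world

* **Frame** — n locations clustered around regional stratum centres on a
  planar km domain (no geographic projections). Lognormal expansion
  weights are rescaled to the configured national cropland area
  (125.4 Mha by default). Replicate weights are a delete-a-group jackknife
  with G = 30 balanced groups (locations dealt to groups in weight order);
  the variance estimator uses the multiplier (G−1)/G. The real survey's
  proprietary replicate scheme is not public; the jackknife is the
  standard stand-in for a two-stage design and its variance is verified
  against the closed-form variance of a weighted iid total (within 20 %).
* **Weather** — sinusoidal seasonal temperature plus AR(1) daily noise
  (ρ = 0.7, σ = 3 °C), two-state wet/dry occurrence chain (stationary wet
  probability 0.3) with exponential intensities matched to the regional
  normal, and a single-bucket water balance (capacity 100 mm, PET linear
  in temperature) yielding the relative-moisture series the decomposition
  modifier consumes.
* **Management truth** — per-practice national adoption trends are
  piecewise-linear curves; the defaults encode the study conditions:
  cover crops zero before 1990 ramping to ~3 % of cropland by 2015,
  conservation tillage rising (faster after 2000) to ~40 %, hay/pasture
  rotation area roughly halving, manure area flat at ~3.6 %, set-aside
  peaking in the early 1990s (~8 %) and declining to ~3.5 %. Locations
  adopt via persistent uniforms (location adopts in year y iff its fixed
  draw < curve(y)), which matches the weighted national curve in
  expectation while keeping individual sequences persistent — CRP-style
  contiguous enrollment, rare tillage switches.
* **Donors and calibration sites** — donors are anchor-period (2001–2005)
  records sampled from the truth with lognormal observation noise on N
  rates, stratified so every (region × crop group × texture class) stratum
  is covered. Calibration sites pair surrogate-simulated equilibrium SOC
  under treatment contrasts with "measured" values generated as
  `intercept + slope·simulated + site_effect + noise`, so the bias-model
  fit has a known truth to recover.

What the generator does **not** emulate: spatial autocorrelation of soils
and weather beyond regional strata, measurement error in the survey frame
itself, crop rotations responding to prices, or any real-data marginals.
Passing tests therefore demonstrate the *machinery* — imputation tracks
known trends, uncertainty propagation is calibrated, counterfactual
attribution recovers known contrasts — not agreement with any real
inventory.

## Calibration

A Sobol total-order screen (Saltelli A/B/AB design, Jansen estimator,
written in-package) ranks surrogate parameters; parameters with total
index > 0.025 are flagged for calibration, mirroring a 17-candidate /
9-selected screen. Sampling importance resampling weights prior draws by a
Gaussian likelihood (log-sum-exp stabilised), resamples with replacement,
and reports the highest-weight resampled particle as the MAP estimate plus
the effective sample size 1/Σw².

The empirical bias model is a REML linear mixed-effects fit
(`statsmodels` MixedLM) of measured on simulated SOC with a region random
intercept and a site variance component (site nested in region); it falls
back to a site-only random intercept — and ultimately to OLS for
perfectly collinear zero-noise data — when the two-level fit is not
identifiable. Covariates beyond simulated SOC are configurable and default
to none.

## Imputation

Six independently seeded sets (M = 6) of complete management histories
carry input-data uncertainty. Cropping, irrigation and set-aside are
treated as survey-observed; tillage, N inputs and cover crops are imputed:

* **Tillage** — trend series over blocks {1980–1985, 1986–1990, …,
  2011–2015} (the first block absorbs 1979; six years, because the blocks
  must align with the 2001–2005 hot-deck anchor). Two donor series are
  spliced by per-class OLS over their overlap, clamped, renormalised and
  gap-filled linearly. The anchor block is hot-decked within
  region × crop-group × texture strata; other blocks are sampled through
  chained **maximal-stay couplings**: the joint mass puts min(pᵢ, qᵢ) on
  the diagonal — provably the largest stay mass any coupling admits, which
  the tests confirm against a linear-program oracle — and spreads the
  residual by the northwest-corner rule in fixed state order NT < RT < FT,
  making the off-diagonal pattern deterministic and the tests exact.
  `p·T = q` holds to 1e−12 by construction.
* **N inputs** — predict-then-match: a configurable predictor (default:
  linear regression on clay and crop-group dummies) is trained on donors;
  each location receives the *observed* rates of the donor whose own
  prediction is nearest (ties to the lowest donor id), so imputed values
  never leave the donor support. Regional year multipliers scale the base
  rate into the annual series.
* **Cover crops** — anchor hot-deck from regional donor rates; backward
  ramp thins adopters with persistent uniforms so expected adoption falls
  linearly to exactly zero in 1990; post-2005 blocks add/remove adopters
  to match census-style targets. Termination practice is unobservable in
  the sources, so it is a scenario axis: every cover-crop result is
  produced under both tillage and herbicide termination.

## Counterfactuals and attribution

Each scenario edits exactly one practice over the full 1979–2015 record
(extending edits to 1979 avoids artificial stock trends an abrupt 1995
switch would create): cover crops removed; NT/RT converted to FT on
cultivated land (set-aside keeps its NT — its absence of tillage belongs
to the set-aside practice, which is attributed directly); hay/pasture
years replaced by annual crops sampled from those grown at the same
location (region-modal crop when there are none); manure N moved into
synthetic fertiliser so plant-available N is unchanged while manure carbon
disappears. The practice effect is the difference in *annual stock
changes* (not stock levels, which would accumulate), baseline minus
counterfactual, reported 1995–2015. Set-aside is attributed directly from
the baseline stock change on enrolled years, since retired land carries no
concurrent practice. Locations whose edited history is identical to the
baseline are not re-simulated; their effect is exactly zero, which makes
the zero-effect guarantee structural rather than numerical. Effects are
not forced to add up to the total — interactions exist — and the residual
"all other management" series is reported explicitly.

## Uncertainty propagation

Simulations are run once per imputation set and cached; each of the 1000
Monte Carlo iterations then draws independently (i) an imputation set,
uniform over M; (ii) a fixed-effect vector from Normal(β, cov β) plus
prediction-error draws; (iii) a replicate-weight vector, uniform over G.
The bias slope is applied to annual stocks *before* differencing (the
order is switchable); because the site and region random effects are
persistent for a location, they cancel exactly in the stock differences,
and only the residual component (σ_resid) contributes per-location-year
noise, drawn on the stock scale and differenced. Estimates are the mean,
s.d. and 2.5/97.5 percentiles across iterations; when every draw is
bit-identical (all sources degenerate) the dispersion is reported as
exactly zero rather than epsilon-level rounding noise.

A scaled-down consequence worth knowing: with 500 synthetic locations
standing in for ~171,000 real ones, the scaling component of the variance
is ~19× larger than it would be at full survey size, so the national
confidence intervals the default configuration prints are much wider,
relative to the means, than a full-size assessment would produce. The
means are unaffected.

## Mapping

Per-location mean 1995–2015 effects are interpolated to a 5 km planar grid
by inverse distance weighting: weights d⁻² over points within 20 km of the
cell centroid, at least 5 supporting points or the cell is null, and a
point within 1 m of the centroid short-circuits to its own value. The
exponent is configurable (the method's sources rarely state one; 2 is the
common default). Grids are written as ESRI ASCII rasters with a metadata
sidecar.

## Problem sizes and numerical choices

Defaults: 500 locations, G = 30 replicates, M = 6 imputations, 1000 MC
iterations — a full run takes under a minute on one CPU. The test suite
uses 60–150-location worlds for orchestration checks, 1,000–10,000
locations where a sampling-error oracle needs them, and the 500-location
world for the end-to-end qualitative checks. Ties in predictive mean
matching go to the lowest donor id; rows of a transition matrix with zero
start mass are set to the target marginal; zero exposed area flags the
per-area rate as undefined rather than zero; a pool going negative raises
a step-size error rather than clipping.

## Known limitations

No nitrogen cycle, gaseous losses, phenology or water balance beyond the
scalar moisture modifier; no depths below 30 cm; no leakage accounting
(displaced production re-converting land elsewhere); national domain only;
the surrogate's parameter values are documented choices, not a calibrated
reconstruction of any published model.
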