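# Methods

This note records the models, numerical choices, and their rationale. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Terrain variables

**Slope and aspect.** Horn's 8-neighbour finite differences on the 3×3
window, the method behind `r.slope.aspect` and essentially every GIS.
Border cells and cells whose window touches nodata are returned as NaN
rather than filled with one-sided differences: a biased edge estimate is
worse than an honest gap, and camera sites sit well inside the raster.
Aspect is the *downslope* compass bearing, degrees clockwise from north.
Flat cells (zero gradient) have no defensible facing and carry an
undefined flag (NaN) that excludes them from aspect classification and
from circular averaging.

**Ruggedness.** Riley's TRI: the root of summed squared elevation
differences between a cell and its 8 neighbours. It is invariant to
elevation offsets and scales linearly with relief, both of which are
property-tested.

**Solar gain.** Daily insolation on the tilted surface, integrated in
6-minute steps over the day and averaged over twelve monthly reference
days (the 15th of each month, non-leap year). Direct beam:
`S0 · τ^m · cos(incidence)` with solar constant S0 = 1367 W/m²,
transmittance τ = 0.75 per unit air mass (configurable), air mass
m = 1/cos(zenith); the beam is clamped to zero below the horizon or
behind the surface. Diffuse: an isotropic term
`0.3 · S0 · cos(zenith) · (1 − τ^m)` scaled by the sky-view factor
(1 + cos β)/2, so it vanishes exactly when τ = 1 — which is also what
makes the extraterrestrial closed-form daily total usable as a test
oracle. Terrain shadowing and turbidity climatology are deliberately out
of scope: this is a *relative* covariate across sites, not a radiometric
product. Note that daily insolation is **not** monotone in
|latitude − declination| near polar day (daylight length wins over sun
angle); the monotonicity test therefore runs at equinox.

**Buffer extraction.** Arithmetic mean over cells whose centers lie within
100 m (default) of the camera point; circular mean for aspect. An empty
buffer is an error, not a silent NaN.

**Classification.** Natural breaks by exact dynamic programming (Fisher's
O(k·n²) algorithm) on the *site* values, since those are the empirical
distribution the model sees. The DP runs over distinct values weighted by
multiplicity because a threshold scheme cannot put equal values in
different classes; values are centered first to avoid catastrophic
cancellation in the prefix-sum SSD. Intervals are half-open [lo, hi) with
the last closed above, so a value exactly at a break belongs to the upper
class; printed integer class bounds (e.g. slope 0°–8°, 9°–16°) are
represented by their upper bounds as breakpoints under this rule. Class
counts default to 4 (slope, labelled low/medium/high/very high), 3
(ruggedness), 4 (solar). A variable that is constant across sites (flat
synthetic terrain) degrades gracefully to fewer classes. Aspect is
classified into quadrants N = [315°, 45°), E = [45°, 135°),
S = [135°, 225°), W = [225°, 315°).

## Events, occasions, effort

The independence filter uses the rolling "delta time" convention: a record
starts a new event only if it falls ≥ 30 min (default) after the *most
recent* record of the current event, absorbed records included. This
matches the camtrapR convention the field's tooling established; the
strict reading of "more than five capture events" (> 5) gates model
inclusion, and both are configurable.

Occasions are 5-day bins tiled from each site's first active day; sessions
at a site are concatenated into one single-season history. Partial
terminal occasions keep fractional effort rather than being truncated —
no data are discarded, and standardized log(effort) in the detection model
absorbs the imbalance. Zero-effort bins (gaps between sessions, camera
failures) are masked and contribute nothing to the likelihood. Day
boundary is local midnight; timestamps carry no timezone arithmetic
(camera clocks are local).

## The multispecies occupancy model

Single-season occupancy with imperfect detection per species; ψ is read as
*habitat use* since ranging species can violate closure. The default
design fits **one topographic variable at a time** (intercept +
reference-coded class indicators, first alphabetical class as baseline),
because per-class ψ is the target quantity for every variable separately;
a combined model adding z-standardized continuous covariates sits behind a
flag. Detection shares the categorical terms and adds standardized
log(effort); a perfectly uniform effort column is dropped as
uninformative. Priors are independent Normal(mean 0, variance 1000) on
all coefficients — the precision-0.001 convention of BUGS-family software;
a Normal with *variance* 0.001 would be strongly informative and
contradict the weakly-informative intent. An optional community layer
(species coefficients drawn from per-term Normal hyperpriors with
conjugate Gibbs updates) exists but is off by default: the base model
treats species independently and makes no attempt at unobserved-species
richness.

### Sampler

Metropolis-within-Gibbs with three deliberate design choices:

1. **Collapsed coefficient updates.** Coefficients are updated against the
   marginal likelihood with z integrated out analytically per site
   (`log(ψ·Π(1−p) + (1−ψ))` for all-zero histories). Conditioning on a
   sampled z instead is the textbook scheme but mixes catastrophically
   whenever a species/class cell is separated — e.g. a species never seen
   in any site of a class — because the "absent" (ψ→0) and
   "present-but-undetected" (p→0) posterior arms cannot be bridged while z
   is pinned. The latent z is still drawn exactly from its conditional at
   the end of every sweep (a partially collapsed Gibbs scheme, which
   preserves the joint posterior).
2. **Adaptive block proposals.** Each species' coefficient vector takes a
   multivariate Gaussian random-walk step whose covariance tracks the
   empirical chain covariance (Haario-style) and whose scalar scale tunes
   toward ≈ 0.3 acceptance. Both adapt during burn-in only and freeze
   afterwards, so retained draws come from a fixed, valid kernel.
   Reference-coded designs make (intercept, class effect) pairs strongly
   correlated; per-coefficient proposals crawl along that ridge, block
   proposals do not.
3. **Prior-independence refresh.** Every 10th sweep, each coefficient also
   receives an independence proposal drawn from its prior, accepted on the
   likelihood ratio alone (prior and proposal densities cancel). On the
   likelihood plateaus that separation creates under a vague prior —
   regions stretching to ±3 prior SD ≈ ±95 on the logit scale — these
   jumps are what lets chains traverse the plateau; for well-identified
   coefficients they are almost never accepted and are harmless.

Chains are seeded via `numpy` `SeedSequence.spawn`, one stream per chain;
a fixed seed reproduces every draw bit for bit. Retained draws per chain
are `floor((n_iter − n_burnin)/thin)`. Acceptance rates pinned near zero
after burn-in trigger a warning. Convergence is summarized by the
Gelman–Rubin potential scale reduction factor (plain variant by default;
split-chain optional); equal-tailed quantile intervals at 95% and 75%
drive the strong/moderate/none support classes.

### Recovery validation and the prior

The recovery test (20 replicates, 60 sites × 10 species × 12 occasions,
coefficients uniform on ±1.5) fits with a Normal(0, 1.5²) prior rather
than the variance-1000 analysis default. This is not a tuning choice but a
well-posedness one: under a vague prior, any separated cell puts its
posterior mass on a plateau whose mean sits tens of logits from the truth,
so posterior-mean recovery is impossible *in principle*, for any sampler.
A weakly informative prior of the scale routinely used for logit
coefficients restores an estimable problem; point-estimate correlation and
95% interval coverage are then meaningful checks of the machinery. The
convergence acceptance check, by contrast, runs with the vague
analysis prior — R̂ measures chain agreement, which the refresh steps
maintain even on plateaus.

## Synthetic data

The generator emulates a semi-arid mountain camera survey: a 30 m DEM
built from two orthogonal ridge/valley sinusoids (wavelengths 3.5 and
5 km, ~180 m relief) plus six smooth random waves and a gentle regional
tilt; sites on a jittered lattice with ≥ 1 km spacing (the field design's
spatial-independence rule); covariates computed *through the real terrain
pipeline*; landscape-unit labels from simple elevation/slope rules as a
stand-in for geomorphological mapping. Species responses are logit-linear
in one categorical variable with coefficients uniform on ±1.5 (detection
intercepts on [−1, 0.5], keeping occasion-level p in a realistic
0.27–0.62 band). Detections are materialized as bursts of 1–4 records
< 30 min apart and ≥ 30 min from the next burst, so the independence
filter recovers exactly one event per simulated detection; deployment
gaps (probability 0.2 per site) and end-trims up to 3 days exercise
masking and fractional effort.

What the generator does **not** emulate: diel activity, home ranges and
spatial autocorrelation, trap-shyness, misidentification, seasonal
turnover. Passing tests therefore demonstrate that the pipeline recovers
the data-generating process it assumes — not that the model is robust to
the ways real surveys violate it.

Default problem sizes in the tests and the acceptance script (40–60
sites, 8–10 species, 12 occasions, chains of 4,000–6,000) are scaled-down
study analogues chosen so the full validation battery runs on a laptop in
minutes; the full-survey scale (131 sites, ~34 species, chains of
100,000) runs unchanged through the same code paths, and the chain
accounting test exercises the full 3 × 100,000 configuration on a minimal
model.

## Known limitations

- Solar gain omits horizon shadowing; in deeply incised valleys it
  overestimates insolation, compressing the contrast the solar classes
  are built from.
- No spatial autocorrelation terms; sites are treated as independent given
  covariates (the ≥ 1 km spacing rule is inherited as an assumption).
- Single-season only: no colonization/extinction dynamics, no
  multi-season pooling beyond concatenation with masking.
- No model selection beyond convergence checks; the per-variable models
  are descriptive contrasts, not a variable-importance analysis.
- The vague-prior posterior for separated species/class cells is honest
  but scientifically vacuous (it reproduces the prior tail); per-category
  ψ for such cells should be read accordingly.
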