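# Methods

This note records the models, parameter choices, numerical decisions, and
known limitations behind `shorewhale`. It is written for a reader who wants
to know exactly what the package computes and what passing its tests does
and does not demonstrate about real field data.

## Geolocation

A theodolite fix is a depression angle θ below the true horizontal plus a
horizontal angle from a surveyed reference azimuth. For a sea-surface target
at horizontal range *s* from an instrument at effective height
*h* = station height − tide, curvature and refraction displace the target
below the horizontal by h + (1−k)s²/(2R), giving

    tan θ = h/s + (1 − k) s / (2R).

We solve the quadratic exactly and take the near root; the far root diverges
as R → ∞ while the near root reduces to the flat-earth solution h/tan θ.
Angles at or below the horizon dip √(2h(1−k)/R) have no sea-surface
intersection and raise a typed error. The refraction coefficient defaults to
the standard surveying value k = 0.13 and is configurable; the correction is
material beyond ~3 km and reaches kilometres near the horizon. The vertical
angle is defined as depression below the *true* horizontal (not the apparent
horizon) — I/O should adhere to that dialect.

All position composition uses a planar east/north grid anchored near the
stations (equirectangular scaling at the anchor latitude). At the < 50 km
extents of a shore-based study the planar error is far below the angular
measurement error (5 arc-sec at 5 km ≈ 30 m of range scatter, versus
centimetre-scale projection error), so no geodesic machinery is used.
Azimuths are degrees clockwise from true north throughout.

## Synthetic study generator

The generator emulates a shore-based behavioral response study during active
seismic acquisition. Its defaults are the study conditions and are not
tuning knobs:

* **Behavioral states.** Four field-annotated states — feeding,
  feeding/traveling, traveling, mixed — follow a 30-s Markov chain whose
  off-diagonals are proportional to the target stationary distribution
  (26/33/30/11 %, the observed activity budget), giving mean dwell times of
  ~20–25 min. The construction is reversible, so the stationary distribution
  is exact by detailed balance.
* **Movement.** A state-switching correlated random walk: per-step speeds
  are log-normal with state means 1.0 / 2.0 / 4.0 / 1.5 km/h (feeding
  through mixed) and heading increments are wrapped-normal with per-state
  concentration κ (1 / 4 / 20 / 2) — directional when traveling, convoluted
  when feeding. Log-normal speeds keep positive support and match the ln
  transform used downstream. Whales reflect at a 100-m shore buffer and at
  the 6-km offshore edge of the nearshore band, consistent with animals that
  forage on average ~1.5 km from shore.
* **Respiration.** Alternating surfacing/dive cycles in continuous time:
  blows per surfacing 1 + Poisson, gamma inter-blow intervals, gamma dives.
  Feeding whales dive long (240 s mean) with short intervals (15 s);
  traveling whales dive briefly (90 s) with long intervals (25 s) — the
  qualitative regime the analysis must detect.
* **Vessels and sound.** Seismic vessels acquire parallel lines
  perpendicular to shore (inshore end 7.5 km out, 15-km lines, 0.5-km
  spacing, 8 km/h, 10-s shot clock; silent line turns); support vessels
  shuttle alongshore. Propagation is SEL(r) = SL − N·log₁₀ r − α·r with
  N = 20 (spherical spreading) and α = 1.5 dB/km, an effective shallow-water
  attenuation; received levels are floored at a 53-dB ambient. A 230-dB
  per-shot source under this law plus the nearshore/offshore geometry keeps
  simulated exposure inside the observed 53–172 dB re 1 μPa²·s envelope
  (typical runs span ~90–165 dB with means in the 130s); in the emulated
  field season the very top of the envelope was shaved by mitigation
  shutdowns, which are deliberately out of scope, so the ceiling here is
  geometric. Window SEL_30s energy-sums the shots in the window; continuous
  sources convert SPL to SEL_30s via +10·log₁₀ 30. A pile-driving channel
  exists in the types but no pile source is generated by default and the
  channel is excluded from default models.
* **Observation process.** One fix per surfacing (configurable to one per
  blow — the field cadence per surfacing is a protocol choice, not a law),
  taken at the first blow, through the exact inverse geodesy plus Gaussian
  angular noise (default 5 arc-sec, the instrument precision class). Fixes
  beyond the station's range (6 km for low stations, 12 km for high ones)
  are suppressed and counted. Behavior-state annotations can be
  misclassified at a configurable rate (default 0). Tide modulates the
  effective instrument height in both directions of the transform.
* **Injected dose–response.** Above a configurable SEL threshold, the
  generator can scale log step speed by s·(SEL − thr) per dB, rotate
  headings toward the away bearing, or stretch inter-blow intervals. The
  exact per-step dose the injection used is stored with the track, so
  recovery tests regress against truth rather than a re-measured proxy.
* **Environment and prey.** Sinusoidal tide (0.8 m amplitude, 12.42-h
  period), depth linear in distance from shore (4 m/km, so the 20-m isobath
  sits 5 km out), straight north–south shoreline. Benthic samples on a
  ~1 × 1.5 km grid inside the 20-m isobath carry five taxa as log-normal
  fields: exponential-covariance Gaussian random fields (3-km range, 0.6 ln
  sd) around taxon medians matched to a nearshore amphipod-dominated
  community, with optional linear depth trends. Totals are exact sums of
  taxa.

What the generator does **not** emulate: measurement-failure gaps and
weather censoring beyond the range cutoff, mother–calf class structure,
individual heterogeneity or sensitization across repeated exposures,
waveform acoustics and bathymetric propagation, and mitigation shutdown
logic. Passing tests therefore demonstrate that the estimators recover what
this idealized field setting contains — not that real data meet the models'
assumptions.

## Response variables

Movement bins span exactly 7 consecutive 90-s steps (10.5 min),
non-overlapping from each sub-track start — overlap would manufacture
autocorrelation on top of what the AR structures already model. Tracks split
where raw fix gaps exceed 600 s; interpolation is linear in time along the
chord and never extrapolates. Definitions: SPD = cumulative step length per
bin duration; LIN = net/cumulative; RR = mean |Δheading| per minute; MDIR
and TRK_R = mean resultant lengths of step headings and of turning angles
respectively (TRK_R is the "directionality index": insensitive to absolute
direction, sensitive to turn consistency); Range = maximum pairwise distance
among the 8 positions (a net-displacement alternative is available by
config — "range index" admits both readings and the choice is logged);
direction is reported as (cos, sin) of the net-displacement azimuth, with
zero-net bins flagged and LIN = 0 retained; ROW folds the difference between
movement azimuth and whale→vessel bearing into [0°, 180°]. Bin state is the
modal state of the 8 positions, ties resolved to "mixed" (the field label
for ambiguous behavior).

Respiration cycles: a surfacing is a maximal blow run with gaps ≤ 60 s
(configurable) not split by a recorded dive start; the 60-s default
separates the ~15–25 s inter-blow regime from true dives by an order of
magnitude on either side. Surfacing duration is last blow − first blow with
a zero post-blow allowance by default (any terminal-surface allowance is a
protocol convention, exposed as a parameter). Cycles join the bin containing
their midpoint; bins with no cycle yield no row rather than zeros. Rates
that require a dive (dive–surface blow rate, percent time at surface) are
computed only over cycles whose dive was observed, so a record that ends at
the surface cannot bias them; all-surface bins report 100 % time at surface.

## Covariates

Exposure is evaluated at interpolated whale positions every 30 s, per
source type, and summarized per bin as the **energy mean** of the step
SEL_30s values — the energy mean stays on the same physical scale as cSEL,
is bounded by the step minimum and maximum, and makes the bin summary the
exact per-window average of received energy (a max summary is available by
config). cSEL accumulates energy from the start of the *track* (not the
bin) and is read at bin end; missing steps are skipped and the running total
carries forward. Distances are bin minima; ROW and vessel count are taken at
the bin midpoint. In model tables, bins during which a source type emitted
nothing carry the ambient floor rather than a missing value — "unexposed"
is a level, not a gap — so unexposed bins inform the dose–response contrast
instead of being deleted.

## Prey surfaces

IDW uses power 2 over the 12 nearest samples (conventional defaults;
exact at sample points by construction). Kriging is regression kriging: an
OLS depth trend, then ordinary kriging of the residuals under an
exponential variogram fitted by Cressie-weighted least squares to the
binned empirical semivariogram; prediction = trend + kriged residual, exact
at sample points when the nugget is zero. A singular kriging system is
ridge-stabilized with a warning; a failed variogram fit falls back to
variance-scale defaults and is logged. Regression kriging was chosen over
KED/co-kriging variants as the simplest member of the family that uses
depth; the flavor is configurable in principle and the default is recorded
here. Per-bin prey is the maximum interpolated biomass over the bin's 8
positions, restricted to the < 20-m isobath where samples exist; prey
enters the default response models only behind a flag, because behavior
state already absorbs the feeding/biomass association and depth-adjusted
kriging would alias the depth covariate.

## Response models

The estimator is a weighted marginal linear model fit by feasible GLS:
y = Xβ + e with Var(e) = σ²·blockdiag_j(W_j^{-1/2} R_j W_j^{-1/2}), where
the blocks are tracks. Weights are Horvitz–Thompson-style inverse-inclusion
weights w_ij = N/(J·n_j): every track gets equal total mass, weights sum to
the bin count, and equal-length designs give unit weights — the natural
reading of "inversely proportional to the probability of obtaining that
observation" for tracks of unequal length. R_j is independence, compound
symmetry ("constant" — also the exact marginal of a track random intercept,
which is how the random-intercept mode is exposed), AR1, or a stationary
per-lag Toeplitz estimate standing in for "unstructured", which is not
estimable in its general form on variable-length tracks. Correlation
parameters come from moment estimators on OLS residuals, iterated once;
whitening is per-block Cholesky. Standard errors use the whitened normal
equations with t-tests at n − p degrees of freedom.

BIC is computed from the Gaussian **ML** likelihood (including the
log-determinant of the correlation blocks and the weight Jacobian), not
REML, because stepwise selection compares models with different fixed
effects and REML likelihoods are not comparable across fixed-effect sets.
Selection runs forward over natural covariates, then forward over impact
covariates (natural effects get first claim on shared variance, so impact
effects must explain residual variation), then one backward pass; BIC ties
within 0.01 resolve toward the smaller model. Transforms: logit with the
boundary squeeze x → (x(n−1)+0.5)/n for the [0,1] indices, ln for speeds,
distances and respiration durations/rates, identity for angles reported as
(cos, sin), ROW, reorientation rate, range and percent time at surface.
Collinearity is screened by pairwise Pearson |r| > 0.60; among collinear
acoustic metrics the SEL_30s/cSEL family is retained and SPL/PK duplicates
dropped. No multiple-testing correction is applied: significance flags are
raw p < 0.05, matching standard practice for these coefficient tables, and
should be read as descriptive. Missing data are handled by listwise
deletion per model with the dropped count recorded on the fit.

PCA is computed on the correlation matrix of complete-case standardized
responses; each loading vector is oriented so its largest-magnitude element
is positive, and PC1–PC3 scores re-enter the model suite as additional
responses. On default generator runs the first three components carry
roughly three quarters of the movement variance and over 90 % of the
respiration variance, reflecting how strongly both families organize along
the feeding–traveling axis.

## Validation design

Calibration checks simulate at two levels. Model-layer simulations
(`simulate_bin_dataset`) draw grouped bin tables directly — 20–25 tracks of
~10–12 bins, between-track exposure spread with slow within-track drift,
AR1 residuals — sized so that hundreds of fits run in seconds: type-I error
of the impact-coefficient test over 500 null fits, AR1-vs-independence BIC
preference at ρ = 0.5 over 100 replicates, and stepwise null/strong
selection rates over 200/100 runs. End-to-end recovery
(`speed_recovery_dataset`) runs the actual generator → resampling → bins →
covariates path with an injected 0.02 /dB log-speed effect across 100
replicates of 6 whales × 5 h and checks 95 % CI coverage of the injected
slope. The regression uses the generator-recorded dose: measuring exposure
on the post-response path instead attenuates the slope ~20 % (an
errors-in-variables effect worth remembering when interpreting real
dose–response coefficients, where only the responded path is observable).
Problem sizes throughout were chosen to make Monte-Carlo error small
relative to the tolerances being checked while keeping the full suite in
the low minutes on one CPU.

## Known limitations

* The planar anchor is shared per run; multi-region studies spanning
  hundreds of kilometres would need a proper projection.
* The AR1/CS moment estimators are consistent but not REML-efficient; with
  very short tracks (≤ 3 bins) correlation parameters are noisy and the
  type-I error of impact tests sits near the upper half of its nominal
  band.
* The "unstructured" correlation is a stationary per-lag approximation, not
  a free within-track covariance.
* The stepwise path is greedy; the exhaustive-subset check in the tests
  bounds, but does not eliminate, the usual stepwise caveats.
* Fleet geometry is a deterministic racetrack; real surveys interleave
  lines, standbys and transits, which matters if exposure histories are
  the object of study rather than a covariate.
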