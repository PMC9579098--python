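# shorewhale

Shore-based behavioral dose–response analysis for gray whales on a nearshore
foraging ground exposed to seismic-survey and vessel sound — implemented as a
tested, reusable pipeline with a synthetic-data generator that provides
ground truth for every stage.

Teams on coastal stations track whales with a theodolite (a vertical and a
horizontal angle per surfacing) and record respiration events during focal
follows, while seismic source vessels acquire lines nearby. This package
turns those raw observations into binned movement and respiration response
variables, attaches acoustic and vessel exposure covariates, and fits
weighted mixed models to ask whether behavior changed with exposure. Because
real datasets of this kind are rarely public, a first-class generator
emulates the whole field setting — behavioral states, surfacing/dive cycles,
seismic line acquisition, sound propagation, tide, bathymetry, benthic prey
— with injectable dose–response effects of known magnitude, so every claim
the analysis makes can be checked against truth.

Intended users: movement ecologists and bioacousticians building behavioral
response studies, and statisticians validating the estimators such studies
rely on.

## What it computes

**Geolocation.** A fix at depression angle θ from tide-corrected instrument
height *h* is inverted through the curvature-and-refraction equation
tan θ = h/s + (1−k)·s/(2R) (refraction coefficient k = 0.13, earth radius
R), choosing the near root for the horizontal range *s*; the flat-earth
limit s = h/tan θ is recovered as R → ∞. At 12 km a naive flat-earth
inversion is ~4 km short; the corrected round trip is accurate to < 1 m.

**Response variables.** Tracks are resampled on a 90-s criterion and scored
over 10.5-min bins (7 steps): speed SPD, linearity LIN = net/cumulative
displacement, reorientation rate RR (deg/min), mean direction MDIR and
directionality TRK_R (mean resultant lengths of headings and turning
angles), range index, shore distance, movement direction (cos, sin), and
the relative orientation to the closest (seismic) vessel ROW ∈ [0°, 180°]
(0 = toward, 180 = away). Focal-follow event streams are segmented into
surfacing/dive cycles and summarized per bin: respiration interval, surface
time, dive time, blows per surfacing, surface and dive–surface blow rates,
and percent time at surface. Correlation-matrix PCA supplies PC1–PC3 score
responses for each variable family.

**Exposure covariates.** Sound exposure level over each 30-s step
(SEL_30s, dB re 1 μPa²·s) per source type, with impulsive sources
energy-summed over shots, 10·log₁₀ Σ 10^(SELᵢ/10); cumulative cSEL from
track start; closest vessel and closest seismic vessel distances; vessel
count; depth, tide, time of day and behavior state as natural covariates.

**Models.** Each transformed response (logit for indices, ln for speeds,
distances, and respiration variables) is fit by weighted feasible GLS with
track-level grouping: Horvitz–Thompson style bin weights equalize track
mass, and within-track residual correlation is selectable among
independence, compound symmetry ("constant"), AR1, and a stationary
per-lag estimate. BIC-based forward (natural, then impact covariates) plus
backward stepwise selection yields coefficient tables with p < 0.05 flags.
Prey biomass is interpolated to whale locations by IDW and by regression
kriging on depth, with a behavior-state ANOVA.

## Worked example

`examples/04_dose_response_model.py` injects a known effect — above 90 dB
SEL_30s, log swimming speed rises by 0.02 per dB — then rebuilds the bin
table through the normal metrics/covariates path and fits the mixed model:

```
272 bins from 8 tracks; injected slope 0.02 per dB
fitted slope 0.0190  (95% CI [0.0165, 0.0215]), p = 1.45e-36
AR1 rho = 0.11, BIC = -122.1

coefficients:
              term    coef     se       t   p  significant
                B0 -1.7440 0.1799 -9.6958 0.0         True
state[feed/travel]  0.7183 0.0322 22.2754 0.0         True
  state[traveling]  1.3800 0.0340 40.5516 0.0         True
      state[mixed]  0.4777 0.0377 12.6734 0.0         True
```

The confidence interval covers the injected truth; the behavior-state
contrasts (reference = feeding) recover the configured speed regimes —
traveling whales move about e^1.38 ≈ 4× faster than feeding whales. The
other examples walk through the generator and observation process (01),
curvature-corrected geolocation (02), bin metrics (03), the full pipeline
with a case-study timeline of cSEL/SEL/vessel distance/speed/displacement
(05), and prey interpolation with the state ANOVA (06).

A thin CLI wraps the pipeline for shell use:

```
shorewhale all --seed 42 --out run1/
shorewhale case-timeline --out run1/ --whale W000 --seed 42
```

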