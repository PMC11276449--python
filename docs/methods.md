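# Methods

This note documents the models, algorithms and numerical choices behind
`aomosaic`, what the synthetic generator does and does not emulate, and the
problem sizes the tests use.

## Magnification model

Retinal distance per degree of visual angle is computed with the
small-angle Bennett schematic-eye relation, `q [mm/deg] = 0.01306·(AL −
1.82)`, where AL is the axial length in mm and 1.82 mm the distance from
the posterior nodal point to the corneal vertex of the reduced eye. The
lateral pixel pitch of a scan is `q · fov / N` for a field of `fov` degrees
sampled with `N` A-scans (`N` defaults to 512 but is configurable). Fuller
Bennett–Rabbetts variants that correct for refraction or corneal curvature
are out of scope: they need per-eye refraction data the package does not
model, and the simple relation is the standard choice when only biometry
is available. OCT depth is treated as geometric distance; optical path
length scaling of the axial axis is not modeled.

## Synthetic data: what it emulates

Cell mosaics are **jittered hexagonal lattices**: points on a hex lattice
with spacing `a = √(2/(√3·D))` for target density `D`, rotated by a seeded
random angle (the lattice has 60° symmetry, so rotations are drawn from
[0, 60°)), each point perturbed by isotropic Gaussian jitter of SD
`jitter_frac · a` (default 0.10). A Poisson process would be wrong here:
real cone and RPE mosaics are quasi-crystalline, and only a quasi-regular
arrangement produces the spectral ring the power-spectrum estimator needs.

En-face images are sums of Gaussian spots at the cell centers (FWHM
defaulting to 3 µm, capped in the pipeline at half the expected spacing so
foveal-adjacent cones stay resolved), attenuated under vessel masks and
degraded with **multiplicative lognormal speckle** of a given coefficient
of variation (default 0.15 in pipeline runs). This is the simplest noise
model that produces realistic contrast variation; it is not coherent
speckle, so the speckle grain has no wavelength-dependent correlation
length.

Volumes place, for each cone, two axial Gaussian reflections (IS/OS at
40 µm and COST at `40 + OSL` µm by default, axial FWHM 8.4 µm ≈ the
resolution of a broadband 1060 nm source) above a continuous RPE band at
90 µm rendered twice as bright as a single cone reflection — that contrast
ordering is what makes flattening-to-the-brightest-band well defined.
Per-cone OSL is drawn `N(mean, sd)`; an optional per-column axial
displacement field exercises flattening. The axial pixel defaults to
1.0 µm.

Topographic defaults (eccentricity `E` in degrees, temporal):

| metric | model | default |
|---|---|---|
| cone density | `a·E^b` | `a = 53,329` cells/mm², `b = −0.731` |
| RPE density | linear | `6913 − 123·E` cells/mm² |
| OSL | poly2 | through (1°, 33.3 µm) and (12°, 18.0 µm) |
| between-subject CV | lognormal | cones 15.2%, RPE 9.3%, OSL 7.2% |
| within-session CV | normal | PR density 1.6%, OSL 2.0%, RPE 2.3% |

The cone exponent is anchored so the power law passes through the 1° and
12° normative means. The OSL polynomial has one free parameter beyond its
two endpoint constraints; it is resolved by requiring the derivative to
vanish at 12°, the minimal choice that keeps the curve monotone decreasing
on [1°, 12°] (steep decline near the fovea, flattening peripherally). The
mid-course of that curve is a modeling convenience, not ground truth, and
all three coefficients are exposed in `CohortSpec`.

Cohorts draw one multiplicative lognormal effect per subject and metric
(mean 1, CV as above) and scale the model curves; cones are generated only
for `E ≥ 1°` (individual foveal cones are not resolved at this image
quality), RPE everywhere. Rods and the rod outer segment tip (ROST) band
are not rendered. All generators are pure functions of (parameters, seed).

### What passing tests do not show

The generator omits eye-motion artifact, scanner warp, coherent speckle
statistics, session-to-session contrast changes, cone reflectance
flickering, and grader behavior. Recovery results therefore demonstrate
that the measurement chain is unbiased under the stated noise model — not
that it would achieve the same accuracy on real volumes. One visible
consequence: simulated repeat sessions vary only by the within-session
CV, so the RPE ICCs from pipeline runs come out near the PR ICCs, whereas
real RPE reliability is degraded by contrast and region-selection effects
that are not modeled.

## Cell detection

The detector is a deterministic classical stand-in for learned cell
counters, adequate at synthetic-image scale: difference-of-Gaussians
band-pass tuned to the expected spacing (center σ = 0.12·spacing, surround
σ = 0.4·spacing — chosen so neighboring spots at the densest mosaics
remain separated), candidate local maxima above a configurable quantile of
the response (default 0.5), then greedy non-maximum suppression in
continuous coordinates with a minimum separation of 0.6·spacing.
Suppression is done in continuous coordinates deliberately: a raster
footprint of the same nominal radius over-suppresses at small spacings
because integer discretization inflates the effective radius. Detections
against ground truth are scored by greedy nearest-pair matching within
half the expected spacing. There is no manual-correction stage; the
pipeline records raw detector output.

## Voronoi metrics

A cell is counted when its Voronoi polygon is finite, lies entirely inside
the analysis window, and does not overlap the vessel mask (tested at the
cell center and polygon vertices). Density uses the summed included
polygon area as denominator — not the window area — which removes boundary
bias and makes the estimate intensive (masking half the window halves the
count but leaves density unchanged). Spacing averages center-to-center
distances over Voronoi-adjacent included pairs; zero-length ridges (the
degenerate corner contacts of a square grid) do not count as adjacency.
At least 10 input points and 3 included cells are required; collinear
inputs are rejected.

## Power-spectrum density

Mean-subtract, 2-D Hann window, FFT, radially averaged power. The ring is
the highest radial peak within 0.5–1.5× the frequency expected from a
density hint (the pipeline uses the normative model value at the ROI's
eccentricity, never the ROI's own truth), refined to sub-bin precision by
parabolic interpolation on log power, and converted by `D = (√3/2)·f²`
(verified against the lattice identity `D = 2/(√3·a²)`). Vessel pixels are
filled with the unmasked mean before windowing, mirroring the Voronoi
exclusion. A peak must rise 2× above the in-band median or a no-ring error
is raised (constant images have no spectrum). The band default is
deliberately narrow; widening it admits speckle peaks at high frequencies
on noisy images. Finite windowing skews the detected peak slightly low, so
spectral density regressed on Voronoi density has slope just below 1 —
this bias is a property of the method, reproduced rather than corrected.

## OSL measurement

Volumes are flattened by shifting each column so the brightest axially
smoothed band (the RPE) sits at a common depth; the reference depth map is
median-filtered laterally (5 px) and shifts are integer pixels, returned
for exact inversion. The per-cone search window ends 6 µm above the RPE
band located on the volume-mean A-scan — wide enough that COST peaks near
the band are kept (the band's truncated rising edge cannot form a spurious
local maximum), narrow enough that the band itself is excluded. Each
cone's A-scan is averaged over a 3×3 px lateral neighborhood, the two most
prominent local maxima with a ≥5 µm separation are taken as IS/OS and
COST, each is refined by 3-point parabolic interpolation, and
`OSL = Δz · axial_pixel`. Peak *maxima* are used, not band edges — edge
definitions systematically yield shorter outer segments and are not
comparable. Cones with fewer than two distinct peaks are flagged invalid,
never silently dropped. Summaries report mean, SD and a bimodality flag
(sample bimodality coefficient `(skew²+1)/kurtosis > 5/9`); the flag is a
screen, not a test, and fires easily on heavy-shouldered distributions.

## Topography fits

Power fits use nonlinear least squares initialized from log–log
regression (so the reported coefficients minimize squared error on the
natural scale, not the log scale); linear and quadratic fits are ordinary
least squares. Cone-derived metrics are fitted for `E ≥ 1°` only. Fits are
made to the per-eccentricity cohort means; both `R²` conventions —
Pearson and Spearman of observed vs predicted, plus Spearman on the raw
eccentricity relation — are reported and labeled, since the literature
quotes either. The cone/RPE ratio is fitted on per-subject ratios averaged
per eccentricity (mean of ratios); the ratio of cohort mean densities is
reported alongside, and the two agree as between-subject variance
vanishes. Constant data make correlation undefined; such fits carry a
`degenerate` flag instead of numbers. No multiple-testing correction is
applied to the correlation p-values.

## Reliability statistics

ICC is fixed to the McGraw–Wong absolute-agreement average-measures form,
`ICC(A,k) = (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n)` from the two-way ANOVA
mean squares; for complete balanced tables the mixed-vs-random distinction
does not change this point estimate. Confidence intervals use the
single-rater F interval stepped up by Spearman–Brown; the implementation
is cross-checked against an independent statistics package in the test
suite. Lin's concordance uses n-divisor moments with the Fisher-z
large-sample interval. The normalized SD is the per-subject
SD-across-sessions divided by the subject mean, averaged with equal
subject weights; note the k=3 sample SD is biased low by the factor
c₄(3) ≈ 0.886, which matters when recovering a generating CV exactly.
Conventional qualitative labels (<0.5 poor, 0.5–0.75 moderate, 0.75–0.9
good, >0.9 excellent) are attached to ICC estimates.

## Pipeline and problem sizes

The default run mirrors the study design: 11 subjects × 13 ROIs (fovea to
12° temporal, 1° spacing), 250 µm mosaic windows at 1 µm/px, one vessel
band of 12 µm per ROI, OSL measured on a 64 µm sub-window volume
(~100 cones/ROI), and a 7-subject × 3-session reliability sub-study. This
configuration runs in well under a minute on one CPU and is the size used
by the recovery tests; the acceptance script uses ~200-cone volumes and
20 mosaics of 256 µm for the density-range regression. Runs are
deterministic given the seed: all stage RNGs are spawned from it, and the
manifest records seed, parameters and file list so any run can be
reproduced or restarted from its serialized stage outputs.

## Known limitations

* The detector is tuned for quasi-regular bright-spot mosaics; it is not a
  general cell segmenter and has no learned component.
* Vessel overlap of a Voronoi polygon is tested at its center and
  vertices, not by exact polygon–raster intersection; thin vessels fully
  inside a large polygon could evade exclusion.
* Flattening uses integer-pixel column shifts; sub-pixel tilt remains
  (≤0.5 px), which is negligible at the default 1 µm axial pitch.
* The OSL minimum peak separation (5 µm) sets a floor on measurable outer
  segment length; shorter OSLs than ~6 µm would need a narrower axial PSF
  than the 8.4 µm default anyway.
* Power-spectrum density requires a density hint within roughly ±50% (the
  search band); it is a verification tool here, not a blind estimator.
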