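# Methods

`compoundv` measures the internal structure of shorebird cluster flocks
("compound-V" formations) from reconstructed 3D trajectories, and ships
synthetic generators with known ground truth so that every estimator can
be validated end to end.  This note records the models, the parameter
choices, the numerical decisions, and what the synthetic validation does
and does not establish about real recordings.

## Data model and kinematics

A recording is a set of per-bird tracks on a shared frame clock
(29.97 Hz by default), positions in metres with z aligned to gravity.
Only relative elevations are meaningful; the origin is arbitrary.
Tracks may contain gaps of up to four frames (the tolerance of the
upstream tracker that produced them); longer gaps must already have been
split into separate tracks.  Gaps are filled by linear interpolation
before differencing.

Velocities are central differences on interior frames and one-sided
differences at the ends (`numpy.gradient`): second-order accurate with
no phase lag, which matters because headings feed circular statistics
downstream.  Heading is the horizontal velocity azimuth in [0, 360);
turn rate is the derivative of the unwrapped heading.  Focal samples
with ground speed below 0.5 m/s are excluded from neighbor analyses —
the flight-aligned frame is undefined for a hovering bird.

Per-bird statistics are extracted at one-wingbeat intervals
(`round(frame_rate / wingbeat_hz)` frames, species default frequency
when no measurement exists) to reduce serial correlation between
samples; every-frame sampling is available as an option and changes the
medians by well under 2%.

## Nearest-neighbor alignment

For each sampled bird the displacement to its nearest flockmate is
rotated into the flight-aligned frame: front-back along the horizontal
velocity, lateral perpendicular (positive to the bird's right),
elevation vertical.  Distances are non-dimensionalized by wingspan —
the shared wingspan for conspecific pairs, the mean of the two for
mixed pairs.  Two neighbor pools are supported:

* `restrict="any"` — the 3D nearest flockmate; the flock-density
  measure used for nearest-neighbor-distance summaries.
* `restrict="leading"` — the nearest bird *ahead* of the focal; the
  alignment-partner measure used for modal positions and the
  biomechanics covariates (a nearest neighbor is then only defined when
  it leads the focal bird).

The distinction matters: taking the minimum over several similarly
distant candidates systematically selects short links, shrinking
"nearest any" offsets by roughly 0.1 wingspans relative to the
generating rule in synthetic flocks.  The leading-neighbor pool has a
single natural candidate (the bird being followed) and recovers
generator truth nearly unbiased.

The modal neighbor position is the argmax of a fixed-bandwidth Gaussian
product-kernel density over (unsigned lateral, front-back) offsets of
leading neighbors within the ±1-wingspan elevation slice.  Modes are
used instead of means because distances truncate at zero and the
distributions are skewed.  Bandwidth is 0.25 wingspans per axis, the
evaluation grid 0.05 wingspans, spanning the data range; ties are
broken toward the smallest distance from the focal bird.  The mode is
therefore quantized at ±half a grid step, and the natural recovery
tolerance is half the bandwidth (0.125 wingspans).

## Elevation slice

"Same horizontal plane" means |elevation offset| ≤ 1 wingspan.  The
in-slice fraction of nearest-any neighbors is reported per flock.  Note
that 3D nearest-neighbor selection preferentially picks same-plane
birds, so this fraction exceeds the value implied by the marginal
elevation distribution: synthetic flocks whose link elevations are
N(0, 1) wingspans measure ~0.78-0.88 in-slice rather than the 0.68 of
the raw Gaussian.  The partition operation itself is validated against
the normal-CDF oracle on directly drawn offsets.

## Flock structure

The flock boundary is a concave hull over horizontal positions: the
union of Delaunay triangles with circumradius below a threshold that
starts at twice the frame's median nearest-neighbor distance and grows
(x1.6 steps) until the polygon is valid and covers every bird, with a
convex-hull fallback for degenerate sets.  Edge distance is the minimum
horizontal distance to the boundary; the flock's maximum radius is the
median edge distance, which guarantees analyses bounded by it retain at
least half the flock.  Because the data-driven boundary hugs the
sampled points, edge distances run slightly below their continuum
values (a uniform disc of 1000 points measures a maximum radius ~10-15%
under the analytic R(1-1/sqrt2); the bias shrinks with density, and the
distance computation itself is validated against dense boundary
sampling).  Hulls are computed per frame and per-bird edge distances
averaged across sampled frames.

Angular structure: at reference distances of 2, 4, 6, 8 wingspans (and
the maximum radius), the signed horizontal angles of all neighbors in a
±1-wingspan distance band and a ±15-degree elevation cone are pooled;
focal birds closer to the boundary than reference + band half-width are
excluded to avoid edge artifacts.  Echelon structure is *axial* — every
leading neighbor at angle a pairs with a trailing one near a+180 — so
the left/right asymmetry label uses the axial mean (half the circular
mean of doubled angles) rather than the plain circular mean, which
cancels on axial data.

The 10-nearest-neighbor power exponent is the least-squares slope of
log(mean distance at rank j) on log(j), j = 1..10, pooled over sampled
birds.  For uniform random points the exact finite-rank oracle is the
slope of log Gamma(j + 1/D) - log Gamma(j): 0.374 in 3D and 0.543 in
2D over ranks 1..10 (1/D is only the large-rank asymptote).  Lower
exponents indicate locally regularized spacing.

## Wind and airspeed

Birds holding a common airspeed trace a circle in ground-velocity
space, centred on the wind vector with radius the airspeed.  Headings
are binned at 10 degrees; each bin with enough samples contributes its
median ground speed as one point; a Kåsa algebraic circle fit refined
by one Gauss-Newton step on the geometric residuals gives the wind
vector and characteristic airspeed.  The literal 500-points-per-bin
rule presumes large recordings with concentrated headings; the
threshold is therefore capped at half the mean occupied-bin count
(floor 50) so that smaller or uniformly spread recordings remain
estimable.  At least three qualifying bins spanning 60 degrees are
required; otherwise the estimator refuses and the pipeline falls back
to station wind when available.  Airspeed is |ground velocity - wind|
per bird-frame.  Relative wind direction folds the angle between the
flight direction and the direction the wind comes from into [0, 180]
(0 = headwind).

## Wingbeat frequency and phase

Flapping pulses the image bounding box; the composite oscillation score
averages four standardized components — height, inverse width,
detrended top-left x and negated detrended top-left y — across
components and cameras (rolling 2-s standardization window).  The
"inverse" of a detrended, zero-mean corner coordinate is implemented as
negation; a literal reciprocal diverges at zero.  The composite is
band-pass filtered (4th-order zero-phase Butterworth, 2-15 Hz) and the
peak of a 128-point FFT magnitude spectrum (Welch-averaged for longer
signals, zero-padded down to 64 samples for shorter ones) gives the
frequency, refined by parabolic interpolation of the three surrounding
log-magnitudes — the raw bin at 29.97 Hz is 0.23 Hz, and interpolation
restores sub-bin resolution.  A peak below five times the median
in-band magnitude (≈25x in power) is declared "no detectable wingbeat";
for white noise over ~50 bins the expected max/median power ratio is
about 7, so false detections are rare.

Temporal phase between neighbor composites is the cross-correlation
lag restricted to ±one wingbeat duration d, refined to sub-frame
precision by parabolic interpolation, mapped to phase as
2π((lag mod d)/d).  Spatial phase subtracts the phase implied by the
along-track separation in wingbeat wavelengths (wavelength = airspeed ×
d) and wraps to [0, 2π).  Pairs require ≥20 overlapping frames and
frequencies within 15% of each other.  Synchronization is tested with
the Rayleigh statistic Z = n R̄²; below n = 10 a seeded Monte-Carlo
p-value replaces the series approximation.

## Species identification

sqrt(pixel area) x camera distance is range-invariant, so per-bird
averages of this scaled size separate species by body size.  The area
sequence is low-pass filtered first (zero-phase moving average one
wingbeat period wide) to remove flapping modulation; frames whose
bounding box merges two birds are excluded; birds with fewer than five
usable frames are unclassifiable.  A two-component normal mixture is
fit by expectation-maximization (five seeded restarts) after a KDE dip
check for bimodality; the classification threshold is the root of the
weighted component-density difference between the means, and the
expected error is w1 P(X1 > t) + w2 P(X2 < t).  Threshold and error are
affine-equivariant/invariant and validated against dense grid search
and trapezoidal quadrature oracles.

## Biomechanics models

One row per bird: median airspeed and climb rate over sampled frames,
wingbeat frequency, nearest-leading-neighbor distance (wingspans),
flock position (along-track rank scaled to [0, 1], 0 = front; invariant
under rigid motions), edge distance (wingspans), neighbor-species code
(-1/0/+1 by wingspan), and the aerodynamic-neighbor flag (leading
neighbor at 0.7-1.5 wingspans lateral and within two wingspans 3D
distance).  Birds without wingbeat data, and the frontmost bird (no
leading neighbor), drop out.

Responses (wingbeat frequency; airspeed) are modelled with
random-intercept linear mixed models grouped by flock.  REML is the
default for coefficient estimation; model selection switches to maximum
likelihood because REML likelihoods are not comparable across
fixed-effect structures, and BIC counts the fixed effects plus the two
variance parameters.  A singular random-intercept fit falls back to
OLS, flagged.  Selection is greedy-forward by default with an
exhaustive mode for ≤10 candidates.

Calibration note: with six groups, two-standard-error intervals cover
95.45% nominally for slopes but less for the intercept (the
between-group degrees of freedom are ~5); the validation suite asserts
coverage with the one-sided binomial allowance of the replicate count
and separately checks that the empirical sd of the estimates matches
the mean reported SE.

## Circular statistics

Rayleigh test: Z = n R̄², p by the standard finite-n series
approximation.  Rao's spacing test: U = half the total deviation of
sorted arc gaps from uniformity; p interpolated from an embedded
quantile table of the simulated null (100,000 replicates per sample
size, n = 4..500, frozen; spot-checks agree with published critical
values to ~0.1 degree) with a seeded Monte-Carlo fallback outside the
table.  Circular-circular correlation is the sine-product
(Jammalamadaka-SenGupta) form with its asymptotic normal test — note
the statistic saturates at |r| = 1, so perfect association yields a
small but non-vanishing p at n = 18.  Modal directions use a von Mises
kernel density on a 1-degree grid, concentration 50 (~4.6-degree sd) by
default, with the resultant length reported as a dispersion caveat.
All tests are invariant under global rotation of the sample.

## Synthetic generators

The generators are kinematic scaffolds, not behavioural simulations:
no steering, no wake aerodynamics.

`generate_compound_v` grows a flock by iterated attachment: each new
bird attaches behind an existing bird at lateral ~ N(1.0, 0.15)
wingspans (side Bernoulli; a bias parameter emulates left/right-aligned
flocks), trailing ~ N(0.8, 0.4), elevation ~ N(0, 1.3), with 0.05-
wingspan white positional jitter per frame and a shared air velocity
(9 m/s) plus a constant wind.  Two structural constraints make the
attachment link the nearest-neighbor link, as the alignment rule
presumes: each bird carries at most one follower per side (echelons
propagate as they do in real compound-V flocks), and a candidate is
redrawn unless its anchor is its nearest existing flockmate at
placement (the exclusion capped at the planar rule length so large
elevation draws are not truncated).  Without these, nearest neighbors
are dominated by accidental near-coincident pairs and no rule is
recoverable.  Trailing-distance variance is not constrained by any
published value and is exposed as a parameter; the default 0.4
wingspans reproduces the qualitative pattern of lateral spacing being
much tighter than trailing spacing.  The elevation sd default of 1.3
wingspans is the direct per-link reading of the observed concentration
of neighbors within ±1 wingspan (P(|N(0,1.3)| ≤ 1) ≈ 0.56).

`generate_simple_v` builds a single echelon or mirrored V at exact
per-link offsets.  `generate_bbox_series` imprints height/width
oscillations in antiphase, corner sway scaled to stroke amplitude, and
(body/distance)² areas.  `generate_mixed_species` draws per-bird scaled
sizes from a stated two-normal mixture with labels retained.  All
randomness flows through one explicitly passed seeded generator; a
`SyntheticTruth` JSON accompanies every bundle.

What synthetic validation shows: that each estimator recovers the
quantity it targets from data that *obey its model* (a shared airspeed,
a stationary rule, sinusoidal flapping, Gaussian size components).
What it cannot show: robustness to manoeuvring flocks, airspeed
modulation with wind, tracking errors, occlusion-driven track breaks,
or non-Gaussian size distributions — conclusions about real recordings
rest on those assumptions holding approximately.

## Problem sizes

Validation runs use flocks of 120-500 birds over 1.5-3 s, 10^4 samples
for wind sweeps, 2000 birds for mixture classification, 2000 replicates
for test calibration, and 50-100 seeds for mixed-model recovery; these
sizes put Monte-Carlo noise comfortably below each stated tolerance.
The acceptance script reruns the same conditions from a single
command-line seed.
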