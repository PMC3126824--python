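# Methods

This note documents the models, defaults, and numerical choices behind
`optomaze`, and what the synthetic components do and do not emulate.

## Units and geometry

All stimulus parameters are in visual degrees; `ScreenGeometry`
(`pixels_per_degree`, default 2 px/°, 640×480 px, 60 Hz) is the single
degrees↔pixels conversion point. Temporal frequency is never an
independent parameter: it is derived as `tf = sf · |v|` from the
spatial frequency and velocity, which are treated as primary. (The
standard grating's printed parameter set is internally inconsistent —
0.016 cpd × 130 °/s = 2.08 Hz, not 3 Hz — so deriving tf from the pair
is the only self-consistent convention.)

## Stimulus rendering

*Gratings* are square waves (two uniform colors, not a sinusoid): each
pixel is exactly `fg_color` or `bg_color`, bars perpendicular to the
motion axis, per-frame phase advance `v · sf / fps` cycles, toroidal
wrap. The standard set is green (0,255,0) on black, 0.016 cpd,
130 °/s — Michelson contrast (255−0)/(255+0) = 1.

*Random-dot kinematograms*: `n_dots` dots, a fraction `coherence` of
which (signal dots) translate along the common direction; each noise
dot draws one uniform-random heading per lifespan rather than a
per-frame random walk — the simplest kinematics consistent with "% of
dots moving coherently", and stable frame to frame. Dot ages are
initialized uniformly over the lifespan so respawns do not flicker in
synchrony; expired dots respawn at uniform-random positions with age 0
(noise dots redraw their heading). Edges wrap toroidally so dot density
is constant; dots are opaque and, in combined stimuli, drawn after the
grating ("layered onto"). The standard dot set is 1500 dots of 13.8°
subtense, 10 s lifespan, 130 °/s.

*Equal-area shapes*: the square stamp is trimmed to exactly the pixel
count of the circle of the same nominal diameter (nearest-integer side
rounded up, corner pixels removed farthest-first with a deterministic
tie-break), so shape manipulations never change the covered area.

*Power-law textures* stand in for natural scenes, whose spectra carry
high energy at low spatial frequencies. White noise is filtered along
the **horizontal** frequency axis so the expected row power spectrum —
the axis the regularity metric measures — falls as `f^-exponent`
exactly; the base image is min-max rescaled to [0, 255] and translated
rigidly with toroidal wrap. Rows are mutually independent (no vertical
correlation structure); this is a spectral stand-in, not a naturalistic
image model.

Monitor refresh is represented only as `frame_rate_hz`; there is no
phosphor or flicker model, no gamma calibration, and "equiluminance"
means equal parameterized intensity, not photometric cd/m².

## Image-regularity metric

Frames are converted to luminance by the unweighted channel mean (the
movies are two- or three-color; perceptual weighting would add an
arbitrary choice without changing orderings). Every pixel row is
Fourier transformed and per-bin power `|F_k|²/width` is averaged over
all rows — averaging over rows rather than one scan line reduces
variance; a single-row variant is available by slicing before the call.
The movie spectrum is the mean ± s.e.m. over frames, and the regularity
metric is the peak over non-DC bins: DC is excluded because it encodes
mean luminance, not structure, and would otherwise dominate every
stimulus. Under this normalization Parseval's identity reads
`P_0 + P_{w/2} + 2·ΣP_middle = width · mean(lum²)`; the constant is
arbitrary for the meta-analysis (only a consistent scale matters) and
is documented here. Frequencies are reported in cycles per image width,
with a cycles-per-degree conversion available via the geometry.

The pipeline maps peak power to a dimensionless salience by dividing by
the peak power of a full-contrast sinusoid on the same screen
(`width · 127.5²/4`), giving ~0.17 for the standard grating.

## Maze model

Junction choices are i.i.d. Bernoulli(p) within and across flies — the
null behavioral model; the hardware reports population tallies only, so
momentum, alternation, and inter-fly interaction are deliberately out
of scope and nothing in real data that depends on them is probed by
these simulations. Fly loss is pre-choice Bernoulli exclusion (default
5%, configurable; the mechanism of real losses is unknown), independent
of behavior, so the conditional tube distribution is unchanged.
Direction-balanced experiments run half the mazes per direction with
per-maze seeds drawn once from the master seed; a baseline left/right
asymmetry enters the toward-stimulus probability with the sign of the
stimulus direction and cancels in expectation under balancing.

Inversion: each counted fly in (direction-corrected) tube N made N+4
of its 8 choices toward the stimulus, so pooled toward-choices are
binomial over 8×(flies) trials; `estimate_p` reports the point estimate
with a normal-approximation 95% CI (at the tool's typical scales the
trial counts are in the thousands, where the approximation's coverage
is within a point of nominal).

Strain presets are parameter conventions, not measurements: wild type
saturates at p_max = 0.60 (E[VR] up to 0.8) with gain 8; the
learning-mutant preset at p_max = 0.70 (E[VR] up to 1.6) with gain 12,
encoding its stronger response to high-contrast, highly structured
motion. Default experiment sizes mirror the assay: 8 mazes of 25 flies
(~200 flies per data point).

## Scoring and statistics

The maze is the statistical unit: per-maze VRs are direction-corrected
first, then pooled; s.e.m. is across mazes. Zero-count mazes are
excluded and logged, never scored 0 (a 0 would bias toward the null).

The normality screen is a Lilliefors test whose p-value comes from a
Monte-Carlo null (50 000 simulated samples per sample size, internally
seeded and cached) rather than approximation tables — reproducible,
table-free, and accurate in the far tail. The screen is applied at
α = 0.05 per comparison; samples below n = 5 default to the parametric
branch. Normal-looking samples get t-tests (one-sample vs zero, Welch
two-sample); others get Wilcoxon signed-rank / Mann–Whitney U — the
one-sample "U-test against zero" is not literally executable, so the
signed-rank test is its analogue. ANOVA is followed by Tukey HSD (the
standard all-pairs procedure for compact letter displays); letters are
assigned by insert-and-absorb so that groups share a letter iff not
significantly different. Pearson correlation tables flag significance
at P < 0.05 and report zero-variance pairs as missing.

`meta_fit` is OLS on a Vandermonde design; its "correlation" is defined
as the Pearson r between fitted and observed responses (for the linear
model this equals the x–y correlation up to sign) — the published fit
legends do not disambiguate among r, R, and fitted-observed
correlation, so the choice is stated here once and used everywhere.
Coefficient standard errors and 95% CIs come from the OLS covariance.

## Problem sizes and determinism

Everything is deterministic given a master seed; per-stage and per-maze
seeds are spawned from it in a fixed documented order. Test-suite and
acceptance computations use desk-scale sizes chosen so Monte-Carlo
standard errors sit well inside the bands being checked: 1000 mazes of
25 flies for mean-VR checks (s.e. ≈ 0.009 VR units), 100 replications
of 50-maze experiments for coverage, 1000 replications for the VR-test
type-I band at α = 0.01, and 10⁴ replications for the Lilliefors
type-I band (rate s.e. ≈ 0.002 against a ±0.01 band).

## Known limitations

- The simulator reproduces the binomial skeleton of the assay, not real
  fly behavior: passing tests validate the pipeline's arithmetic and
  calibration, not any biological claim.
- The spectral metric is 1-D (horizontal) by design; vertical structure
  and temporal-frequency spectra are out of scope.
- At the default geometry the standard 1500-dot/13.8° field covers ~95%
  of the screen; after matching mean luminance to the standard grating,
  its attainable spectral contrast is small, so its regularity peak
  falls below that of a low-frequency-heavy power-law texture. The
  three stimulus families' peak ordering is therefore
  grating ≫ texture > dots under these conditions.
- Real-time display, hardware sync, and photometric calibration are not
  modeled.
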