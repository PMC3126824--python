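# optomaze

Desk-scale re-implementation of an automated choice-maze paradigm for
*Drosophila* visual psychophysics: parameterized moving-stimulus
generation, a spectral image-regularity metric, an agent-based simulator
of fly populations walking serial binary-choice mazes, the Visual
Response (VR) population statistic, and its statistical pipeline. Every
stage of the assay is runnable and testable without any hardware — the
simulator stands in for the infra-red tube counters.

It is written for behavioral neurogeneticists and visual
psychophysicists who want to prototype stimulus batteries, power
analyses, and scoring pipelines for population choice-maze assays.

## The assay and its statistic

Populations of ~25 flies walk through a maze of 8 sequential
T-junctions while a moving stimulus is displayed beneath them. The
maze's 9 ranked exit tubes are indexed N = −4..+4; a fly's exit tube
encodes its net turning bias. The population readout is the **Visual
Response**

    VR = Σ_N N · (# flies in tube N) / (total # flies),  N = −4..+4,

sign-corrected by the stimulus direction so that following the motion is
positive, and averaged across mazes (the maze is the statistical unit;
runs are balanced for image direction, which cancels any
stimulus-independent turning bias).

The simulator models each counted fly as making 8 independent
Bernoulli(p) choices toward the stimulus, so the tube distribution is
Binomial(8, p) shifted to −4..+4 and **E[VR] = 4(2p − 1)** — a closed
form the test suite checks against exhaustive enumeration of all 2⁸
choice paths. The per-junction probability p comes from a saturating
psychometric function of stimulus salience,
`p = 0.5 + (p_max − 0.5)(1 − e^{−gain·s})`, with strain-specific
parameters (the learning-mutant preset saturates higher and faster than
wild type).

**Image regularity** of a movie is quantified spectrally: frames are
converted to luminance, each pixel row is Fourier transformed, per-bin
power |F_k|²/width is averaged over rows and frames, and the metric is
the peak of the mean spectrum with DC excluded — large for a periodic
grating, small for broadband dot fields, and insensitive to the motion
itself (power discards phase). VR-vs-peak-power meta-analysis models
(a quadratic for the mutant, a line for wild type) are fit by OLS.

## Worked example

```python
from optomaze import (ExperimentConfig, GratingSpec, WILD_TYPE, DUNCE1,
                      run_pipeline)

config = ExperimentConfig(
    stimulus=GratingSpec(),          # standard green/black drifting grating
    strains=(WILD_TYPE, DUNCE1),
    n_mazes=8, n_flies_per_maze=25, master_seed=7,
)
report = run_pipeline(config)
```

which renders the movie, measures its regularity, simulates 8
direction-balanced mazes per strain, scores VR, and tests it. With the
seed above it prints (via the `optomaze run` CLI):

```
wild_type: VR = 0.493 ± 0.103 (p = 0.002)
dunce1:    VR = 1.169 ± 0.084 (p = 2.3e-06)
```

The grating's normalized salience is 0.172 with its spectral peak at
5 cycles/image-width (a 125-px period on a 640-px screen). Both strains
respond significantly to the standard grating and the mutant preset
responds roughly twice as strongly, with the between-strain Welch test
at p ≈ 1.9e-04 — the qualitative phenotype the simulator's parameter
sets encode.

The same stages are exposed as CLI commands: `optomaze render`,
`spectrum`, `simulate`, `score`, `stats`, `metafit`, and `run`.

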