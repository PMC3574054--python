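# Methods

This note documents the models implemented in `headingbias`, the
defaults and numerical choices, and what the synthetic data do and do
not establish.

## Conventions

Headings are degrees in the earth-horizontal plane, canonical range
(−180, 180], 0° straight forward, positive clockwise from above
(rightward). All wrapping goes through `angles.wrap_deg`; note the
closed upper end (`wrap(-180) == 180`). The head-fixed frame is x
forward, y leftward, z up, so the unit vector of a heading θ is
(cos θ, −sin θ, 0).

Circular statistics use the trigonometric-moment definitions: the mean
direction is atan2 of mean sine/cosine and the circular SD is
√(−2 ln R̄) in degrees, the wrapped-normal-equivalent SD, which agrees
with the linear SD at small dispersion. When R̄ is within 1e−9 of 1 the
log formula loses all precision, so the implementation switches to the
algebraically equivalent small-angle form √(mean (2 sin(Δ/2))²) over
deviations Δ from the mean direction. A mean resultant below 1e−9 is
reported as a degenerate input rather than a number.

## Stimulus kinematics

Translations have a Gaussian speed profile with SD = duration/6,
truncated to zero outside the movement window (±3 SD), and amplitude
scaled so the speed integral equals the displacement. The duration/6
choice is the one under which a 1 s, 13 cm translation reproduces the
standard printed peaks (≈0.31 m/s, ≈1.14 m/s²) simultaneously; the
truncation discontinuity in acceleration at the window edges is
~0.3% of peak speed and is ignored. Peak velocity and acceleration are
computed in closed form; `extremal_accel_times` locates the
acceleration extrema numerically (bounded scalar minimization,
xatol 1e−12) and exists to cross-check the closed form.

## Synthetic observers

*Identification*: response = wrap(stimulus + b(θ) + ε), with
b(θ) = A sin 2θ (default A = 6°, the magnitude of the largest
behavioral biases; zeros at 0/±90/180 and overestimation forward,
underestimation backward) and ε wrapped-normal with heading-dependent
SD (default constant 5°). An optional lapse rate replaces the response
with a uniform draw, emulating accidental button presses. The default
design is 48 headings (0°–352.5°, step 7.5°) × 5 blocks × 2
repetitions = 480 trials per subject; a 12-subject cohort therefore
yields 5760 measurements and a 6-subject cohort 2880.

*Discrimination*: a 2AFC observer responds "clockwise" with probability
Φ((s − PSE_true)/JND_true). This is the standard cumulative-Gaussian
signal-detection model; it has no lapse by default.

What the generator does **not** emulate: response-dial anchoring
(reduced bias/variability at marked reference directions), the oblique
effect in variability, inter-subject heterogeneity beyond independent
noise, left/right asymmetries, and adaptation across staircase blocks.
Passing recovery tests therefore show the estimators are correct and
unbiased under the stated generative model, not that real data meet
that model.

## Identification analysis

Per heading, responses pass a single-pass Chauvenet-style rule:
exclude responses deviating more than 2.4 circular SD from the circular
mean of all presentations (typically ten). The rule is deliberately not
iterated, and uses circular moments throughout. A 1e−9° absolute slack
is added to the cutoff so floating-point error in the mean cannot
exclude a perfectly concentrated sample whose SD is exactly zero.
Groups with fewer than three responses skip the filter; headings whose
kept responses have a vanishing resultant are flagged, not dropped.

For cross-task comparison the mean-response curve is interpolated with
a degree-12 polynomial. Responses are first unwrapped to
stimulus + wrapped bias — continuous and near the identity line — since
a polynomial cannot represent the 360° discontinuity. Evaluation
outside the fitted stimulus range raises an error; polynomial behavior
beyond the data is meaningless and extrapolation is refused rather than
guessed.

## Staircases and psychometric fitting

Transformed up-down rules: n_up consecutive "less-than" responses move
the stimulus up one step, n_down consecutive "greater-than" responses
move it down; the consecutive-response counters reset when a step is
taken (reset-on-step, one of two conventions in the literature; chosen
and fixed here). With step size small relative to the JND these rules
asymptotically track the stimulus level where the probability of the
stepping sequence is ½: the 50% point for 1U1D and the
√½ ≈ 70.7% / 1 − √½ ≈ 29.3% points for 1U2D / 2U1D.

A block interleaves two tracks of the same rule in strict alternation,
descending from +offset and ascending from −offset (defaults: 35
trials/track and ±26° for 1U1D; 40 trials/track and ±18° for the
transformed rules, started at the 1U1D PSE estimate in the full
pipeline). A trial is flagged a reversal when it changes its track's
step direction; the PSE estimate is the mean reversal level after
discarding the first four reversals per track. Simulated at the
default settings the three rules track the 50.2% / 29.1% / 71.2%
points (500 blocks, observer JND 8°) — the small offsets from the
asymptotic values are finite-step, finite-length effects.

The psychometric function P(cw|x) = λ/2 + (1−λ) Φ((x − PSE)/JND) is
fit by maximum likelihood (binomial likelihood over grouped levels,
Nelder-Mead on (PSE, log JND), λ = 0 by default with an optional fixed
lapse). The tests cross-check this fit against an independent probit
GLM route.

## Population-vector decoding

The afferent model is linear: rate = s (F·P) + d0 with F in g. The
response used for decoding is the peak-to-trough modulation — the rate
at maximum acceleration minus the rate at maximum deceleration — which
removes gravity and the resting discharge exactly and equals
2 s a_peak (u(θ)·P). Rates are not rectified by default (the linear
model is applied as stated; a rectify flag exists for sensitivity
analysis, and with rectification the gravity cancellation no longer
holds). Decoded angle = atan2 of the horizontal projection of
Σ rᵢ Pᵢ. Consequences, all under test: decoded angles are invariant to
uniform sensitivity scaling, to resting-discharge changes, and to
gravity magnitude; bilateral mirror symmetry forces zero bias at 0° and
180° (numerically ~1e−13° from summation order).

Generator defaults for afferent-like populations: 313 neurons,
horizontal-projection azimuths von Mises around +50° with 30° spread
(mirrored bilaterally to supply −50°), elevations uniform in ±60°,
sensitivity ≈ 35 spikes·s⁻¹/g and resting discharge ≈ 90 spikes/s
(plausible otolith-afferent magnitudes; they cancel in the decoder, so
only the azimuth distribution shapes the bias curve). The 30° spread
gives the pronounced ±50° peaks with troughs at 0/180 (~4:1 density
contrast) that characterize the afferent distribution; broader spreads
wash the structure out. Cortical-like (MSTd analog) populations are
horizontal cosine-tuned units with preferred directions mixed at ±90°,
built as exact mirror pairs; the uniform special case (spread → ∞)
places the base azimuths on an even grid, making "uniform ⇒ unbiased"
a property of the construction rather than of sampling noise.

## Bayesian observer

Posterior ∝ wrapped-Gaussian likelihood × wrapped bimodal prior, both
evaluated on a 0.1° grid over (−180, 180] (wrapping sums image terms
k = −3…3, ample for SDs up to ~100°). The likelihood SD is evaluated at
the *stimulus* angle (the simplest reading of an eccentricity-dependent
sensory noise; evaluating at the hypothesis angle is a documented
alternative not implemented). The default node tables for the
likelihood SD (vestibular 12→38° and visual 4→20° from 0° to 180°) are
illustrative, editable configuration — no numeric table of these values
is published.

The MAP estimate is the posterior argmax; plateau ties (within 1e−9
relative) resolve toward the stimulus, and an exactly symmetric pair of
maxima returns the stimulus itself, so bias is zero at 0° and 180°.
`predict_bias_curve` computes only positive heading magnitudes and
antisymmetrizes, which makes bias(−θ) = −bias(θ) exact by construction
and halves the work.

σ_prior is fit by dense scan at 0.5° resolution over a default range of
5–120° (covering priors from strongly attracting to effectively flat),
minimizing the residual sum of squares against the observed bias curve;
R² = 1 − SS_res/SS_tot about the mean observed bias and may be
negative. Scan ties resolve to the largest σ (the flattest prior
consistent with the data), so an all-zero bias curve lands on the flat
boundary, which is flagged. Noiseless self-consistency recovers
σ_prior ∈ {15, 30, 50, 80}° exactly at scan resolution; with 2°
observation noise the mean recovered value over 100 seeds stays within
a few percent, though single-fit scatter grows sharply for broad priors
(σ = 80° predicts ≤ 2° of bias, close to the noise floor).

## Comparison statistics

Spearman rank correlation (average ranks, large-sample two-sided p) via
scipy; type II regression as the standardized major axis
sign(r)·SD(y)/SD(x) by default (scale-symmetric and standard for
errors-in-both-variables comparisons; the major-axis variant is a
flag); R² against an external prediction as 1 − SS_res/SS_tot about the
observed mean (an about-zero variant is available since the centering
convention is ambiguous in parts of the literature). The 0°/180°
headings are excluded from cross-task correlations by the callers, as
both tasks are unbiased there by symmetry.

## Problem sizes

Defaults are desk-scale: 12 subjects × 480 trials, 500-block staircase
simulations, 313-neuron populations (626 after mirroring), 0.1°
posterior grids and 0.5° prior scans. The full pipeline runs in about a
second; the complete test suite in about two minutes.

## Known limitations

- The generator's bias function is a pure sinusoid; real bias curves
  are asymmetric between left/right and forward/backward, which this
  package measures but does not emulate.
- The afferent and cortical populations are distributional stand-ins
  with the stated peak structure, not the published datasets; decoded
  curves are therefore qualitatively, not quantitatively, comparable to
  figures derived from real recordings.
- The degree-12 response-curve fit is only defined on the sampled
  stimulus range; with the default design the wrap region near ±180° is
  inside the domain only up to the outermost sampled headings.
- The Bayesian model is exactly symmetric; it cannot represent
  hemispheric asymmetries and will fit asymmetric data with attenuated
  σ_prior and low R² by design.
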