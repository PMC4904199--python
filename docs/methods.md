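# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the `alphalight` package.

## The scientific question and the analysis chain

Hemispheric asymmetry in posterior alpha-band (8–13 Hz) activity is an
established electrophysiological correlate of the spatial distribution
of visual attention: attending one hemifield suppresses alpha over the
contralateral parieto-occipital cortex. The pipeline asks whether prior
exposure to brighter blue-enriched light — an alerting stimulus acting
through intrinsically photosensitive retinal ganglion cells — biases
this system: raising right-hemisphere alpha, speeding responses to
left-hemifield targets, and reshaping the usual alpha→RT coupling.

The chain is: epoched EEG → single-trial alpha envelope → per-session
electrode selection → trial screening → multilevel models with
likelihood-ratio tests → Sobel mediation.

## Alpha envelope estimation

Epochs (−700…1200 ms around coherent-motion onset, 500 Hz) are
baselined to the mean of −100…0 ms, band-passed to 8–13 Hz with a
4th-order Butterworth applied forward and backward (zero net phase),
rectified sample-wise, trimmed by 200 ms at each edge to discard filter
transients, and averaged inside 100 ms windows advancing in 50 ms
steps. Windows are half-open [t, t+100) and contribute only when fully
inside the trimmed support, so the usable envelope spans −500…1000 ms
with centres at −450, −400, …, 950 ms. "Alpha power" always means this
rectified, smoothed amplitude envelope in µV — never its square. The
pre-target summary is the mean over [−500, 0) ms and over an electrode
pool; for a pure sinusoid of amplitude A the summary is 2A/π.

Windows are centred on grid times; whether a centred or left-aligned
convention is "correct" is underdetermined, and the choice only
relabels the grid.

A broad-band 35 Hz low-pass and average re-referencing are available
for recorded data; synthetic data are generated band-limited and
referenced, so these are no-ops in the synthetic path.

## Electrode selection

Candidates are the 16 lateral parieto-occipital sites (left: P1, P3,
P5, P7, PO3, PO7, PO9, O1; right: the even homologues). Per session the
trial-averaged envelope is computed separately for targets
contralateral versus ipsilateral to each electrode's hemisphere;
desynchronisation is the 50–600 ms post-target mean minus the −500…0 ms
pre-target mean of the same average. Electrodes are ranked by the
contralateral-minus-ipsilateral difference ascending (strongest
contralateral suppression first) and the top 4 per hemisphere are
selected, with ties broken by candidate-list order. Ranking by absolute
magnitude is available as a configuration alternative; the signed
criterion is the default because attention-induced suppression is
directional. Trials entering the selection average pass the
desynchronisation-purpose artifact screen (−100 ms to RT+100 ms).

The cumulative light topography (High−Low) + (High−Medium) +
(Medium−Low) — algebraically 2·(High−Low) — is provided for
visualising where light modulates alpha.

## Screening

Rules apply in a fixed order: (1) trials without a response, responses
faster than 200 ms or slower than 1000 ms; (2) trials whose broad-band
voltage exceeds ±100 µV on any channel within −500…0 ms (pre-target
analyses) or within −100 ms…RT+100 ms (desynchronisation analyses);
(3) natural-log transform of alpha summaries (positively skewed to
near-normal); (4) a single-pass screen removing observations more than
3 SD from their participant x light-condition (x hemisphere, for alpha)
cell mean, computed on the model's dependent variable — RT in ms, log
alpha for alpha models. Single-pass means the rule is applied once, not
iterated; degenerate cells (SD = 0) remove nothing. Outliers are
defined on the log-alpha scale (raw available by configuration) because
that is the modelled variable.

## Multilevel models

All models are fit by maximum likelihood (not REML) because every
reported test is a likelihood-ratio test between nested fixed-effect
structures: χ² = 2·ΔlogLik with df equal to the parameter difference.
Factor reference levels are fixed (low light, right hemifield, left
hemisphere, lower vertical field); time-on-task enters as the trial
number rescaled to [0, 1], which leaves LRTs invariant. Design matrices
(treatment coding, interaction columns, random-effect and
variance-component designs) are constructed by the package; the
numerical optimisation is delegated to statsmodels `MixedLM`. The
optimiser runs lbfgs first, falls back to bfgs and powell, and always
applies a warm-started polish step — converged-but-suboptimal solutions
otherwise occasionally break the likelihood ordering of nested models.
Non-convergence is recorded in the result, never silently accepted.

Random structure: by-participant intercepts plus by-participant slopes
(hemifield and pre-target alpha for RT models); for alpha outcomes,
hemisphere nested within participant as a variance component. The
counterbalancing-order level of the nesting is omitted from the fitted
random structure: with a single grouping factor it is not expressible
above participant, it has only 6 levels, and in the balanced design
participant intercepts absorb it. Condition order is carried in every
table for auditability.

Random-structure pruning starts from the maximal candidate set
(recording its convergence), then tests each candidate slope in listed
order by an LRT between the model with and without the slope, retaining
it only when p < 0.05 *and* the larger model converges — the numeric
criterion the retention rule needs but which "improved the fit" leaves
open. The audit trail records every comparison. The boundary-corrected
null distribution of variance-component LRTs is not used; the plain χ²
reference is conservative, which matches the pruning procedure's
intent.

Follow-up pairwise light contrasts take estimates and SEs from the
fitted fixed-effect covariance, use the normal (z) reference — per-cell
trial counts are in the hundreds — and adjust the family by single-step
max-|t| under the multivariate-normal distribution of the contrast
statistics (Bonferroni–Holm available). The max-|t| probability is
evaluated by deterministic-seeded quadrature so reports are exactly
reproducible.

The light-awareness check uses a bootstrapped Yuen–Welch test: 20%
trimmed means, winsorized variances, and a percentile bootstrap of the
statistic after centring each sample at its own trimmed mean.

## Mediation

Mediation requires a binary treatment, so only low versus high light
enters. Three multilevel fits on left-hemifield trials give the paths:
mediator (right-hemisphere log alpha, standardised) on treatment (a);
outcome on treatment (c); outcome on treatment plus mediator (b, c′).
Path SEs are the fixed-effect SEs of those fits. The indirect effect is
a·b with first-order Sobel SE √(b²SE²ₐ + a²SE²_b) (second-order variant
by configuration); z = a·b/SE with a two-sided normal p. Mediation is
"inconsistent" when c′ and a·b have opposite signs. The mediator is the
trial-level alpha summary (session means by configuration);
standardisation is reported and leaves z and p invariant.

## The synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions the package is calibrated to.

Design: 24 participants x 3 light levels in 6 counterbalanced orders
(4 participants each); 336 trials per session; each 48-trial block
contains the 24 trial types (3 incoherent-motion delays x 4 quadrants x
2 directions) exactly twice, in a seeded permutation. Coherent-dot
speed follows displacement x frame rate (0.282° x 21.25 fps ≈ 6°/s).

EEG: each trial is 1/f (exponent 1) Gaussian background noise (5 µV
RMS) on all 64 channels, plus an alpha oscillation (carrier drawn
uniformly in 9–11 Hz, random phase) projected with weight 1.0 onto four
"true" electrodes per hemisphere (P5, P7, PO7, O1 / P6, P8, PO8, O2),
0.5 onto the remaining candidates, and 0 elsewhere — giving the
selection algorithm a recoverable ground truth. The oscillation
amplitude per trial and hemisphere is

    A = alpha_base · gain(light, hemisphere)
        · exp(subject + hemisphere-offset + drift + noise)

with `alpha_base` 10 µV; log gains (0, 0.04, 0.07) on the right and
(0, 0.01, 0.03) on the left across low/medium/high — the generative
counterparts of the reported per-hemisphere light contrasts on log
alpha; a time-on-task drift of 0.2 log units across the session
(centred); lognormal trial noise split into a bilaterally shared
component (σ = 0.30) and hemisphere-specific components (σ = 0.25), so
left and right alpha co-fluctuate trial to trial (r ≈ 0.6) — without
this the hemisphere-interchangeability of the alpha→RT coupling seen in
real data cannot arise; and participant-level offsets (σ = 0.15 common,
0.05 per hemisphere). From 50 ms to 600 ms after target onset the
amplitude contralateral to the target drops by `desync_depth` (0.3)
with 100 ms raised-cosine ramps — a smooth stand-in that matches the
selection window without claiming fidelity to real desynchronisation
dynamics.

Behaviour: response times follow

    RT = 499 + subject + I(right)·(hemifield drift) + I(left)·light_effect
         + slope(light)·alpha_dev + residual

with left-hemifield light effects (0, −2, −9) ms chosen so the
condition means land on 499/497/490 ms; alpha→RT coupling slopes
(8.0, 5.2, 3.0) ms per log-unit across light levels, whose pairwise
differences reproduce the reported coupling-suppression contrasts;
`alpha_dev` the session-demeaned realised log pooled envelope (demeaning
keeps condition means exactly calibrated); a hemifield-specific
time-on-task drift of 12 ms full range (right-hemifield responses
slower early, the advantage waning); residual σ 50 ms; and
participant-level SDs of 5 ms (intercept), 3 ms (hemifield) and 1.5 ms
(alpha slope). The subject SDs are deliberately small so that
condition-mean calibration at 24 participants carries ~1–2 ms
Monte-Carlo error, consistent with the ~1.7 ms condition-mean SEs the
design targets. Misses occur uniformly at 2.6% (matching 97.4% ceiling
accuracy; the generator makes no claim about the real miss mechanism),
and 3% of trials receive a >100 µV pre-target transient for the
artifact screen to catch.

The realised per-trial envelopes and the coupling variable are written
into the trial table (`log_alpha_true_*`, `alpha_dev`) as ground truth
for recovery tests. Behaviour-only simulation (`eeg=False`) draws from
a stream separate from the EEG noise, so trial tables are identical
between modes.

What the generator does **not** emulate: volume conduction and realistic
topography beyond the two-level weighting; non-alpha rhythms and evoked
potentials; eye movements and blinks (the paradigm excludes them at
source); RT distributions' right skew (residuals are Gaussian);
condition-order carry-over effects. Passing tests therefore demonstrate
that the *analysis chain* recovers the effects it assumes, not that the
generator reproduces real EEG.

## Problem sizes and runtime choices

The full synthetic study (72 sessions with EEG) runs in a few minutes;
tests that need many replicates scale the problem down rather than gate
themselves: parameter recovery uses 50 behaviour-only replicates of the
full design; random-structure pruning recovery uses 12 participants and
reduced sessions; LRT type-I calibration uses the fixed-effects-only
special case of the same fitting routine; electrode-selection recovery
uses candidate-only channel sets and 3-block sessions. The chosen sizes
are stated in the tests themselves.

## Known limitations

* The grouping structure supports one clustering factor plus nested
  variance components; crossed random factors are out of scope.
* Sobel inference is normal-theory; bootstrap mediation CIs are not
  implemented.
* LRTs on variance components use the unadjusted χ² reference
  (conservative at the boundary).
* The synthetic path never exercises channel interpolation or
  re-referencing beyond no-ops; applying the pipeline to recorded data
  would require those preprocessing steps upstream.
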