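# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `phosvpl`.

## Phosphene field

The field emulates the retinotopy of early visual cortex: percepts are
smaller and more tightly packed at the point of regard. Local density
follows a cortical-magnification-style profile M(e) = 1/(e + e₂), with
eccentricity *e* in degrees and half-saturation eccentricity **e₂ = 2°**
by default (smaller e₂ → stronger central weighting). Centers are drawn by
rejection sampling inside a disc of diameter `field_span` (default **80°**,
so the map covers the whole usable visual field on a ~40°-wide monitor);
one phosphene is always anchored at the origin, which also fixes the
degenerate n = 1 case. The exact layout algorithm of any published map is
not reproduced; the profile above is chosen because it reproduces the
qualitative structure with two interpretable knobs.

Each phosphene's Gaussian radius is `sigma_fraction` (default **0.5**)
times its mean distance to its 3 nearest neighbors, so sizes track local
spacing and grow with eccentricity up to sampling jitter. Sampling is
fully seed-controlled; the same seed reproduces a map file byte for byte.

Degrees↔pixels conversion needs a viewing distance, which is not a
physical measurement here: `deg_per_px` is an explicit configuration value
(default 0.025 °/px, i.e. a 1600-px monitor subtending 40°), never
inferred. Screen coordinates are pixels with origin top-left, x rightward,
y downward; field coordinates are gaze-centered degrees with the same axis
orientation.

## Veridical-encoding renderer

Each phosphene first acts as a filter — a Gaussian-weighted mean of image
luminance with its own σ, truncated at 3σ (a uniform disc of radius 2σ is
available as a config switch) — and then as a display, a unit-peak 2D
Gaussian scaled by the sampled luminance. Because no blend rule is implied
by the encoding itself, overlapping Gaussians are **summed and clipped**
to [0, 1]; max-compositing would be the main alternative and changes
little at these densities. The filter/display pair shares one σ, making
the encoding self-consistent: a uniform scene renders back at its own
luminance under every phosphene.

Color is reduced to luminance by Rec. 601 luma before rendering; nothing
downstream sees chroma. Rendering is offline (frame stack + gaze log in,
frames out). In a live setup the pattern would be re-centered on the most
recently read gaze sample at every refresh; the offline equivalent is
hold-last-value for invalid gaze samples, flagged per frame, with no
interpolation.

The frame scheduler maps video frames onto monitor refreshes with a
fractional accumulator: at ratio r = monitor_hz / video_fps each frame is
held ⌊r⌋ or ⌈r⌉ refreshes and the running error never exceeds one refresh.
At 144 Hz over 23.96 fps (r = 6.01) this yields runs of 6-repeats with a
7-repeat roughly every 4.2 s — the cadence a synchronized playback loop
needs to stay locked to the video clock.

## Reading psychometrics

Scoring is positional: response word *i* against sentence word *i*, case-
and punctuation-insensitive. This is a deterministic stand-in for live
experimenter scoring; it gives no credit for transpositions, which keeps
the statistic conservative. Accuracy is 100·correct/total per print size;
speed is correct words per minute; pooled values are unweighted means over
print sizes, matching a design with equal trials per size.

Equivalent acuity comes from a logistic in print size (logMAR) with
asymptotes fixed at 0 and 100%, fitted by maximum likelihood on word-level
Bernoulli counts (a binomial GLM with logit link), so the midpoint is
exactly the 50% point. With only two sentences per print size per test,
the word-count likelihood extracts substantially more information than
least squares on percentages (which remains available via
`method="ls"`). Whether asymptotes should instead be estimated is an open
modeling choice; fixing them is the stronger assumption but is what makes
"the 50% level" well defined at these trial counts.

Degenerate profiles are censored, not failed: all-correct → acuity better
than the smallest size tested (reported as that bound, flagged `low`),
all-wrong → flagged `high`. Censored fits are excluded from downstream
span deltas, with the dropped-span count reported. Quasi-separated data
(a 0→100% step) falls back to a bounded likelihood profile over the
midpoint with the slope capped at 100/logMAR and is marked non-converged.
Uncertainty, when requested, is a sentence-level nonparametric bootstrap
(default 1000 resamples, seeded percentile interval); no analytic CI is
attempted because the per-test word counts are small.

Default print sizes are logMAR 0.9–1.4 in 0.1 steps (Snellen 20/160 to
20/500).

## Syncopated schedule and the synchronous decoder

Each subject has 23 sessions: an intake acuity check, 21 video sessions,
and a final reading-test-only day. Eight potential reading-test positions
sit one per three videos; a subject takes six of them — always the first
and last — and skips two non-adjacent intermediate positions, so
consecutive tests bound three 3-video (RvvvR) and two 6-video (RvvvvvvR)
spans that together account for all 21 videos. Across the cohort, skips
are balanced so each intermediate position keeps 5–6 of 8 subjects.
`build_schedule` finds such an assignment by seeded randomized search;
a fixed admissible assignment ships as `data/default_schedule.csv`
(generated by `build_schedule(8, seed=0)`) so downstream results do not
depend on regeneration.

On a test day the reading test precedes the video, and a test is assumed
to influence only *later* measurements, never its own. Under a constant
per-session improvement β_R from each reading test and β_V from each
video, span improvements satisfy y₁ = 3β_V + β_R and y₂ = 6β_V + β_R,
inverting to β_V = (y₂ − y₁)/3 and β_R = 2y₁ − y₂. The default decodes
the pooled span means (the population-level headline); `per_subject=True`
decodes each subject's (mean y₁, mean y₂) pair to expose the spread.
Gain attribution multiplies each rate by its session count — 5 influencing
reading tests and 21 videos under the no-self-influence convention; a
6-reading-test convention is equally computable and both are left to the
caller, since the convention is not uniquely determined by the design.

As a model-free cross-check, `rates_from_regression` regresses acuity on
cumulative minutes spent in each task (OLS; reading-only, video-only, and
joint models) and converts the univariate per-minute slopes to per-session
rates via the mean session lengths t_reading = 13.6 min and
t_video = 24.7 min.

Reports round rates to 3 decimals and acuities to 2, matching their
measurement precision.

## Scan paths

Path length sums Euclidean distances between consecutive valid gaze
samples, divided by screen width in pixels. No saccade detection or
smoothing is applied by default (an optional odd-kernel median filter
exists); invalid samples are dropped, and sample pairs separated by more
than 100 ms (configurable) are treated as gaps contributing zero distance,
so blinks cannot inflate the total. The between-task correlation first
removes each subject's mean from both series, then computes Pearson's r on
the pooled residuals with df = n − 2; this isolates session-to-session
covariation (e.g. motivation) from stable subject differences. Zero-
variance residuals return an undefined-correlation flag rather than NaN
arithmetic.

## Synthetic cohorts and what they do (not) show

The generator draws each subject's baseline acuity from
N(**1.28**, **0.04²**) logMAR and evolves true acuity additively:
**β_R = −0.015** per reading test taken and **β_V = −0.01/3** per video —
the same linear no-forgetting dynamics the decoder assumes (an exponential-
saturation variant, off by default, supports misspecification
experiments). At each scheduled test, word responses are Bernoulli draws
from a logistic with slope **15/logMAR** around the current true acuity:
6 print sizes × 2 sentences × 12 words, mirroring the reading-test design.
Sentence durations are gamma per-word reading times (mean 5 s/word
phosphene view, 0.43 s natural view; shape 4), placing pooled phosphene
speeds in the single-digit-WPM regime — an anchor, not a fitted target.
Measurement noise is word-level (Bernoulli) by default; an additive
per-test acuity noise variant (`noise_model="additive"`, default sd 0.04,
taken from the between-subject spread for lack of a within-subject
estimate) carries exact expected word counts so that its noiseless limit
recovers the generating rates to machine precision.

The recovery harness runs generate → fit → spans → decode per replicate
and reports bias, RMSE, the empirical coverage of per-subject t-intervals,
the |β_R| > |β_V| ordering fraction, and the acuity-fit error against the
latent truth. Under the default conditions the decoder is unbiased and
coverage is nominal, but the per-replicate ordering fraction is ~0.8: the
decoded β̂_R has a standard error (~0.012 at these trial counts) comparable
to the gap |β_R| − |β_V| ≈ 0.012, so a single 8-subject study separates
the two rates in sign and rough magnitude but cannot guarantee the
ordering; that is a property of the design's power, not of the estimator.

What passing tests show: the pipeline's estimators are correct and
unbiased *under the generator's assumptions*. What they do not show:
robustness to the structure real data adds — forgetting between sessions,
subject-specific psychometric slopes, serial correlation in responses,
fatigue, or gaze-dependent reading strategies. The saturation and additive-
noise switches exist precisely to start probing those gaps.

## Numerical conventions

- Improvements are *negative* logMAR changes throughout (lower = better).
- Gaussian footprints truncate at 3σ; rendered sums clip to [0, 1].
- The scheduler accumulator adds a 1e-9 guard before flooring so exact
  integer ratios are not perturbed by binary round-off.
- All randomness flows through `numpy.random.default_rng` seeds; every
  generator and the schedule builder are deterministic per seed.
- Monte-Carlo sizes (200 recovery replicates, 500 fit replicates, 10⁴
  decoder identity draws) were chosen to bound the relevant standard
  errors well below the assertion tolerances while keeping the full suite
  in the low minutes on one CPU.
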