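# Methods

## Model conventions

The recursion is the standard RSA ladder (literal listener → softmax
speaker → pragmatic listener) over worlds `w ∈ {0..N}` with `N = 3` by
default, extended in two ways: the speaker has a *knowledge state* (access
`a`, observed count `o`), and the listener is uncertain which *alternative
set* the speaker draws from.  Conventions where the mathematics leaves
choices open:

- **Rationality α.** The softmax speaker is written with an explicit
  sharpness parameter; α = 1 is the plain exponential-utility speaker and
  α = 0 a speaker indifferent among assertable utterances.  The default is
  α = 1.  The condition table reported throughout the examples uses α = 3,
  at which both full-knowledge cells round to 98%.  No fitting to
  behavioral data is performed anywhere in the package.
- **Observation law.** The `a` examined objects are a uniformly random
  subset drawn without replacement, so `P(o | w, a)` is hypergeometric.
  Exchangeability of indistinguishable objects forces this law once "the
  speaker examined a subset" is taken literally.
- **Speaker belief.** The knowledge state's belief over worlds is the
  Bayesian update of the world prior by the hypergeometric likelihood —
  not a uniform distribution over the compatible worlds.  With a uniform
  prior on {0..3} and a = 2, observing o = 2 gives belief (1/4, 3/4) over
  {2, 3}: seeing both examined objects with the property already favors
  the all-world.
- **Mute states.** A state where every alternative is false in some
  belief-supported world (e.g., a = 2, o = 0: no quantifier in
  {none, some, all} is assertable over support {0, 1}) has no defined
  softmax; it is flagged and contributes zero mass to the L1 sum.  This is
  the unique convention keeping L1 a proper conditional on "the speaker
  said u".
- **Numerals** are lower-bounded (⟦two⟧ = {2, 3}) and the inventory stops
  at N — no larger numeral is consistent with the scenario.  Exact
  readings emerge pragmatically, not lexically.
- **Numerics.** All products are accumulated in log space and normalized
  by log-sum-exp.  Degenerate priors are allowed; an utterance whose
  meaning misses the prior's support raises an explicit error rather than
  producing NaNs.  The core module is fully deterministic.

The partial-knowledge / no-numerals cell (5/8 = 0.625 under a uniform
prior) is α-invariant: "some" is the only assertable utterance in every
non-mute partial state, so the softmax cancels.  This makes it a sharp
internal consistency check, and the package treats the partial-cell
predictions as ordinal (with-numerals > no-numerals; interaction sign)
rather than as point targets.

## Synthetic experiment generator

The generator emulates the factorial rating paradigm: a between-subject
exposure condition (whether filler trials habituate the listener to
numeral use), a within-subject knowledgeability condition, 8 target trials
(4 partial / 4 full) and 24 exposure trials per participant, pseudo-random
order with the first trial an exposure trial and no two targets adjacent
(target positions are sampled uniformly over the valid layouts via the
non-adjacent-combination bijection), and a 0–100 rating of the probability
that *all* objects have the property.  Analyses use the complement
(`not_all_rating = 100 − rating`).

Ratings are a cell mean plus Gaussian participant, item and residual
components, **clipped** to [0, 100].  Clipping (rather than re-drawing
out-of-range values) is chosen because bounded rating scales pile
responses up at the endpoints, and because it keeps the boundary bias
small and analytically tractable: the expected rating is the
censored-normal mean, implemented in `expected_cell_means` as a
closed-form oracle independent of the sampling path.  With default
spread, boundary clipping compresses the generated effects relative to
the nominal cell means by several points; any consistency claim about the
estimator is therefore stated against these true generator moments, not
the nominal inputs.

Defaults are the second rating study's observed cells on the not-all
scale — 45.4, 52.3 (partial without/with numerals), 64.7, 62.0 (full) —
with total SD 33.375 (the mean of that study's cell SDs) split 40%
participant / 10% item / 50% residual.  The variance split is an explicit
assumption: the studies report no decomposition.  Two consequences worth
knowing: with only 8 target items, item effects do not average out across
participants (cell *levels* retain item-level noise of ~1.7 points, while
balanced *contrasts* cancel it), and mean-composition tests therefore
switch item noise off.  Exposure-trial ratings are generated (mean
probability-of-all 80, the "almost always" baseline) but never analyzed.
Comprehension answers are two booleans per trial with an error rate of 0
by default — the analyzed samples in the original studies were screened to
perfect target-trial accuracy — and the exclusion filter (participant
accuracy threshold, plus optional per-trial removal) reproduces the
screening mechanics when a nonzero error rate is set.

One master seed drives `SeedSequence.spawn` streams per participant (plus
one stream for item effects and one for group assignment), so datasets are
bit-reproducible and partially regenerable.

## Estimator

The estimand is the 2×2 fixed-effect structure (±0.5 contrast coding:
intercept, knowledgeability, exposure, interaction) on the not-all scale.
Instead of a mixed-effects regression, the package aggregates target
trials to per-participant cell means, averages them within exposure group,
and applies the contrast algebra to the four cell averages; on balanced
data this equals the mixed-model fixed-effect estimates, and it is exactly
linear in the ratings.  Uncertainty comes from a nonparametric bootstrap
resampling participants within exposure group (exposure is
between-subject), 2,000 resamples by default, percentile intervals.  The
"significance" criterion is a 95% CI excluding zero; no degrees-of-freedom
approximations are attempted.  Participants missing a knowledgeability
cell (possible after trial-level exclusions) contribute their available
cell, and the count of missing cells is reported in the fit.

Simple effects (exposure difference within one knowledgeability level) use
the same participant-level machinery restricted to that level.

The Monte-Carlo power analysis simulates full experiments from the
generator and records the fraction of interaction CIs excluding zero,
with `mc_se = sqrt(p(1−p)/n_sims)`.  Default problem sizes (500
simulations, 1,000 bootstrap resamples inside each) keep a power curve to
a couple of minutes per grid point; increase both for publication-grade
curves.  Under a zero-interaction generator the rejection rate is
calibrated to the nominal 5% within Monte-Carlo error (verified in the
test suite at n = 240, 500 simulations).

## Known limitations

- The listener's uncertainty over the speaker's *access* is not modeled:
  the access statement is treated as common ground, as in the stimuli.
- Recursion stops at L1; no deeper listener/speaker levels.
- The generator's Gaussian-plus-clipping response model is a convenience;
  real rating distributions are lumpier (round-number responses, bimodal
  endpoint use), so calibration results transfer to real data only
  approximately.
- The bootstrap treats items as fixed; with 8 target items an item-level
  random effect would widen intervals for the intercept (contrasts are
  essentially unaffected in the balanced design).
- Order effects within a session (adaptation across exposure trials) are
  deliberately not simulated.
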