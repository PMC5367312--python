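# Methods

This note documents the statistical model behind `gazeclust`, the choices
made where the design was genuinely open, and what the simulations do and
do not establish.

## Design and data model

The emulated experiment is a one-factor, three-condition within-subject,
within-item design: `n_subjects` (default 24) each see `n_items` (default
18) exactly once, with items rotated through the conditions `OS1P`, `OS2P`,
`TS2P` across three lists (a Latin square; subjects are assigned to lists
round-robin).  Gaze is sampled at `sample_rate_hz` (default 500 Hz) over an
analysis window `window_ms` (default 0–2500 ms after the offset of the
negated expression) and labelled by four areas of interest: the *negated*,
*unmentioned* and *critical* alternatives plus *elsewhere* (off-object gaze
or track loss), so the three object shares need not sum to one.

## Gaze generator

Each trial is a renewal process of fixations: durations are i.i.d.
gamma with shape `fixation_shape` (default 4) and mean `fixation_mean_ms`
(default 250 ms), drawn until the window is covered.  At each fixation
onset the fixated AOI is drawn from the condition's *preference curve* — a
baseline probability vector plus an ordered sequence of logistic ramps,

p(t) = v0 + Σ_k σ((t − m_k)/s_k) · (v_k − v_{k−1}),

which is a valid probability vector at every t.  A single-ramp curve is
the usual componentwise logistic interpolation between baseline and
asymptote.  Fixations are expanded to the sampling grid, so consecutive
samples within a fixation share an AOI; this reproduces the run-length
autocorrelation that motivates resampling-based inference in the first
place.  Saccade gaps are not modelled: every sample lies in a fixation.

Random effects are rigid time shifts of all ramp midpoints, normal with sd
`subject_sd_ms` (default 100 ms) per subject and `item_sd_ms` (default
50 ms) per item — the smallest structure that makes by-subject and by-item
analyses genuinely different resampling problems.  Shifting midpoints
rather than asymptotes keeps every unit's asymptotic preference identical
while varying effect timing, which is the quantity the cluster analysis
localizes.

### Default condition curves

All conditions share the baseline (negated .30, unmentioned .30, critical
.30, elsewhere .10); `elsewhere` holds a constant 0.1 share throughout.

| condition | ramp 1 (midpoint 900 ms) | ramp 2 (midpoint 1600 ms) |
|---|---|---|
| `OS1P` | (.12, .39, .39, .10) — equal preference kept | — |
| `OS2P` | (.12, .52, .26, .10) | (.08, .72, .10, .10) |
| `TS2P` | (.12, .52, .26, .10) | — |

Both logistic slopes are 150 ms.  This encodes the target qualitative
pattern: an unmentioned-over-critical preference ramping at ~900 ms in both
two-precedent conditions (the *linguistic* effect) and a second boost at
~1600 ms only when the precedent is in common ground with the live speaker
(the *common-ground* effect); `OS1P` keeps its log ratio at zero.

Only the midpoints and the ordering of the two effects are externally
anchored; the asymptote magnitudes are this package's design choice.  They
were fixed by a power analysis of the generator itself: with ~6 trials per
subject × condition and 50 ms frames, a cell-frame usually contains a
single fixation per trial, so the empirical-logit noise is governed by ~6
effective Bernoulli draws and is both large (per-frame contrast-score sd
near 2.8 by subjects) and right-skewed when the critical share is small.
The chosen asymptotes give per-frame t statistics comfortably above the
two-tailed 0.05 criterion throughout each effect's window, so that a
24-subject experiment detects both effects reliably without being
trivially saturated, and the two onsets remain well separated.  A stronger
separation was rejected because it delayed the apparent linguistic onset
and eroded the onset ordering.

Selection probabilities default to the per-condition choice counts implied
by the reference rate table (72/71/1, 116/23/5 and 81/62/1 out of 144 for
unmentioned/critical/negated), i.e. unmentioned rates of 50.0%, 80.6% and
56.2%.  Track-loss and off-object shares are not externally reported
anywhere; the constant 0.1 `elsewhere` share is an invented default,
flagged as such in the config.

## Aggregation and the log ratio

Samples are binned into half-open frames of `bin_width_ms` (default 50 ms;
the width must divide the window).  The analysis variable is the
baseline-category log ratio of looks to the unmentioned versus the
critical alternative with a +0.5 continuity correction,
eta = log((c_u + ½)/(c_c + ½)), computed from counts pooled within
unit × condition × frame (ratio of sums, not mean of ratios — stable on
sparse frames).  The correction keeps eta finite at zero counts and is
first-order unbiased; eta is exactly zero at equal counts and antisymmetric
under swapping the two AOIs.  `elsewhere` and `negated` samples never enter
eta.  A unit with no trials in a condition gets NaN there — flagged
missing, never fabricated.

## Cluster-mass permutation test

Per frame, each unit's contrast score is the weighted sum of its three
condition etas; the per-frame test is a one-sample t of those scores
against zero (df = n_units − 1), the standard choice for a fully
within-unit design.  Frames with |t| at or above the two-tailed critical
value at `alpha` (default 0.05) are marked; maximal same-direction runs of
marked frames are clusters, with mass Σ t.  The permutation scheme
relabels the three whole condition series within each unit independently
and uniformly — this respects both the within-subject/within-item design
and each unit's temporal autocorrelation, and the per-frame t is
exchangeable under it.  The null summary is the maximum |mass| per
permutation (0 when none forms), which controls familywise error over all
clusters and both directions; p = (b + 1)/(n + 1) with ties counted toward
b (conservative, valid at any n).  Tie comparisons use a 1e-9 absolute
tolerance so structural ties (e.g. the identity relabelling) are counted
identically by independent implementations.  With `exhaustive=True` all
6^U relabellings are enumerated and p = #(null ≥ |mass|)/6^U, identity
included.  Zero-variance and n < 2 frames are untestable: they carry no t,
break runs, and can never seed a cluster.

Numerical details: score variances are computed from centred sums with a
relative threshold (sd below 1e-9 of the mean's magnitude counts as zero
variance); permutations are evaluated in vectorized chunks; cluster masses
for the null are computed by run-boundary segmentation, verified in the
tests against the scalar cluster detector.

## Bootstrap bands

Bands are pointwise percentile bootstrap over units (subjects by default,
items by flag): units are resampled with replacement `n_boot` times, the
per-condition frame means recomputed, and the band taken at the
(1 ± level)/2 percentiles.  The percentile method was preferred over BCa
as the simplest choice adequate for these approximately symmetric means;
bands are pointwise, not simultaneous.  Coverage of the true mean curve,
measured by simulation, sits at the low edge of nominal (≈ 0.90–0.93)
because the per-subject eta distribution is right-skewed at small counts;
this is a property of percentile intervals on skewed means at n = 24, not
of the implementation.

## Selection analysis

The rate table reports, per condition, the percentage choosing each
alternative to one decimal.  Pairwise condition comparisons use a
subject-level randomization test: statistic = mean over subjects of the
difference in unmentioned-selection rates, null generated by flipping the
two condition labels within each subject (a sign flip of its difference),
two-sided p = (b + 1)/(n + 1), or exact enumeration of all 2^n sign
patterns for small n.  This deliberately replaces a crossed-random-effects
logistic mixed model: the question (a paired condition difference) is
answerable exchangeably, and the substitution is recorded in the result's
`method` metadata.  Model-comparison χ² statistics of a particular mixed
model are properties of a specific dataset and model family and are out of
scope.

## Operating characteristics, problem sizes

`scripts/acceptance.py` measures, at the default design size: familywise
error under a null generator with identical curves in all conditions (200
simulations × 200 permutations, expected in the exact binomial 95% range
around 0.05 for every contrast × unit kind); detection and onset-ordering
rates under the default effect curves (100 simulations × 500 permutations);
bootstrap coverage (100 simulations × 500 replicates against a 960-subject
truth pool); and the simulated selection table with the randomization
test's power.  These sizes give Monte-Carlo error small enough for the
stated ranges while keeping a full run under a minute.

## What the simulations do and do not show

The generator reproduces the statistical structure the analysis relies on —
the crossed design, run-length autocorrelation from fixations, per-unit
timing variability, and condition effects with known onsets — so passing
tests establish that the pipeline is calibrated, powerful and correct *for
data of that structure*.  Real eye data additionally contain saccade gaps,
blinks and track loss (here folded into a constant `elsewhere` share),
spatial AOI ambiguity, drift over the session, and fixation-duration
distributions that vary with content; none of these are modelled, so the
simulations validate the inference machinery, not any empirical claim
about real listeners.

## Known limitations

* The per-frame test assumes unit scores are exchangeable across condition
  labels under the null; unequal per-condition trial counts within a unit
  weaken this (the permutation still relabels whole series, but pooled
  counts then differ in precision across labels).
* Onset estimates are cluster starts and inherit the cluster test's known
  conservatism about boundaries: detected onsets lag true ramp midpoints
  systematically (by roughly the time the ramp needs to clear the per-frame
  threshold), so they are comparable between contrasts but are not unbiased
  change-point estimates.
* No threshold-free cluster enhancement or extent-only statistics; the
  mass statistic with a fixed per-frame alpha is the only cluster summary.
* The bootstrap band is pointwise; simultaneous coverage over 50 frames is
  necessarily lower.
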