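# Methods

This note documents the models, conventions and numerical choices behind the
toolkit, and what the synthetic-data experiments do and do not demonstrate.

## Rating model and label conversion

Ratings are 9-point SAM-style integers on two dimensions, valence and
arousal. Labels come from the thirds partition (1–3 / 4–6 / 7–9). The
partition is defined on integer scale points, so fractional ratings are
rejected rather than rounded — silently rounding a 3.5 would silently decide
a label. Neutral pictures are split by *mean* valence into low neutral
(4, 5] and high neutral (5, 6], inclusive on the stated right endpoints
(5.0 is low neutral, 6.0 high neutral). Because a picture's neutral label
comes from rater agreement rather than from the mean, a neutral picture's
mean valence can in principle fall outside (4, 6]; such pictures are
assigned the nearer subtype and flagged (`subtype_out_of_range`) instead of
being dropped — the choice is surfaced, not hidden.

Rater eligibility is the conjunction: normal color vision, Zung anxiety
(SAS) < 50, Zung depression (SDS) < 53 — the Chinese normative cutoffs,
strict at the boundary.

## Identity-ratio screening and the two-round merge

For each picture and dimension, the identity ratio is modal-label count /
rater count. A tie for the modal label means there is no dominant affect
type: the picture reports ratio = tied fraction with no modal label and
therefore fails any threshold above that fraction (at the standard 0.60
threshold a tie can never pass, since a tied label has ratio ≤ 0.5).
Ratings recorded in sessions where the rater's own pre-session affect was
abnormal are excluded before anything is computed; the operational
definition of "abnormal" in the synthetic pipeline is a per-session flag
carried in the rating table, so real data can apply whatever session screen
the study used. Pictures missing a dimension are excluded and reported.

The merge requires retention in both rounds *and* identical valence and
arousal labels across rounds. Final mean ratings default to the
second-round (larger-panel) means — the larger panel gives the more stable
estimate — with a `means="pooled"` switch for rater-count-weighted pooling
of both rounds.

Screening is monotone in the threshold by construction (a property test
verifies it), and the merged library is always a subset of each round's
retained set.

## Psychometric statistics

Cronbach's α treats the rater panel as the scale items
(α = k/(k−1)·(1 − Σ item variances / total-score variance), sample
variances), measuring panel consistency across the rated pictures;
`raters_as_items=False` transposes the matrix for ordinary item-set
reliability. α is undefined (NaN, not passed) when the total score is
constant. The mean item–total reliability is the mean Pearson correlation
between each rater's rating vector and the across-rater mean vector
(including that rater — the convention that matches an "overall rating"
computed once for the panel); constant raters are excluded with a warning.
Both reliability statistics pass strictly above 0.50.

Validity is Pearson correlation with a calibration instrument: concurrent
passes at r > 0.45, discriminant at r < 0.45, both strict — r exactly at
the cutoff passes neither, which is the conservative reading of both rules.
The paired pre/post test reports mean difference, SD, SEM, t-based 95% CI
and two-tailed p; zero-variance differences with nonzero mean are flagged
degenerate (every pair moved identically; p = 0 by convention).

All of these are checked against independent textbook-formula oracles to
1e-10 on random small matrices, and α against pingouin as an external
cross-check.

## Trial generation and scoring

A trial presents all five content categories exactly once, in seeded-random
order; each round draws one picture per valence stratum uniformly at random
(strata are disjoint, so a trial never repeats a picture), and the
within-round presentation order is an independent random permutation. The
3-option scale version draws its single neutral picture from the union of
the two neutral subtypes. Identical (library, version, seed) yields an
identical trial sequence — the reproducibility contract that makes studies
auditable.

The numeric trial score is the mean library valence of the five selections:
it is monotone in selection valence and lives on the same 1–9 scale as SAM,
making the concurrent-validity correlation directly interpretable. The
trial label is the modal selection label with neutral subtypes collapsed;
ties resolve to neutral, the central category, which biases neither validity
direction. Trials with fewer than five selections are excluded with a log
entry rather than scored partially.

Cross-trial picture reuse is allowed (the intended libraries are large) and
monitored by the duplication rate: within a window of a participant's
trials, the fraction of presentations after the first trial whose picture
already appeared earlier in the window. A single trial scores 0; two trials
on a minimal 20-picture library are forced to 1.

## Synthetic study generator

The generator emulates the statistical structure of a two-round library
build plus a repeated-measures validation cohort; it makes no attempt at
image content or demographic realism beyond the covariate knobs.

**Pictures.** Each category's pictures are allocated evenly across the four
valence strata, with true values drawn uniformly from the interior of each
label's score bin: negative (1.9, 2.95), low neutral (4.3, 4.85), high
neutral (5.15, 5.8), positive (7.05, 8.0); arousal analogously per label.
Two properties are built into these intervals. First, every true value is
at least ~0.5 scale units from the 3.5/6.5 rounding boundaries, so at low
rater noise the modal rated label provably recovers the generating label
(the basis of the label-recovery checks). Second, adjacent strata are
placed symmetric about the label-bin edges — the expected midpoint between
a sampled negative and low-neutral picture is 3.5, and between high-neutral
and positive is 6.5 — so a respondent choosing the valence-nearest picture
reproduces the binned SAM label everywhere except a thin layer at the bin
edges. Real libraries are denser near the edges (published positive
exemplars run from 6.11 upward), so real-data label consistency will be
lower than the synthetic ceiling; the published field accuracy (~90%) sits
between the synthetic low-noise value (~96–98%) and chance.

**Raters.** score = round(clip(true + N(0, σ), 1, 9)). The default rater
noise SD is 1.0 — enough to lose a realistic fraction of pictures at the
60% threshold; the low-noise checks pass σ = 0.25 explicitly. A
configurable fraction of expert sessions (default 5%) is flagged as rated
under abnormal affect and must be excluded by the screening step.

**Respondents.** Each participant has a trait baseline b ~ N(5, 0.6)
(clipped) and latent momentary affect following a mean-reverting
(emotional-inertia) process a_{t+1} = b + ρ(a_t − b) + drift + N(0, v),
clipped to [1, 9], with ρ = 0.6 by default; ρ = 1 recovers a pure bounded
random walk. Mean reversion is the standard AR(1) description of
experience-sampled affect, and it keeps the latent dispersion stationary
instead of spreading with the number of sessions. Volatility is
v = 0.32·exp(−0.25·age_group): successive-session SAM changes average ~0.4
scale units, and older participants are calmer — the ground truth the
rMSSD–age analysis should recover (and does, with r ≈ −0.25 at n = 110).
Choices are softmax in negative valence distance with temperature 0.5 by
default (0.1 in the low-noise checks); SAM pre/post are independent rounded
reports of the same latent state (the trial itself does not move affect, so
the reflection check holds by construction); PANAS PA/NA are affine in
(trait, state) with a deliberately weak state loading (1.2 trait / 0.25
state, noise SD 4) — PANAS asks about a longer time frame, which is what
makes it the discriminant instrument. The PANAS composite used in validity
and instability analyses is the PA − NA balance score; PA-only and NA-only
are available.

**What passing tests show.** Parameter recovery (labels, retention,
validity signs, rMSSD orderings as noise → 0) demonstrates that the
*pipeline* preserves the signal it is fed, under a generative model whose
assumptions (unimodal trait distribution, symmetric report noise,
distance-based choice) are idealized. They do not certify field reliability
or validity of any real picture library.

## Numerical and degenerate-input conventions

* Undefined statistics (zero-variance series, constant panels) return NaN
  with an explanatory note and never pass.
* Identity-ratio ties: no modal label; fails screening above the tied
  fraction.
* Trial-label ties: neutral.
* Scale generation fails fast with a diagnostic naming every (category,
  stratum) the library lacks.
* Percent SAM change uses the 8-unit span: |Δ|/8 × 100, "changed" at ≥ 10
  percentage points; the threshold is configurable because other span
  normalizations exist.
* Apparently abnormal responses are operationalized as implausibly fast
  trials (< 2 s by default) or participants with zero score variance across
  multiple trials; both screens are configurable and logged.
* Ordinal covariates (age group, education, marital status, management
  level, seniority) are integer-coded in their listed category order before
  Pearson correlation; significance stars at two-tailed 0.05/0.01.

## Problem sizes

The default test-suite and acceptance runs use 80-picture libraries (16 per
category), panels of 7–15 raters, and cohorts of ~110 participants × 10
trials (≥ 1,000 scored trials), with 1,000 replicates × n = 500 for the
type-I calibration of the paired test — sizes at which every Monte-Carlo
check is stable across seeds while the whole battery runs in seconds.

## Known limitations

* The generator's stratum intervals leave the bin-edge regions of the
  valence scale unpopulated; real libraries do not, so synthetic consistency
  numbers are an upper bound.
* Identity ratio is computed against the modal label; if a study instead
  fixes an expected label per picture, ratios against that label are not
  currently produced.
* The abnormal-affect session screen and the abnormal-response screen are
  simple operationalizations of judgment calls that real studies make with
  richer information.
* No item-response-theoretic or factor-analytic modeling: validity here is
  correlation-based, as is conventional for picture-scale validation.
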