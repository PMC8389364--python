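# Methods

## Generative model of choice behaviour

A fly is reduced to two latent traits: a light-choice probability
`p_light ∈ [0, 1]` and a non-negative `activity` scale. The two competing
population models differ only in the distribution of `p_light`:

* **spontaneity** — a point mass at `p_mean`; every choice is an
  independent Bernoulli draw, so subgroup composition carries no
  information about future choices;
* **individuality** — `p_light ~ Beta(α, β)` drawn once per fly and held
  fixed for life. Five-choice countercurrent tube occupancy is then
  beta-binomial, and conditioning on a first-session tube `k` gives the
  posterior `Beta(α+k, β+5−k)` and an expected retest Performance Index
  `5(α+k)/(α+β+5)`, strictly increasing in `k`.

Activity has a normal marginal truncated at zero (mean 1, sd 0.3 by
default — a dimensionless scale, 1 being the reference fly). Correlation
`rho` between preference and activity is induced by a Gaussian copula: a
latent standard-normal pair with correlation `rho` is pushed through the
Beta and truncated-normal quantile functions. This keeps both marginals
exact while the observed Pearson correlation of the traits tracks `rho`
closely (within ~0.03 at `rho = 0.6`). The copula is the simplest
structure that reproduces the observed association between weak
phototaxis and low locomotor output without committing to a mechanism.

Traits are fixed across sessions; there is no day-to-day drift term in
the default model, so any retest effect is attributable to latent
heterogeneity alone.

## Session simulators

**T-maze.** Each fly is first caught in the elevator with probability
`elevator_capture_prob` (default 0.05), independently of its preference —
nothing in the assay identifies a preference-linked capture mechanism, so
independence is the neutral assumption. Conditional on exiting, the fly
goes bright with probability `p_light`. Default cohort size is 80 flies.

**Countercurrent (CPP).** Each of 5 choices is walk-toward-light vs stay.
Because the two options are asymmetric (one costs locomotion), the default
walk probability is `p_light · s(activity)` with the saturating link
`s(a) = min(a / activity_ref, 1)`: it equals 1 at the reference activity,
never exceeds 1, and the pure-preference case is exactly recoverable with
`walk_link="preference"`. The tube index is the number of walk choices.

**Retest protocol.** Bright-arm subgroups are retested per replicate;
dark + elevator flies (the elevator is itself dark) are pooled across
replicates until 40 flies — half the standard cohort — accrue. CPP
subgroups are pooled per tube across as many first sessions as needed to
close the requested number of 40-fly second-session pools. Pools that
cannot reach the minimum are retested anyway and flagged rather than
dropped, so shortfalls stay visible to downstream tests.

**Buridan arena.** A 117 mm diameter platform with two opposing stripes.
The stripe distance is stored as 148.5 mm; the apparatus description this
mimics prints the figure in centimetres, which is dimensionally
inconsistent with the rest of the geometry, so millimetres are assumed and
the value is configurable. Kinematics are discrete-time on the sampling
grid (10 Hz, 900 s): the fly heads for the current stripe centre with a
normally-jittered heading (sd `heading_noise`, default 0.3 rad) at speed
`base_speed · activity` (default 15 mm/s at activity 1); reaching the
platform edge flips the target to the opposite stripe. While walking, a
pause begins with per-frame hazard `pause_rate/(60·rate)` (default 4/min)
and lasts a geometric number of frames with mean `pause_duration_mean·rate`
(default 3 s). These defaults give fully active flies realistic outputs
(median speed 15 mm/s, ~10 m traveled, ~6 stripe transits/min) and were
fixed before any comparison-driven adjustment; no continuous-time
integration is attempted because the metrics consume the sampled grid
directly.

## Trajectory metrics

The eight metrics and their numerical conventions:

* A frame counts as movement when its displacement exceeds
  `movement_epsilon` = 0.1 mm (1 mm/s at 10 Hz, below plausible tracking
  noise); the threshold is configurable and is the one parameter the
  metric definitions need that their verbal description omits.
* A **pause** is a maximal run of non-movement frames spanning strictly
  more than 1 s; runs of exactly 1 s or less are activity. Activity time
  plus pause time partitions the experiment exactly.
* **Median speed** is computed over movement frames only, after removing
  jumps (> 50 mm/s). Jumps are excluded from the median only; they still
  contribute to **distance traveled**, which sums every movement length.
* **Walks per minute** counts strict alternations between the two
  stripe-approach zones (sector within ±30° of a stripe bearing, outer
  20% of the platform radius — both configurable, since "arriving at a
  stripe" needs an operational definition). Re-entering the same zone
  does not count.
* **Stripe deviation** takes, per movement frame, the smaller of the two
  angles between the velocity vector and the fly→stripe vectors, median
  over frames, degrees.
* **Meander** is |turning angle|/speed per consecutive movement pair
  (degrees·s/mm), using the speed of the later displacement; pairs broken
  by rest frames are skipped.
* Metrics that need movement or pauses report missing values (NaN), never
  0, when undefined; the statistics layer excludes and counts them. All
  metrics are invariant under rigid rotation/translation of track and
  arena together.

## Statistics

Group comparisons use Kruskal–Wallis with mid-rank tie correction,
followed by Dunn's z tests on the joint ranks (tie-corrected), reporting
unadjusted and Bonferroni-adjusted p-values; Dunn's test is the standard
companion to Kruskal–Wallis and stands in for an unspecified "rank test"
post-hoc. Homogeneity of variance uses Levene's test with median centring
(Brown–Forsythe) by default; normality uses Shapiro–Wilk. A single
threshold, p < 0.005, is applied uniformly.

PCA operates on the correlation matrix of the standardized variables.
Components with eigenvalue ≥ 1 are retained; loadings are reported as
eigenvector × √eigenvalue (the correlation of each variable with the
component), with raw eigenvectors also available, and a deterministic
sign convention (largest-magnitude loading positive). Constant variables
are rejected by name. Scipy provides the classical test statistics; the
Kruskal–Wallis/Dunn pipeline is additionally verified in the test suite
against brute-force rank computations, and the PCA against an independent
SVD implementation.

## Model fitting

Tube-count models are fitted by maximum likelihood under multinomial
sampling. The binomial MLE is closed-form (mean walk fraction). The
beta-binomial likelihood is maximized over log-shapes by Nelder–Mead from
the fixed start α = β = 1 with tolerance 1e-8, making fits deterministic.
Comparison is by AIC; a likelihood-ratio test against the chi-square with
1 df is offered secondarily and flagged as approximate, because the
binomial sits on the boundary of the beta-binomial family. All-one-tube
data drive either fit to its boundary and are flagged rather than raised.
Flies lost from the apparatus are excluded: counts condition on recovery.

## Problem sizes and reproducibility

All randomness flows from one caller-supplied seed through a single
`numpy` Generator passed down the call chain; identical inputs and seed
give byte-identical outputs after serialization. The default analysis
battery uses cohorts of 80 flies, 8 retested 40-fly pools per subgroup,
and 13 Buridan flies per tube at the full 900 s / 10 Hz resolution —
small enough to run the entire battery in seconds while keeping
Monte-Carlo error well below the effect sizes the tests assert.

## What the synthetic data does and does not show

The generator emulates: the ~70/30 bright/dark split, elevator capture,
five-choice fractionation into six tubes, subgroup pooling and retesting,
and arena tracks whose activity covaries with phototactic tendency. It
deliberately omits inter-fly interaction within a group, dark adaptation,
circadian phase, sex differences, day-to-day trait drift, and within-
session choice persistence (first-order dependence between consecutive
choices). Consequently, passing tests demonstrate that the pipeline
recovers the signatures its models generate — not that real flies obey a
beta-binomial; in particular, between-fly heterogeneity and within-fly
persistence can produce similar fractionation curves, and only the
heterogeneity account is estimated here. Real tracking data also carries
jitter, blob losses and reflections that the simulator does not model;
the metrics' movement threshold and jump filter are the only noise
defences exercised.
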