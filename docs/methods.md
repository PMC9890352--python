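# Methods

## Model and assumptions

The unit of data is a post time stamp. The core assumption is that a user's
posting rate over the local day is flat while they are awake and depleted
in a single contiguous nighttime window anchored at their habitual bedtime.
Night-to-night variability in actual sleep onset is not modeled explicitly;
it is absorbed into the smooth quadratic shape of the depletion, which is
why the decline begins somewhat before the habitual bedtime rather than at
it. Consequences of the assumptions:

- One bedtime per user. Shift workers, travelers who change zones, and
  users with strongly bimodal schedules violate the model and will be
  estimated poorly (typically with a low template correlation `rho`, which
  callers can threshold on).
- Equal-weight aggregation. The aggregate bedtime-relative profile averages
  user fingerprints rather than pooling posts, so prolific users cannot
  dominate the fitted curve.
- Fractions, not percentages. All 96-bin vectors are stored summing to 1;
  the normalization equation for the flat height `d` presumes this unit.

## Fitting

For each candidate cut-point pair (S, E) on the 15-minute grid, the
quadratic is an unweighted ordinary least squares fit to the profile values
at the section's bin starts, `d` follows from normalization, and the run's
mean squared error is taken over all 96 bins. The search is exhaustive over
S ∈ {0, 0.25, …, 6} h and E ∈ {0.25, …, 11.75} h. The bounds are a design
choice (they comfortably bracket physiologic sleep windows inside the
24-hour relative frame); the section must hold at least three bins so the
quadratic is determined. A candidate is discarded when the implied `d` is
negative or any modeled bin is negative — the curve is a frequency
distribution. Exact-mse ties (within 1e-12 absolute, far above float noise
at the profile's scale) resolve to the narrower section, then the smaller
S, so a uniform profile deterministically yields the degenerate 3-bin fit
with a = b = 0.

The curve is evaluated at bin starts: "S = 0.75, E = 10" means the first
parabolic bin starts 0.75 h before bedtime and the last starts 10.0 h
after, 44 bins in all, with the return to the flat baseline at +10.25 h.
With the reference coefficients, the quadratic's interior minimum requires
the linear coefficient to be negative in this frame (a positive one pushes
the vertex outside the section and drives `d` negative); coefficients are
therefore stored signed and fitted freely. The vertex of the reference
parabola lands at x ≈ 4.62 h; the depletion depth 1 − min/d is the
parametrization-invariant summary and rounds to 87%.

## Estimation

Template matching uses Spearman correlation with average ranks — the flat
section makes rank ties pervasive, and average ranking keeps the statistic
well defined. Because every template is a rotation of one curve, the 96
rank vectors are rotations of a single rank vector, computed once.
Estimation is exactly rotation-equivariant: shifting a fingerprint by j
bins shifts the estimate by 15·j minutes. Ties across templates are broken
toward the candidate nearest the circular mean of the tied set, then by
the earliest candidate clockwise from noon; both rules are deterministic
and avoid a bias toward midnight. Fingerprints that cannot be ranked
meaningfully (all mass in one bin, or fewer than two distinct values) are
flagged `degenerate` instead of estimated; with the default 250-post
eligibility floor they essentially never occur.

When S = 0.75 the winning template's bedtime label sits 45 minutes after
the start of its parabolic section, so "bedtime = 45 minutes after the
depletion begins" is an equivalent description of the estimator for that
fitted S; the template argmax is the primary definition.

## Circular statistics

Clock times are angles on the 24-hour circle. Means use the mean resultant
vector; the circular SD is √(−2 ln R̄) rescaled to hours. The outlier rule
for reported bedtimes (beyond 2 circular SDs from the circular mean) is
applied in a single pass over the otherwise-included cohort, not iterated
to convergence, and is invariant under a common rotation of all bedtimes —
a naive linear SD on clock values would not be, since bedtimes straddle
midnight. Agreement between estimated and reported bedtimes uses the
angular (sine-deviation) circular–circular correlation, which is invariant
to rotating either variable; "within k hours" counts are boundary-inclusive
(exactly 60 minutes counts as within 1 hour). Antipodal or constant inputs
make these statistics undefined; the functions raise rather than guess.

## Screening

The four bot rules are thresholds on: maximum posts in a single epoch
minute (≥ 9), lifetime posts (≥ 2^14), the share of posts at one exact
minute-of-day (≥ 2%), and username substrings {bot, admin, mod, auto},
case-insensitive. "Same exact minute each day" is read as a recurring
minute-of-day; scheduled bots may run on local or UTC clocks, so both
tallies are checked and either crossing 2% fires the flag. Bot rules apply
in the application context only — users who answered a bedtime poll have
demonstrated humanity — while the post floor applies everywhere.

## Cross-validation

Labeled users are shuffled into k near-equal partitions per seed (sizes
differ by at most one; 159 users split 53/53/53 at k = 3). Each fold
refits the model from scratch on the training partitions' aggregate
profile, rebuilds the templates, and scores both training and hold-out
users. Ten seeds × three folds gives 30 validation rows, summarized by
medians and IQRs; a failed fit marks its row `failed` without aborting the
harness. The released model is refit on all labeled users.

## Synthetic cohorts

The generator draws each user's true bedtime from a von Mises law (default
mean 23:45, κ = 6.5, circular SD ≈ 1.5 h — a cohort whose mean bedtime sits
just before midnight), rounds it to the 15-minute grid, and samples post
minutes-of-day i.i.d. from that bedtime's template under the reference
model, with uniform jitter inside the bin, dates uniform over a one-year
span, and conversion to UTC epochs through each user's IANA zone (users
cycle through five common zones, so DST handling is exercised). A `noise`
parameter blends each user's template with a user-level Dirichlet draw.
Bot archetypes are constructed to trip exactly one rule each.

What the generator does not emulate: weekday/weekend structure, bursty
within-day sessions (posts are i.i.d. given the template), night-to-night
bedtime drift (an explicit per-night jitter exists but defaults to 0), and
content. Passing tests on these cohorts therefore show correctness of the
machinery and recoverability under the model's own assumptions, not
real-world accuracy on any platform's users.

Problem sizes used in the test suite and scripts — e.g. 200 users × 2,000
posts for parameter recovery, 159 users × 1,000 posts for the
cross-validation design, 10^5 posts for distributional checks — are chosen
so each property is measured well above its noise floor while the whole
suite runs in well under a minute per module.

## Known limitations

- The circular-correlation formula behind published "correlation in polar
  coordinates" figures is not standardized; this package uses the angular
  sine-deviation statistic, which can differ numerically from other
  conventions on the same data.
- Estimates are snapped to the 15-minute grid; sub-grid precision is out
  of scope, as are wake time, sleep duration, and per-night variability.
- The 2-SD outlier rule here is circular; cohorts screened with a linear
  SD on clock values may retain or drop different users near midnight.
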