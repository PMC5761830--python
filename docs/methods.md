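# Methods

This note documents the statistical machinery in `dualforage`: what each
stage computes, the choices that were genuinely open, and what the synthetic
data can and cannot establish.

## Data model

The observational unit is the 10-minute window: during a continuous 48-h
session (288 windows) each member of a marked breeding pair is scored
present at the colony (CO) or absent.  A maximal run of absence is a
foraging trip; a trip ends at the first colony window after it, which is
also when the chick is fed.  Every window of a processed timeline carries
one of four codes: CO, ST (short trip), LT (long trip) or MASKED (removed
from analysis).  All durations are whole multiples of 10 min; a duration in
hours is `n_windows / 6`.  Behaviour inside a window is unrepresentable at
this resolution; a bird present at any point of a window is scored present.

## Short/long trip classification

Trip durations pool across all birds, sessions and years into one bimodal
sample, well described by a two-component log-normal mixture.  The threshold
is the cut-off *c* minimizing the summed within-class sample variance
(denominator n−1) of log-durations.  Because that objective is piecewise
constant between data points, the candidate set — midpoints of consecutive
distinct sorted log-durations — is exact, and the implementation is verified
against an exhaustive scan in the tests.  Ties at the threshold go to LT
(`d < c` is short); each class must keep at least `min_class_size = 2`
members (sample variance needs two points).  A single study-wide cut-off is
estimated and applied globally.

## Exclusions and masking

Trips clipped by the session start or end cannot be classified (their true
duration is unknown) and are excluded together with the partner's records
over the same window span: both birds receive the identical MASKED span, so
the two timelines stay aligned and the overlap statistic keeps a symmetric
support.  A session in which the female fed at most once in 48 h is flagged
excluded (female brood desertion late in chick rearing would otherwise
contaminate the provisioning pattern), as are sessions with faded colour
marks (an input flag).  Exclusion is a flag, never deletion.

Masking the bare window span can cut a partner's complete trip into a
*fragment* that survives at the mask boundary.  Fragments are handled
specially by the null model (below).  An alternative, expanding the mask
over any straddling trip to a fixed point, is available as a diagnostic
(`mask_style="whole_trip"`) but discards far more data (roughly half of a
typical simulated session) and frequently leaves sessions with no
information at all, so the span interpretation is the default.

## The randomization null

Per session and per bird, the unmasked timeline splits at MASKED spans into
sub-series, each run-length encoded into activity strings.  One shuffle
redraws, independently for each bird and sub-series, the order of trip
strings uniformly over the positions that held trip strings, and of CO
strings over the positions that held CO strings — all without replacement.
Because an observed series alternates trips and colony stays, this keeps
exactly one randomly sampled CO string between consecutive trips while
leaving the number of STs or LTs in a row unconstrained, and it conserves
the total window count, the multiset of string durations and each bird's
per-category window totals.

Two design points matter for the validity of the test, and both were chosen
from first principles about exchangeability (and confirmed by calibration
simulations at zero coupling):

* **Boundary structure is preserved.**  Truncation masking makes windows at
  the session edges CO-certain in the observed data (any trip touching an
  edge is masked).  A shuffle allowed to park trips flush against those
  edges flattens the null spatially and makes the observed overlap look
  systematically large; permuting strings within their positional skeleton
  removes that artifact.
* **Fragments are pinned.**  A trip fragment at a mask boundary comes from a
  length-biased draw (long trips are the ones that straddle masked spans)
  and is therefore not exchangeable with complete trips; fragments stay
  fixed in place in every shuffle and only complete strings are permuted.

Statistics recomputed on each shuffle:

* `st_lt_overlap` — windows where one bird is on ST and the other on LT;
  MASKED windows contribute nothing.  Upper-tail test: coordination means
  more overlap than chance.
* `interfeed_cv` — sample SD over mean of inter-feeding intervals, feedings
  pooled over both parents at each trip's end and re-derived from the
  shuffled series; a trip flush with a sub-series end yields no feeding
  (its return is unobserved), and the observed statistic is computed through
  the same machinery so observed and null share one support.  Feedings of
  both parents in the same window merge into one event time.  Lower-tail
  test: coordination means more even provisioning.

Three p-values are reported for each test: the strict rule (proportion of
null draws strictly beyond the observed value), the **mid-p** (ties with the
observed value counted half), and a (+1)-corrected value
`(beyond + 1)/(n + 1)`.  On a discrete statistic such as the overlap count,
the strict rule is anti-conservative by up to the tie mass at the critical
value; the mid-p restores type-I calibration and is the package's inferential
default, used for downstream combination.  Sessions whose shuffle admits a
single arrangement (e.g. one trip and one colony stay) have a point-mass null
and carry no information; they are flagged degenerate and excluded from
combination rather than contributing a meaningless zero p.

The session-level **coordination level** is `(observed − exp)/exp` with
`exp` the null mean, and the same relative index is computed for the
interval CV.

An exact-enumeration oracle (`exact_null_small`) lists every admissible
arrangement with its probability for small sessions and is used to validate
the Monte Carlo engine (total-variation agreement) in the tests.

## Combining p-values

Sessions are the test unit; pairs observed repeatedly would otherwise be
pseudoreplicated.  Per pair, one-tailed session p-values (clamped into
`(1/(n+1), n/(n+1))`) are combined with Stouffer's Z; Fisher's chi-square
(−2Σln p on 2k df) and the logit method (−Σ logit p over
`sqrt(k π²(5k+2)/(3(5k+4)))`, referred to t with 5k+4 df) are computed as
qualitative checks.  The logit method's k = 1 case is only an approximate
identity (a logistic variate referred to a scaled t), which the tests
acknowledge.  Study-level combinations are reported both over all session
p-values and over the per-pair combined values; for Stouffer with equal
sessions per pair the two coincide exactly.

## Chick growth

Eight indicators per chick: mass on day 14–16 (earliest such record), peak
mass and its day (earliest day on ties), fledging mass (last measurement),
mass recession (peak − fledging), fledging day, and two Specific Growth
Rates.  The SGR formula divides the log-mass change by `(t₂−t₁) × 100`
(`paper_literal`); the conventional percent-per-day form is also available,
differs by exactly 10⁴, and — because the PCA z-scores its inputs — has no
effect on any downstream result (a tested property).  The fledging day is
interval-censored by the every-3-days nest checks and taken as the midpoint
between the last day seen and the first day missing (disappearance counts
only after day 21); without check records it falls back to the last
weighing day plus a configurable offset (default 1.5 days).

The indicators are strongly intercorrelated and are reduced by PCA on
z-scored variables (equivalently, eigendecomposition of the correlation
matrix) over complete cases; zero-variance variables are dropped with a
warning and component signs are fixed deterministically.  The first two
component scores are the condition responses.

Four linear mixed models (maximum likelihood, breeding pair as random
intercept, via statsmodels MixedLM): (a) coordination level ~ chick age;
(b) relative interval CV ~ coordination level; (c) PC1/PC2 ~ coordination
level + total feedings per 48 h; (d) PC1/PC2 ~ relative CV + feedings.
F statistics are Wald `(estimate/SE)²` on 1 numerator df with a
residual-style denominator df (`n_obs − n_fixed − n_groups`), reported so
results can be re-referenced under another df convention; boundary
(singular) random-effect fits are flagged, not silenced.

## Synthetic data

The generator reproduces the structure the analysis assumes, with defaults
set once to the study-shaped conditions:

| parameter | default | rationale |
|---|---|---|
| pairs / sessions | 25 pairs, 1–5 sessions each (median 3) | study shape |
| session | 48 h on a 10-min grid | observation protocol |
| ST duration | log-normal, meanlog `ln 1.9 − 0.125`, sdlog 0.5 | mean exactly 1.9 h |
| LT duration | log-normal, meanlog `ln 12.8 − 0.08`, sdlog 0.4 | mean exactly 12.8 h |
| colony bout | log-normal truncated to [10, 80] min, sdlog 0.5, meanlog solved so the truncated mean is 49 min | attendance summary |
| `p_lt` | 0.25 | ~4 trips/bird/day and ~2 LT per 48 h, matching the provisioning rate of a small auk |
| `kappa` | 0.6 | moderate coupling; produces study-like positive coordination |
| `growth_effect_beta` | 0 | no built-in growth effect |
| mass noise | 3 g SD | balance accuracy (0.1 g) vs handling variability |

Both birds are co-simulated event by event from a 24-h burn-in, because the
coupling needs the partner's instantaneous state: at each trip start the trip
is long with probability `p_lt (1 − kappa · [partner on LT])`.  `kappa = 0`
gives independent birds — the calibration null — and `kappa = 1` forbids
starting a long trip while the partner is on one.  Boundary trips are
emitted clipped, so the pipeline's truncation handling is exercised on every
corpus.  Sessions split across two breeding years (earlier sessions year 1,
later year 2) and each pair rears one chick per year observed; without this
repeated-season structure the growth response would be constant within the
random-effect group and ML estimation would force all session-varying fixed
slopes to zero.  Chick mass rises along a saturating curve (rate 0.1/day)
to a peak near day 20, then declines linearly to fledging between days 24
and 30; `growth_effect_beta` depresses the peak in proportion to the pair's
realized inter-feeding CV.

What passing tests on this generator do **not** show about field data: real
attendance series have diel and weather structure, observation error, and
behavioural dependencies (e.g. reactive trip shortening) that the
renewal-style generator omits; the coupling mechanism is one interpretable
choice among several; and calibration of the randomization test is
demonstrated under the generator's null, not under every conceivable
attendance process.

## Problem sizes and numerical choices

Test problem sizes were chosen to make each check informative at interactive
runtimes: calibration uses 1,000 simulated sessions at 1,000 shuffles per
test; power monotonicity uses 500 sessions per coupling level at 500
shuffles with session random streams shared across levels (a paired design,
so the comparison is not washed out by between-session noise); the
end-to-end check aggregates the study-level Z over six replicate corpora,
since a single 25-pair corpus carries only ~50% power against the 0.05
threshold and would test the seed rather than the method.  The acceptance
script runs the full pipeline at the study scale (10,000 shuffles per
session).

Numerical conventions: natural logs throughout; sample variance and SD use
denominator n−1; random numbers come from numpy's PCG64 generator, with all
entry points seedable and results bit-reproducible under a fixed seed;
zero-length inter-feeding intervals (merged same-window feedings) are
dropped; p-value clamping bounds are `(n+1)⁻¹`.

## Known limitations

* The overlap statistic is integer-valued, so even the mid-p is mildly
  discrete at small session information; combined Z statistics are slightly
  under-dispersed under the null (conservative).
* Pinning fragments sacrifices some power at strong coupling (fragment
  windows carry real signal that the null conditions away); the trade was
  made in favour of type-I calibration.
* The mixed-model stage is a thin contract over standard machinery; denominator
  df conventions differ across packages and only the reported convention is
  implemented.
* Sessions are assumed independent within pair for combination; no weighting
  by session length is applied.
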