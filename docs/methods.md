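# Methods

## Model and decision rule

Each arm's binary endpoint (MPR for resectable cohorts, 6-month DCR for
locally advanced cohorts) is modelled as Bernoulli with rate π. Rates carry
conjugate Beta priors; both experimental and control priors default to the
non-informative Beta(1, 1). After x successes in n patients the posterior is
Beta(α + x, β + n − x).

An experimental arm is claimed successful when the posterior probability of
superiority by a margin,

PP = Pr(π_e > π_c + δ | data),  δ = 0.05,

strictly exceeds a threshold θ_t. PP is computed by adaptive quadrature of

∫₀^{1−δ} f_c(x) · S_e(x + δ) dx,

where f_c is the control posterior density and S_e the experimental
posterior survival function (`scipy.integrate.quad`, absolute and relative
tolerance 1e−10, so the result is accurate well below the 1e−8 contract).
The comparison with θ_t is strict (PP = θ_t does not succeed). Values are
clipped to [0, 1] to absorb quadrature round-off. A margin δ ≥ 1 is rejected
rather than returning the trivial 0, since it almost certainly indicates a
caller error. There is no early efficacy stopping: each arm is evaluated
once, at full enrollment.

## Adaptive randomization

Allocation depends only on counts, not outcomes. While the control arm has
treated fewer than its cap (default 30), every open arm — control included —
receives probability 1/(m + 1), where m is the number of experimental arms
open to accrual and below their planned size. Once the cap is reached the
control receives 1/(1 + 3m) and each open experimental arm 3/(1 + 3m).
Arms that completed accrual drop out of m immediately; the control accrues
indefinitely (at the reduced rate) while any experimental arm remains open.

## Platform simulation

Patients arrive by a Poisson process (exponential inter-arrival times) at a
default 5 patients/month; a deterministic fixed-rate alternative is
available. The accrual rate is a calibration choice, not a quantity the
design fixes: 5/month makes the simulated mean control size ≈ 42, matching
the design's reported control workload, and is the kind of accrual a
multi-site phase-II pancreatic-cancer study plans for. Experimental arms of
30 patients enter at months 0, 6, 12, 18 at fixed calendar offsets
regardless of other arms' progress. If no experimental arm is open (one arm
filled, the next not yet entered), accrual pauses: arriving patients are
not enrolled and the control does not accrue.

Each enrolled patient's outcome is an independent Bernoulli draw at the
assigned arm's true rate, generated in arrival order from the replicate's
single RNG stream; replicates use substreams spawned from the master seed
(`numpy.random.SeedSequence`), so every result is reproducible bit-for-bit
from `(scenario, reps, seed)`.

**Control comparison set.** Which control patients enter an arm's analysis
is a genuine design ambiguity. Three conventions are implemented:

* `"final"` (default): every arm is compared against the control arm's
  complete data after the platform stops accruing. This is the convention
  under which the design's stated per-arm type-I bound (≤ 15%) actually
  holds for all arms: the first arm otherwise reaches its analysis with
  only ~30 controls, where the false-positive rate of the θ_t = 0.72 DCR
  rule is ≈ 0.17.
* `"all_accrued"`: each arm is analyzed at its own enrollment completion
  against all control outcomes accrued by then (non-concurrent controls
  included). Early arms see fewer controls; later arms more.
* `"concurrent"`: as `"all_accrued"`, restricted to controls enrolled at or
  after the arm's entry time.

Endpoint ascertainment (12 weeks for MPR, 6 months for DCR) is ignored by
default — analyses are indexed to enrollment completion — with an optional
fixed `analysis_delay_months`; under `"final"` the delay is immaterial.
Graduation-expansion cohorts (up to 10 additional patients after a positive
decision) do not change the decision and are not simulated.

## Threshold calibration

θ_t is the smallest value on the grid {0.50, 0.51, …, 0.99} for which the
simulated per-arm probability of claiming success under the null scenario
(all experimental rates equal to the control's) is at or below the target
(default 0.15) for the worst arm. One batch of null replicates (default
1000) is simulated and reused across the whole grid — common random
numbers — so the returned threshold is a monotone function of the target.
With the built-in null scenarios this recovers θ_t within one or two grid
steps of 0.67 (MPR) and 0.72 (DCR); at 1000 replicates the Monte-Carlo
standard error of a per-arm null rate is ≈ 0.011, so neighbouring grid
values are genuinely indistinguishable at that precision.

## Toxicity monitoring

The toxicity rate π_tox carries a Beta(0.6, 1.4) prior (prior mean 0.3,
matching the unacceptable rate; prior weight two patients). At each look
(cumulative n = 10, 20, 30) the arm stops if Pr(π_tox > 0.3 | data) > 0.8.
The boundary at a look is the smallest toxicity count satisfying the
inequality — 5/10, 8/20, 12/30 under the defaults — computed from the beta
posterior survival function; a look can have no attainable boundary, in
which case it is skipped.

Operating characteristics are exact, not simulated: the distribution of
cumulative toxicities among continuing paths is propagated look to look by
convolution with the binomial increment, giving the stopping probability
and the expected sample size (patients added at each look weighted by the
probability of reaching it). **Early stopping** counts crossings at interim
looks only (n = 10, 20): a crossing at the final look n = 30 flags the arm
but no longer shortens enrollment, so it is reported separately
(`boundary_hit_prob`) and excluded from `early_stop_prob` and from the
expected-sample-size reduction. This convention reproduces the design's
published toxicity table to three decimals; counting final-look crossings
as "early" would overstate the stopping probabilities by 0.002–0.07.

Toxicity monitoring consumes binary toxicity indicators; the clinical event
definition (CTCAE grading) is outside computational scope. The safety
lead-in dose-finding phase (a BOIN design) is a separate procedure and is
not implemented here.

## Exact intervals

Clopper–Pearson equal-tailed intervals use the beta quantile
characterization: lower = B(α/2; x, n−x+1) (0 when x = 0), upper =
B(1−α/2; x+1, n−x) (1 when x = n). Display rounding is three decimals,
matching the protocol's worked examples (6/30 → (0.077, 0.386); 27/30 →
(0.735, 0.979)). Coverage is conservative (≥ nominal), verified by
exhaustive enumeration at n = 30 in the test suite.

## What the simulator does and does not emulate

The synthetic trials emulate the design's probabilistic structure: staggered
entry, count-adaptive allocation with a capped shared control, independent
Bernoulli endpoints, and one posterior analysis per arm. They do not model
dropout or missing outcomes, accrual seasonality or site effects,
time-to-event secondary endpoints, outcome-adaptive randomization (the
design's adaptation is count-driven by construction), or correlation
between toxicity and response. Passing operating-characteristics checks
therefore validates the decision machinery under the design's own
assumptions, not the behaviour of the trial under real-world deviations
from them.

## Numerical and implementation notes

* Posterior-probability quadrature results are cached on the posterior
  parameters; platform simulations at 30-patient arms hit the cache heavily.
* Problem sizes: published-table reproductions use 1000 replicates per
  scenario (the design's own simulation size); the test suite uses smaller
  batches (40–500 replicates) for structural checks and the full 1000 for
  the operating-characteristics comparisons.
* Monte-Carlo comparisons in tests use 3-standard-error bands; exact
  quantities (boundaries, intervals, allocation probabilities) are asserted
  to printed precision.
* Degenerate inputs: arms with `planned_n = 0` open and close immediately
  and are analyzed on prior information alone; `BinomialData(0, 0)` leaves
  the prior unchanged; a scenario without an open experimental arm cannot
  randomize and raises.

## Known limitations

* The accrual process behind the published platform tables is not stated in
  the design; the Poisson-5/month default reproduces the control mean size
  but other rates shift per-arm analysis times (not decisions, under the
  default `"final"` comparison).
* The published power for the 0.26-rate MPR arm (0.676) sits at the top of
  the band this engine can produce under any of its comparison conventions
  (exact enumeration of a 30-vs-n_c comparison wiggles between 0.61 and
  0.69 as n_c varies); our simulated value is ≈ 0.63–0.65. All other
  published platform values reproduce within Monte-Carlo noise.
* Calibration at 1000 replicates can return a neighbouring grid value
  (±0.01–0.02) of the published thresholds; that is inherent Monte-Carlo
  granularity, not a defect.
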