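# platoc

Design-evaluation engine for Bayesian multi-arm **platform trials** with a
shared control arm — the setting of a phase-II trial in localized pancreatic
cancer where experimental regimens enter the study in a staggered fashion
and each is compared with a common control on a binary endpoint (major
pathological response, MPR, or 6-month disease control rate, DCR).

It is written for trial statisticians who need to evaluate or re-derive the
operating characteristics of such a design: type-I error, power, expected
sample sizes, toxicity-monitoring behaviour, and the calibration of the
decision threshold.

## The design in brief

**Efficacy decision.** Each arm's response rate carries a Beta prior
(non-informative Beta(1, 1) by default). When an experimental arm completes
its planned 30 patients, it is claimed successful if

    Pr(π_e > π_c + δ | data) > θ_t,        δ = 0.05,

under independent beta posteriors for the experimental (π_e) and control
(π_c) rates. The threshold θ_t is calibrated by simulation so that the
per-arm false-positive rate stays at or below 15% — which yields θ_t ≈ 0.67
for the MPR design (control rate 0.13) and ≈ 0.72 for the DCR design
(control rate 0.70).

**Adaptive randomization.** Patients are randomized equally across the open
arms until the control arm has treated its cap (30 patients); thereafter the
control receives probability 1/(1 + 3m) and each of the m open experimental
arms 3/(1 + 3m) — e.g. control 1/7 with two open arms, 1/10 with three. New
arms enter at 6-month intervals.

**Toxicity monitoring.** With a Beta(0.6, 1.4) prior on the toxicity rate
π_tox, an arm stops early if Pr(π_tox > 0.3 | data) > 0.8, evaluated in
cohorts of 10 up to 30 patients — equivalent to stopping at ≥5/10, ≥8/20,
≥12/30 cumulative toxicities. Operating characteristics are computed by
exact enumeration of binomial paths.

**Exact intervals.** Clopper–Pearson equal-tailed intervals via the beta
quantile characterization, as used in the design's analysis plan.

## Worked example

```python
>>> from platoc import *
>>> update_posterior(BetaPrior(1, 1), BinomialData(6, 30))
BetaPrior(alpha=7, beta=25)
>>> prob_exceeds_margin(BetaPrior(7, 25), BetaPrior(5, 27), delta=0.05)
0.5514760468716589
>>> decide(BetaPrior(7, 25), BetaPrior(5, 27), DecisionRule(theta_t=0.67)).success
False
>>> [stopping_boundary(ToxRule(), n) for n in (10, 20, 30)]
[5, 8, 12]
>>> exact_oc(ToxRule(), 0.4)
ToxOC(true_rate=0.4, early_stop_prob=0.623099666210813, expected_n=20.10003591389186, boundary_hit_prob=0.6970131789850673)
>>> print(clopper_pearson(6, 30, 0.95))
(0.077, 0.386)
```

With 6/30 responders the posterior is Beta(7, 25); against a 5/27 control
posterior the superiority probability 0.55 falls short of θ_t = 0.67, so the
arm is not claimed successful. A true toxicity rate of 0.4 would trigger
early termination with probability 0.62 and treat 20.1 patients on average.

Simulating the four-arm MPR platform (control 0.13; experimental rates
0.195, 0.26, 0.13, 0.30 entering at months 0, 6, 12, 18):

```python
>>> oc = operating_characteristics(mpr_scenario(), reps=1000, seed=101)
>>> oc.table[["true_rate", "start_time_months", "mean_n", "prob_claim_success"]]
   true_rate  start_time_months  mean_n  prob_claim_success
0      0.130                0.0   41.72                 NaN
1      0.195                0.0   30.00               0.380
2      0.260                6.0   30.00               0.647
3      0.130               12.0   30.00               0.157
4      0.300               18.0   30.00               0.785
```

The null arm (true rate equal to the control's 0.13) is falsely claimed
successful ≈16% of the time in this batch — consistent with the 15% type-I
target given the ±1.1% Monte-Carlo error of 1000 replicates — while the
0.26- and 0.30-rate arms are detected with roughly 65% and 79% power; the
control arm accrues ~42 patients on average.

The same functionality is exposed on the command line:

```bash
platoc ci 6 30
platoc tox-oc --out tox.csv
platoc simulate --scenario scenario.yaml --reps 1000 --seed 1 --out oc.csv
platoc calibrate --scenario null.yaml --target-type1 0.15
platoc reproduce-tables --out tables/ --seed 1
```

`reproduce-tables` regenerates the design's three operating-characteristics
tables (MPR platform, DCR platform, toxicity monitoring) with a provenance
sidecar recording the exact configuration and seeds.

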