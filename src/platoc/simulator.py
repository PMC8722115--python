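"""Discrete-event simulation of a multi-arm platform trial with a shared control.

Patients arrive under an accrual model (Poisson process by default), are
randomized among the open arms by the adaptive allocation rule, and
contribute an independent Bernoulli endpoint at their arm's true rate.
When an experimental arm fills its planned sample size it is compared with
the control data accrued up to that moment via the posterior superiority
rule.  Operating characteristics aggregate many independent replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable, Literal, Sequence

import numpy as np
import pandas as pd

from .posterior import BetaPrior, BinomialData, DecisionRule, decide, update_posterior
from .randomization import AllocationState, ArmSpec, allocation_probabilities

__all__ = [
    "AccrualModel",
    "TrialScenario",
    "ArmResult",
    "TrialResult",
    "OCTable",
    "simulate_trial",
    "operating_characteristics",
]


@dataclass(frozen=True)
class AccrualModel:
    """Patient arrival process: Poisson (exponential gaps) or a fixed rate."""

    kind: Literal["poisson_process", "fixed_rate"] = "poisson_process"
    rate: float = 5.0  # patients per month

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"accrual rate must be > 0, got {self.rate}")

    def interarrival(self, rng: np.random.Generator) -> float:
        if self.kind == "poisson_process":
            return rng.exponential(1.0 / self.rate)
        return 1.0 / self.rate


def _default_prior() -> BetaPrior:
    return BetaPrior(1.0, 1.0)


@dataclass(frozen=True)
class TrialScenario:
    """Everything needed to simulate one platform-trial configuration.

    ``control_comparison`` selects which control patients enter an arm's
    analysis.  ``"final"`` (default) compares every arm against the control
    arm's complete data once the platform stops accruing: this is the
    convention whose operating characteristics keep the per-arm false
    positive rate at or under the design's 15% target, because early arms
    are otherwise judged against very few controls.  ``"all_accrued"``
    compares each arm at its own enrollment completion against the control
    outcomes accrued by then; ``"concurrent"`` additionally drops controls
    enrolled before the arm entered.  ``analysis_delay_months`` postpones
    each arm's analysis past its enrollment completion (endpoint
    ascertainment); controls accrued during the delay, while other arms
    keep the trial open, are then included (no effect under ``"final"``).
    """

    arms: tuple[ArmSpec, ...]
    rule: DecisionRule
    endpoint: str = "MPR"
    prior_e: BetaPrior = field(default_factory=_default_prior)
    prior_c: BetaPrior = field(default_factory=_default_prior)
    accrual: AccrualModel = field(default_factory=AccrualModel)
    control_cap: int = 30
    control_comparison: Literal["final", "all_accrued", "concurrent"] = "final"
    analysis_delay_months: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        controls = [a for a in self.arms if a.role == "control"]
        if len(controls) != 1:
            raise ValueError(f"scenario needs exactly one control arm, got {len(controls)}")
        exp = self.experimental_arms
        if not exp:
            raise ValueError("scenario needs at least one experimental arm")
        times = [a.open_time for a in exp]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("experimental open_times must be strictly increasing")

    @property
    def control_arm(self) -> ArmSpec:
        return next(a for a in self.arms if a.role == "control")

    @property
    def experimental_arms(self) -> tuple[ArmSpec, ...]:
        return tuple(a for a in self.arms if a.role == "experimental")


@dataclass(frozen=True)
class ArmResult:
    arm_id: Hashable
    true_rate: float
    n_treated: int
    n_success: int
    posterior_prob: float
    success: bool
    analysis_time: float
    control_n_at_analysis: int
    control_successes_at_analysis: int


@dataclass(frozen=True)
class TrialResult:
    """One replicate: every experimental arm's decision plus control totals."""

    arms: tuple[ArmResult, ...]
    control_n_treated: int
    control_n_success: int


@dataclass(frozen=True)
class OCTable:
    """Per-arm operating characteristics over replicates.

    ``table`` has one row per arm (control first) with columns
    ``arm_id, role, true_rate, start_time_months, mean_n, prob_claim_success``.
    """

    table: pd.DataFrame
    reps: int
    seed: int


def simulate_trial(scenario: TrialScenario, seed: int | np.random.Generator) -> TrialResult:
    """Run one replicate of the platform trial.

    Accrual pauses while no experimental arm is open (between one arm
    filling and the next entering); the control arm accrues only while the
    trial is randomizing.  Each experimental arm's decision is evaluated
    when its planned size is reached (plus any ascertainment delay),
    against the control comparison set selected by the scenario.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exp_arms = scenario.experimental_arms
    arm_by_id = {a.arm_id: a for a in exp_arms}

    n_treated = {a.arm_id: 0 for a in exp_arms}
    n_success = {a.arm_id: 0 for a in exp_arms}
    fill_time: dict[Hashable, float] = {
        a.arm_id: a.open_time for a in exp_arms if a.planned_n == 0
    }
    control_times: list[float] = []
    control_outcomes: list[int] = []
    control_rate = scenario.control_arm.true_rate

    pending = [a.arm_id for a in exp_arms if a.planned_n > 0]
    t = 0.0
    while pending:
        t += scenario.accrual.interarrival(rng)
        open_ids = [
            a.arm_id
            for a in exp_arms
            if a.open_time <= t and n_treated[a.arm_id] < a.planned_n
        ]
        if not open_ids:
            # trial paused until the next arm enters; skip this arrival
            future = [a.open_time for a in exp_arms if a.arm_id in pending]
            t = max(t, min(future))
            continue
        state = AllocationState(
            control_treated=len(control_times),
            active_arm_ids=open_ids,
            control_cap=scenario.control_cap,
        )
        probs = allocation_probabilities(state)
        idx = int(rng.choice(len(probs), p=probs))
        outcome = int(rng.random() < (control_rate if idx == 0 else arm_by_id[open_ids[idx - 1]].true_rate))
        if idx == 0:
            control_times.append(t)
            control_outcomes.append(outcome)
        else:
            aid = open_ids[idx - 1]
            n_treated[aid] += 1
            n_success[aid] += outcome
            if n_treated[aid] == arm_by_id[aid].planned_n:
                fill_time[aid] = t
                pending.remove(aid)

    ctimes = np.asarray(control_times)
    couts = np.asarray(control_outcomes, dtype=int)
    results = []
    for arm in exp_arms:
        analysis_time = fill_time[arm.arm_id] + scenario.analysis_delay_months
        if scenario.control_comparison == "final":
            mask = np.ones(ctimes.size, dtype=bool)
        else:
            mask = ctimes <= analysis_time
            if scenario.control_comparison == "concurrent":
                mask &= ctimes >= arm.open_time
        nc = int(mask.sum())
        sc = int(couts[mask].sum()) if ctimes.size else 0
        post_e = update_posterior(
            scenario.prior_e, BinomialData(n_success[arm.arm_id], n_treated[arm.arm_id])
        )
        post_c = update_posterior(scenario.prior_c, BinomialData(sc, nc))
        d = decide(post_e, post_c, scenario.rule)
        results.append(
            ArmResult(
                arm_id=arm.arm_id,
                true_rate=arm.true_rate,
                n_treated=n_treated[arm.arm_id],
                n_success=n_success[arm.arm_id],
                posterior_prob=d.posterior_prob,
                success=d.success,
                analysis_time=analysis_time,
                control_n_at_analysis=nc,
                control_successes_at_analysis=sc,
            )
        )
    return TrialResult(
        arms=tuple(results),
        control_n_treated=len(control_times),
        control_n_success=int(couts.sum()) if ctimes.size else 0,
    )


def replicate_posteriors(
    scenario: TrialScenario, reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior superiority probabilities and control sizes over replicates.

    Returns ``(pp, control_n)`` with ``pp`` of shape (reps, n_experimental_arms)
    ordered as in ``scenario.experimental_arms``.  One RNG substream is
    spawned per replicate from the master seed, so results for a given
    (scenario, reps, seed) are reproducible and the same draws can be reused
    across decision thresholds (common random numbers).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    streams = np.random.SeedSequence(seed).spawn(reps)
    pp = np.empty((reps, len(scenario.experimental_arms)))
    control_n = np.empty(reps, dtype=int)
    for r, ss in enumerate(streams):
        res = simulate_trial(scenario, np.random.default_rng(ss))
        pp[r] = [a.posterior_prob for a in res.arms]
        control_n[r] = res.control_n_treated
    return pp, control_n


def operating_characteristics(scenario: TrialScenario, reps: int, seed: int) -> OCTable:
    """Aggregate ``simulate_trial`` over independent replicates.

    Per arm: the proportion of replicates claiming success (posterior
    probability strictly above the threshold) and the mean number of
    patients treated.  The control row reports its mean size; its success
    probability is undefined (NaN).
    """
    pp, control_n = replicate_posteriors(scenario, reps, seed)
    success = (pp > scenario.rule.theta_t).mean(axis=0)
    exp_arms = scenario.experimental_arms
    ctrl = scenario.control_arm
    rows = [
        {
            "arm_id": ctrl.arm_id,
            "role": "control",
            "true_rate": ctrl.true_rate,
            "start_time_months": ctrl.open_time,
            "mean_n": float(control_n.mean()),
            "prob_claim_success": np.nan,
        }
    ]
    for j, arm in enumerate(exp_arms):
        rows.append(
            {
                "arm_id": arm.arm_id,
                "role": "experimental",
                "true_rate": arm.true_rate,
                "start_time_months": arm.open_time,
                "mean_n": float(arm.planned_n),
                "prob_claim_success": float(success[j]),
            }
        )
    return OCTable(table=pd.DataFrame(rows), reps=reps, seed=seed)
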