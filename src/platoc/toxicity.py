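"""Bayesian toxicity monitoring: stopping boundaries and exact operating characteristics.

An experimental arm is monitored in cohorts (default 10 patients, up to 30).
Let pi_tox be the arm's toxicity probability with a Beta(0.6, 1.4) prior.
At each look the arm is terminated if

    Pr(pi_tox > p0 | cumulative data) > cutoff

with p0 = 0.3 and cutoff = 0.8 by default, which translates into the
cumulative boundaries 5/10, 8/20, 12/30.  Operating characteristics
(early-stopping probability and expected sample size) are computed by exact
enumeration of binomial outcome paths over the look schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .posterior import BetaPrior

__all__ = [
    "ToxRule",
    "BoundarySchedule",
    "ToxOC",
    "stopping_boundary",
    "boundary_schedule",
    "exact_oc",
    "oc_table",
]


@dataclass(frozen=True)
class ToxRule:
    """Prior, unacceptable rate, posterior cutoff and look schedule for monitoring."""

    prior: BetaPrior = field(default_factory=lambda: BetaPrior(0.6, 1.4))
    unacceptable_rate: float = 0.3
    posterior_cutoff: float = 0.8
    cohort_size: int = 10
    max_n: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.unacceptable_rate < 1):
            raise ValueError(f"unacceptable_rate must be in (0, 1), got {self.unacceptable_rate}")
        if not (0 < self.posterior_cutoff < 1):
            raise ValueError(f"posterior_cutoff must be in (0, 1), got {self.posterior_cutoff}")
        if not (1 <= self.cohort_size <= self.max_n):
            raise ValueError("need 1 <= cohort_size <= max_n")
        if self.max_n % self.cohort_size != 0:
            raise ValueError("max_n must be divisible by cohort_size")

    @property
    def looks(self) -> list[int]:
        """Evaluation points: cumulative patient counts at each look."""
        return list(range(self.cohort_size, self.max_n + 1, self.cohort_size))


@dataclass(frozen=True)
class BoundarySchedule:
    """(n evaluated, minimum cumulative toxicities to stop) at each look.

    ``None`` at a look means no toxicity count up to that n can trigger a stop.
    """

    looks: tuple[tuple[int, int | None], ...]

    def __str__(self) -> str:
        parts = ["no stop" if b is None else f"{b}/{n}" for n, b in self.looks]
        return ", ".join(parts)


@dataclass(frozen=True)
class ToxOC:
    """Operating characteristics of a monitoring rule at one true toxicity rate.

    ``early_stop_prob`` is the probability of terminating at an interim look,
    i.e. before the full ``max_n`` patients are enrolled; a boundary crossing
    at the final look flags the arm but no longer shortens it, and is counted
    separately in ``boundary_hit_prob`` (crossing at any look).
    """

    true_rate: float
    early_stop_prob: float
    expected_n: float
    boundary_hit_prob: float


def stopping_boundary(rule: ToxRule, n: int) -> int | None:
    """Smallest toxicity count x among n patients that triggers termination.

    Returns the smallest x with Pr(pi > p0 | Beta(a + x, b + n - x)) > cutoff,
    or ``None`` if no x <= n qualifies.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    a, b = rule.prior.alpha, rule.prior.beta
    x = np.arange(n + 1)
    exceed = beta_dist.sf(rule.unacceptable_rate, a + x, b + n - x) > rule.posterior_cutoff
    hits = np.flatnonzero(exceed)
    return int(hits[0]) if hits.size else None


def boundary_schedule(rule: ToxRule) -> BoundarySchedule:
    """Stopping boundary at every look of the rule's cohort schedule."""
    return BoundarySchedule(tuple((n, stopping_boundary(rule, n)) for n in rule.looks))


def exact_oc(rule: ToxRule, true_rate: float) -> ToxOC:
    """Exact operating characteristics by enumeration of binomial paths.

    The continuing-path distribution of cumulative toxicities is propagated
    look to look; a path stops at the first look where the cumulative count
    reaches the boundary.  Expected sample size accumulates the patients
    added at each look weighted by the probability of reaching it.
    """
    if not (0.0 <= true_rate <= 1.0):
        raise ValueError(f"true_rate must be in [0, 1], got {true_rate}")
    schedule = boundary_schedule(rule).looks
    # probs[c] = Pr(cumulative toxicities == c and not yet stopped)
    probs = np.array([1.0])
    expected_n = 0.0
    early_stop = 0.0
    hit_any = 0.0
    prev_n = 0
    for i, (n, bound) in enumerate(schedule):
        add = n - prev_n
        reach = probs.sum()
        expected_n += add * reach
        pmf = binom.pmf(np.arange(add + 1), add, true_rate)
        probs = np.convolve(probs, pmf)
        if bound is not None:
            stopped = probs[bound:].sum()
            hit_any += stopped
            if i < len(schedule) - 1:
                early_stop += stopped
            probs = probs[:bound]
        prev_n = n
    return ToxOC(
        true_rate=true_rate,
        early_stop_prob=float(early_stop),
        expected_n=float(expected_n),
        boundary_hit_prob=float(hit_any),
    )


def oc_table(rule: ToxRule, true_rates) -> pd.DataFrame:
    """Operating characteristics at several true rates, as a tidy table."""
    rows = [exact_oc(rule, r) for r in true_rates]
    return pd.DataFrame(
        {
            "true_rate": [r.true_rate for r in rows],
            "early_stop_prob": [r.early_stop_prob for r in rows],
            "expected_n": [r.expected_n for r in rows],
        }
    )
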