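"""Exact (Clopper-Pearson) binomial confidence intervals.

The equal-tailed exact interval for a binomial proportion uses the beta
quantile characterization: with x successes out of n at level 1 - alpha,

    lower = BetaQuantile(alpha/2;     x,     n - x + 1)   (0 if x = 0)
    upper = BetaQuantile(1 - alpha/2; x + 1, n - x)       (1 if x = n)
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta as beta_dist

__all__ = ["ExactCI", "clopper_pearson"]


@dataclass(frozen=True)
class ExactCI:
    lower: float
    upper: float
    level: float

    def __str__(self) -> str:
        return f"({self.lower:.3f}, {self.upper:.3f})"


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> ExactCI:
    """Exact equal-tailed confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 <= successes <= n):
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes))
    return ExactCI(lower=lower, upper=upper, level=level)
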