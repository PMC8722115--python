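"""Grid calibration of the posterior decision threshold to a type-I-error target.

Under a null scenario (every experimental arm's true rate equal to the
control's) the threshold theta_t is chosen as the smallest grid value for
which the simulated probability of claiming success is at or below the
target for every experimental arm.  The same simulated posterior
probabilities are reused across the whole grid (common random numbers),
so the search is a single pass over one batch of replicates.
"""

from __future__ import annotations

import numpy as np

from .simulator import TrialScenario, replicate_posteriors

__all__ = ["calibrate_threshold", "CalibrationError"]


class CalibrationError(RuntimeError):
    """No grid value met the type-I-error constraint."""


def calibrate_threshold(
    scenario: TrialScenario,
    target_type1: float,
    grid_step: float = 0.01,
    reps: int = 1000,
    seed: int = 0,
    grid_lo: float = 0.50,
    grid_hi: float = 0.99,
) -> float:
    """Smallest grid threshold with worst-arm null success probability <= target.

    Parameters
    ----------
    scenario
        Null configuration: all experimental true rates must equal the
        control's true rate.
    target_type1
        Maximum tolerated per-arm probability of falsely claiming success.
    grid_step, grid_lo, grid_hi
        Candidate thresholds ``grid_lo, grid_lo + grid_step, ..., grid_hi``.
    reps, seed
        Monte-Carlo replicates of the null platform trial and master seed.

    Raises
    ------
    CalibrationError
        If even the largest grid value exceeds the target; the message
        reports the type-I error achieved there.
    """
    if not (0 < target_type1 <= 1):
        raise ValueError(f"target_type1 must be in (0, 1], got {target_type1}")
    control_rate = scenario.control_arm.true_rate
    if any(a.true_rate != control_rate for a in scenario.experimental_arms):
        raise ValueError("calibration requires a null scenario: all experimental true rates equal to the control rate")

    pp, _ = replicate_posteriors(scenario, reps=reps, seed=seed)
    grid = np.round(np.arange(grid_lo, grid_hi + grid_step / 2, grid_step), 10)
    for theta in grid:
        worst = float((pp > theta).mean(axis=0).max())
        if worst <= target_type1:
            return float(theta)
    worst_at_max = float((pp > grid[-1]).mean(axis=0).max())
    raise CalibrationError(
        f"no threshold in [{grid_lo}, {grid_hi}] meets type-I target {target_type1}; "
        f"achieved {worst_at_max:.4f} at theta={grid[-1]}"
    )
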