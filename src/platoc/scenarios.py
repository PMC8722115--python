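"""Scenario construction and YAML/JSON serialization.

Built-in scenarios mirror the protocol's two primary-endpoint designs:

* MPR (major pathological response, resectable cohorts): control rate 0.13,
  experimental rates 0.195 / 0.26 / 0.13 / 0.30, threshold 0.67;
* DCR (6-month disease control, locally advanced cohorts): control rate
  0.70, experimental rates 0.70 / 0.80 / 0.90 / 0.95, threshold 0.72.

Experimental arms of 30 patients enter at months 0, 6, 12, 18; the margin
is 0.05, priors Beta(1, 1), control cap 30, Poisson accrual 5/month.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from .posterior import BetaPrior, DecisionRule
from .randomization import ArmSpec
from .simulator import AccrualModel, TrialScenario

__all__ = [
    "mpr_scenario",
    "dcr_scenario",
    "null_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
]

MPR_CONTROL_RATE = 0.13
MPR_EXPERIMENTAL_RATES = (0.195, 0.26, 0.13, 0.30)
MPR_THETA = 0.67
DCR_CONTROL_RATE = 0.70
DCR_EXPERIMENTAL_RATES = (0.70, 0.80, 0.90, 0.95)
DCR_THETA = 0.72
ENTRY_TIMES = (0.0, 6.0, 12.0, 18.0)


def _build(endpoint: str, control_rate: float, exp_rates, theta_t: float, **kwargs: Any) -> TrialScenario:
    arms = [ArmSpec("control", "control", control_rate, planned_n=30, open_time=0.0)]
    for i, (rate, t) in enumerate(zip(exp_rates, ENTRY_TIMES), start=1):
        arms.append(ArmSpec(f"exp{i}", "experimental", rate, planned_n=30, open_time=t))
    return TrialScenario(arms=tuple(arms), rule=DecisionRule(theta_t=theta_t, delta=0.05), endpoint=endpoint, **kwargs)


def mpr_scenario(**kwargs: Any) -> TrialScenario:
    """Four-arm MPR platform design (threshold 0.67)."""
    return _build("MPR", MPR_CONTROL_RATE, MPR_EXPERIMENTAL_RATES, MPR_THETA, **kwargs)


def dcr_scenario(**kwargs: Any) -> TrialScenario:
    """Four-arm DCR platform design (threshold 0.72)."""
    return _build("DCR", DCR_CONTROL_RATE, DCR_EXPERIMENTAL_RATES, DCR_THETA, **kwargs)


def null_scenario(endpoint: str = "MPR", **kwargs: Any) -> TrialScenario:
    """Null configuration: every experimental rate equals the control's."""
    if endpoint.upper() == "MPR":
        return _build("MPR", MPR_CONTROL_RATE, (MPR_CONTROL_RATE,) * 4, MPR_THETA, **kwargs)
    if endpoint.upper() == "DCR":
        return _build("DCR", DCR_CONTROL_RATE, (DCR_CONTROL_RATE,) * 4, DCR_THETA, **kwargs)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def scenario_to_dict(scenario: TrialScenario) -> dict:
    return {
        "endpoint": scenario.endpoint,
        "theta_t": scenario.rule.theta_t,
        "delta": scenario.rule.delta,
        "prior_e": [scenario.prior_e.alpha, scenario.prior_e.beta],
        "prior_c": [scenario.prior_c.alpha, scenario.prior_c.beta],
        "accrual": {"kind": scenario.accrual.kind, "rate": scenario.accrual.rate},
        "control_cap": scenario.control_cap,
        "control_comparison": scenario.control_comparison,
        "analysis_delay_months": scenario.analysis_delay_months,
        "arms": [
            {
                "arm_id": a.arm_id,
                "role": a.role,
                "true_rate": a.true_rate,
                "planned_n": a.planned_n,
                "open_time": a.open_time,
            }
            for a in scenario.arms
        ],
    }


def scenario_from_dict(cfg: dict) -> TrialScenario:
    arms = tuple(
        ArmSpec(
            arm_id=a["arm_id"],
            role=a["role"],
            true_rate=float(a["true_rate"]),
            planned_n=int(a.get("planned_n", 30)),
            open_time=float(a.get("open_time", 0.0)),
        )
        for a in cfg["arms"]
    )
    accrual_cfg = cfg.get("accrual", {})
    return TrialScenario(
        arms=arms,
        rule=DecisionRule(theta_t=float(cfg["theta_t"]), delta=float(cfg.get("delta", 0.05))),
        endpoint=cfg.get("endpoint", "MPR"),
        prior_e=BetaPrior(*cfg.get("prior_e", [1.0, 1.0])),
        prior_c=BetaPrior(*cfg.get("prior_c", [1.0, 1.0])),
        accrual=AccrualModel(
            kind=accrual_cfg.get("kind", "poisson_process"),
            rate=float(accrual_cfg.get("rate", 5.0)),
        ),
        control_cap=int(cfg.get("control_cap", 30)),
        control_comparison=cfg.get("control_comparison", "final"),
        analysis_delay_months=float(cfg.get("analysis_delay_months", 0.0)),
    )


def load_scenario(path: str | Path) -> TrialScenario:
    """Read a scenario from a YAML or JSON file (keyed on extension)."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(cfg)


def save_scenario(scenario: TrialScenario, path: str | Path) -> None:
    path = Path(path)
    cfg = scenario_to_dict(scenario)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
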