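"""Intervention scenarios: counterfactual edits to decision probabilities.

A :class:`Scenario` pairs a side-effect-free selector (a conjunction of
attribute/history conditions evaluated on the agent's state at decision
time) with an action — override the probability, add percentage points, or
multiply — always clipped to [0, 1].  Agents outside the selector are
untouched, so under paired seeds their trajectories are identical to the
baseline run.

Three presets reproduce the published experiments:

* ``scenario1`` — agents whose last screening result was positive attend
  with probability 0.95 (override);
* ``scenario2`` — agents who have attended at least once get +5 percentage
  points;
* ``scenario3`` — students under 25 get +20 percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["Condition", "Scenario", "PRESETS", "apply_scenario", "compare_scenarios"]

_OPS = {
    "eq": lambda col, v: col == v,
    "ne": lambda col, v: col != v,
    "lt": lambda col, v: col < v,
    "le": lambda col, v: col <= v,
    "gt": lambda col, v: col > v,
    "ge": lambda col, v: col >= v,
    "in": lambda col, v: col.isin(list(v)),
}

ACTIONS = ("set", "add", "multiply")


@dataclass(frozen=True)
class Condition:
    """One comparison against an agent attribute or history field."""

    attribute: str
    op: str
    value: Union[str, float, int, bool, Sequence]

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown condition operator {self.op!r}")

    def mask(self, agents: pd.DataFrame) -> np.ndarray:
        if self.attribute not in agents.columns:
            raise KeyError(f"condition references unknown attribute {self.attribute!r}")
        return np.asarray(_OPS[self.op](agents[self.attribute], self.value), dtype=bool)

    def to_dict(self) -> dict:
        return {"attribute": self.attribute, "op": self.op, "value": self.value}


@dataclass(frozen=True)
class Scenario:
    """A named intervention: selector conditions (AND) plus one action."""

    name: str
    conditions: tuple  # of Condition
    action: str
    value: float

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown scenario action {self.action!r}")
        if self.action == "set" and not 0.0 <= self.value <= 1.0:
            raise ValueError("set action value must be a probability in [0, 1]")

    def selector(self, agents: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(agents), dtype=bool)
        for cond in self.conditions:
            mask &= cond.mask(agents)
        return mask

    def apply(self, agents: pd.DataFrame, p: np.ndarray) -> np.ndarray:
        """Modified probabilities; unselected agents keep ``p`` bitwise."""
        p = np.asarray(p, dtype=float)
        mask = self.selector(agents)
        out = p.copy()
        if self.action == "set":
            out[mask] = self.value
        elif self.action == "add":
            out[mask] = np.clip(p[mask] + self.value, 0.0, 1.0)
        else:
            out[mask] = np.clip(p[mask] * self.value, 0.0, 1.0)
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "conditions": [c.to_dict() for c in self.conditions],
            "action": self.action,
            "value": self.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            name=d["name"],
            conditions=tuple(Condition(**c) for c in d.get("conditions", [])),
            action=d["action"],
            value=float(d["value"]),
        )


def apply_scenario(scenario: Scenario, agents: pd.DataFrame, p) -> np.ndarray:
    """Functional form of :meth:`Scenario.apply` (clips to [0, 1])."""
    return scenario.apply(agents, p)


PRESETS: Dict[str, Scenario] = {
    "scenario1": Scenario(
        name="scenario1",
        conditions=(Condition("last_result", "eq", "positive"),),
        action="set",
        value=0.95,
    ),
    "scenario2": Scenario(
        name="scenario2",
        conditions=(Condition("times_attended", "ge", 1),),
        action="add",
        value=0.05,
    ),
    "scenario3": Scenario(
        name="scenario3",
        conditions=(Condition("age", "lt", 25), Condition("student_flag", "eq", True)),
        action="add",
        value=0.20,
    ),
}


def compare_scenarios(baseline_results: Sequence, scenario_results: Sequence) -> pd.DataFrame:
    """Per-subregion adherence deltas between paired baseline/scenario arms.

    Both arms are lists of :class:`~drscreen.simulate.RunResult` produced
    from the same population with paired seeds; rates are means over
    replicates.  Returns columns ``baseline_pct``, ``scenario_pct``,
    ``difference_pct`` per subregion plus an ``Overall`` row.
    """

    def mean_rates(results):
        rates = pd.concat([r.adherence_rates() for r in results], axis=1).mean(axis=1)
        overall = float(np.mean([r.overall_adherence() for r in results]))
        return rates, overall

    base_rates, base_overall = mean_rates(baseline_results)
    scen_rates, scen_overall = mean_rates(scenario_results)
    if set(base_rates.index) != set(scen_rates.index):
        raise ValueError(
            "mismatched subregion sets: "
            f"{sorted(set(base_rates.index) ^ set(scen_rates.index))}"
        )
    table = pd.DataFrame(
        {
            "baseline_pct": base_rates,
            "scenario_pct": scen_rates.reindex(base_rates.index),
        }
    )
    table.loc["Overall"] = [base_overall, scen_overall]
    table["difference_pct"] = table["scenario_pct"] - table["baseline_pct"]
    table.index.name = "subregion"
    return table
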