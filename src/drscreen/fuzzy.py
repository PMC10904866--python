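"""Mamdani fuzzy-inference machinery for the individual adherence decision.

The agent's propensity to attend a screening appointment is expressed through
three fuzzy components rooted in the Health Belief Model:

* ``access_barriers`` — perceived barriers as a function of age (B1), income
  (B2), screening-location difficulty (B3) and degree of urbanization (B4);
* ``disease_knowledge`` — knowledge of the disease as a function of age (C1),
  educational qualifications (C2) and prior adherence (C3);
* ``program_quality`` — quality of the screening strategy as a function of
  reminder practice (E1), waiting time (E2) and call-notice lead time (E3).

Each input variable carries exactly two linguistic terms (a binary partition,
e.g. "easy"/"difficult").  Rules are generated combinatorially from an
"at-least-half favorable" template, activations use the minimum t-norm,
consequent sets are clipped at the activation level, aggregated by pointwise
maximum and defuzzified by centre of gravity (COG) on a discretized output
domain.  Component scores live on a 0–100 propensity scale.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "MembershipFunction",
    "FuzzyVariable",
    "FuzzyRule",
    "FuzzyComponent",
    "evaluate_membership",
    "fire_rule",
    "aggregate_and_defuzzify",
    "component_scores",
    "generate_majority_rules",
    "build_default_components",
    "components_to_json",
    "components_from_json",
    "COG_GRID_POINTS",
]

#: Number of evenly spaced points used to discretize an output domain for COG.
COG_GRID_POINTS = 1001

MF_KINDS = ("linear_two_point", "gaussian", "max_of_gaussians")


class ConfigurationError(ValueError):
    """Raised for invalid fuzzy-system definitions (bad kind, σ ≤ 0, ...)."""


# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembershipFunction:
    """A membership function over a closed domain, valued in [0, 1].

    Parameters
    ----------
    kind:
        ``linear_two_point`` — the line through two anchor points, clamped to
        [0, 1]; ``gaussian`` — peak-normalized exp(−(x−c)²/(2σ²));
        ``max_of_gaussians`` — pointwise maximum of two gaussians with a
        shared spread.
    params:
        ``linear_two_point``: ((x0, y0), (x1, y1)); ``gaussian``: (c, sigma);
        ``max_of_gaussians``: (c1, c2, sigma).
    domain:
        Closed interval (lo, hi) in the variable's units.

    Gaussians here are fuzzy memberships normalized to peak 1 at the centre,
    not probability densities.
    """

    kind: str
    params: tuple
    domain: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in MF_KINDS:
            raise ConfigurationError(
                f"unknown membership kind {self.kind!r}; expected one of {MF_KINDS}"
            )
        lo, hi = self.domain
        if not lo < hi:
            raise ConfigurationError(f"empty domain [{lo}, {hi}]")
        if self.kind == "gaussian":
            _, sigma = self.params
            if sigma <= 0:
                raise ConfigurationError(f"gaussian spread must be positive, got {sigma}")
        elif self.kind == "max_of_gaussians":
            _, _, sigma = self.params
            if sigma <= 0:
                raise ConfigurationError(f"gaussian spread must be positive, got {sigma}")
        elif self.kind == "linear_two_point":
            (x0, _), (x1, _) = self.params
            if x0 == x1:
                raise ConfigurationError("linear anchors must have distinct x")

    def __call__(self, x):
        return evaluate_membership(self, x)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": _listify(self.params), "domain": list(self.domain)}

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipFunction":
        params = d["params"]
        if d["kind"] == "linear_two_point":
            params = (tuple(params[0]), tuple(params[1]))
        else:
            params = tuple(params)
        return cls(kind=d["kind"], params=params, domain=tuple(d["domain"]))


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(o) for o in obj]
    return obj


def evaluate_membership(mf: MembershipFunction, x):
    """Evaluate ``mf`` at ``x`` (scalar or array), clamping x to the domain.

    Returns degrees in [0, 1]; out-of-domain inputs are clamped with a logged
    warning.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = mf.domain
    if np.any(x < lo) or np.any(x > hi):
        logger.warning(
            "input outside domain [%s, %s] clamped for %s membership", lo, hi, mf.kind
        )
        x = np.clip(x, lo, hi)
    if mf.kind == "linear_two_point":
        (x0, y0), (x1, y1) = mf.params
        y = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        out = np.clip(y, 0.0, 1.0)
    elif mf.kind == "gaussian":
        c, sigma = mf.params
        out = np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
    else:  # max_of_gaussians
        c1, c2, sigma = mf.params
        g1 = np.exp(-((x - c1) ** 2) / (2.0 * sigma**2))
        g2 = np.exp(-((x - c2) ** 2) / (2.0 * sigma**2))
        out = np.maximum(g1, g2)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Variables, rules, components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyVariable:
    """A linguistic variable: a domain plus labelled membership functions.

    Every variable in this model carries exactly two terms (binary
    partition); the output "propensity" variables do too (strong/weak).
    """

    name: str
    domain: Tuple[float, float]
    terms: Mapping[str, MembershipFunction]
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.terms) != 2:
            raise ConfigurationError(
                f"variable {self.name!r} must have exactly two terms, got {len(self.terms)}"
            )
        for label, mf in self.terms.items():
            if tuple(mf.domain) != tuple(self.domain):
                raise ConfigurationError(
                    f"term {label!r} of {self.name!r} has domain {mf.domain}, "
                    f"expected {self.domain}"
                )

    def membership(self, label: str, x):
        if label not in self.terms:
            raise ConfigurationError(f"variable {self.name!r} has no term {label!r}")
        return evaluate_membership(self.terms[label], x)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domain": list(self.domain),
            "units": self.units,
            "terms": {label: mf.to_dict() for label, mf in self.terms.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyVariable":
        return cls(
            name=d["name"],
            domain=tuple(d["domain"]),
            units=d.get("units", ""),
            terms={k: MembershipFunction.from_dict(v) for k, v in d["terms"].items()},
        )


@dataclass(frozen=True)
class FuzzyRule:
    """An IF–THEN rule; antecedents combine with the minimum t-norm."""

    antecedents: Tuple[Tuple[str, str], ...]  # (variable name, linguistic label)
    consequent: Tuple[str, str]  # (output variable name, linguistic label)

    def to_dict(self) -> dict:
        return {"if": [list(a) for a in self.antecedents], "then": list(self.consequent)}

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyRule":
        return cls(
            antecedents=tuple((a[0], a[1]) for a in d["if"]),
            consequent=(d["then"][0], d["then"][1]),
        )

    def describe(self) -> str:
        cond = " AND ".join(f"{v} IS {t}" for v, t in self.antecedents)
        return f"IF {cond} THEN {self.consequent[0]} IS {self.consequent[1]}"


@dataclass(frozen=True)
class FuzzyComponent:
    """One decision component: inputs, an output variable, and a rule base."""

    name: str
    inputs: Tuple[FuzzyVariable, ...]
    output: FuzzyVariable
    rules: Tuple[FuzzyRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ConfigurationError(f"component {self.name!r} has an empty rule base")
        declared = {v.name: set(v.terms) for v in self.inputs}
        for rule in self.rules:
            for var, label in rule.antecedents:
                if var not in declared:
                    raise ConfigurationError(
                        f"rule references undeclared variable {var!r} in {self.name!r}"
                    )
                if label not in declared[var]:
                    raise ConfigurationError(
                        f"rule references unknown term {label!r} of {var!r}"
                    )
            out_var, out_label = rule.consequent
            if out_var != self.output.name or out_label not in self.output.terms:
                raise ConfigurationError(
                    f"rule consequent {rule.consequent!r} does not match output "
                    f"variable {self.output.name!r}"
                )

    @property
    def input_names(self) -> Tuple[str, ...]:
        return tuple(v.name for v in self.inputs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "inputs": [v.to_dict() for v in self.inputs],
            "output": self.output.to_dict(),
            "rules": [r.to_dict() for r in self.rules],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyComponent":
        return cls(
            name=d["name"],
            inputs=tuple(FuzzyVariable.from_dict(v) for v in d["inputs"]),
            output=FuzzyVariable.from_dict(d["output"]),
            rules=tuple(FuzzyRule.from_dict(r) for r in d["rules"]),
        )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def fire_rule(
    rule: FuzzyRule,
    crisp_inputs: Mapping[str, float],
    variables: Mapping[str, FuzzyVariable],
) -> float:
    """Rule activation: minimum over antecedent memberships."""
    degrees = []
    for var, label in rule.antecedents:
        if var not in crisp_inputs:
            raise KeyError(f"missing crisp input for variable {var!r}")
        degrees.append(variables[var].membership(label, crisp_inputs[var]))
    return float(min(degrees))


def _output_grid(output: FuzzyVariable) -> np.ndarray:
    lo, hi = output.domain
    return np.linspace(lo, hi, COG_GRID_POINTS)


def component_scores(component: FuzzyComponent, crisp_inputs: Mapping[str, np.ndarray]) -> np.ndarray:
    """Vectorized Mamdani inference for a batch of agents.

    ``crisp_inputs`` maps each input-variable name to a scalar or an array of
    crisp values (broadcast together).  Returns the COG score for each sample;
    samples whose aggregate is identically zero fall back to the domain
    midpoint.
    """
    variables = {v.name: v for v in component.inputs}
    for name in variables:
        if name not in crisp_inputs:
            raise KeyError(f"missing crisp input for variable {name!r}")
    # memberships[(var, label)] -> array of degrees per sample
    memberships: Dict[Tuple[str, str], np.ndarray] = {}
    shape = np.broadcast_shapes(*(np.shape(np.asarray(crisp_inputs[n])) for n in variables))
    for name, var in variables.items():
        x = np.broadcast_to(np.asarray(crisp_inputs[name], dtype=float), shape)
        for label in var.terms:
            memberships[(name, label)] = np.atleast_1d(var.membership(label, x))
    n = int(np.prod(shape)) if shape else 1

    # For each output term, the aggregation level is the max activation over
    # rules with that consequent (max over rules of min(act, term) collapses
    # to min(max act, term) for a shared consequent set).
    levels = {label: np.zeros(n) for label in component.output.terms}
    for rule in component.rules:
        act = np.ones(n)
        for var, label in rule.antecedents:
            act = np.minimum(act, memberships[(var, label)].reshape(n))
        out_label = rule.consequent[1]
        levels[out_label] = np.maximum(levels[out_label], act)

    grid = _output_grid(component.output)
    aggregate = np.zeros((n, grid.size))
    for label, level in levels.items():
        term_on_grid = np.atleast_1d(component.output.membership(label, grid))
        aggregate = np.maximum(aggregate, np.minimum(term_on_grid[None, :], level[:, None]))

    # Trapezoid-rule centroid on the uniform grid.
    w = np.ones_like(grid)
    w[0] = w[-1] = 0.5
    denom = aggregate @ w
    numer = aggregate @ (w * grid)
    lo, hi = component.output.domain
    midpoint = 0.5 * (lo + hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, numer / np.maximum(denom, 1e-300), midpoint)
    return scores.reshape(shape) if shape else float(scores[0])


def aggregate_and_defuzzify(component: FuzzyComponent, crisp_inputs: Mapping[str, float]) -> float:
    """Mamdani inference for one sample: clip, aggregate by max, COG.

    Returns the centre of gravity of the aggregated output set on the
    component's output domain; the domain midpoint if no rule fires.
    """
    out = component_scores(component, {k: np.asarray(v, dtype=float) for k, v in crisp_inputs.items()})
    return float(np.asarray(out).reshape(-1)[0])


# ---------------------------------------------------------------------------
# Rule generation
# ---------------------------------------------------------------------------


def generate_majority_rules(
    input_vars: Sequence[FuzzyVariable],
    favorable_labels: Mapping[str, str],
    output: FuzzyVariable,
    strong_label: str = "strong",
    weak_label: str = "weak",
) -> List[FuzzyRule]:
    """Enumerate all 2^n label combinations with an at-least-half template.

    The consequent is ``strong`` when the number of favorable labels in the
    antecedent is at least ⌈n/2⌉, else ``weak``.
    """
    for var in input_vars:
        if len(var.terms) != 2:
            raise ConfigurationError(
                f"majority rules require binary variables; {var.name!r} has "
                f"{len(var.terms)} terms"
            )
        if favorable_labels.get(var.name) not in var.terms:
            raise ConfigurationError(
                f"favorable label for {var.name!r} missing or not a declared term"
            )
    n = len(input_vars)
    threshold = math.ceil(n / 2)
    rules: List[FuzzyRule] = []
    label_choices = [tuple(v.terms) for v in input_vars]
    for combo in itertools.product(*label_choices):
        favorable = sum(
            1 for var, label in zip(input_vars, combo) if label == favorable_labels[var.name]
        )
        consequent_label = strong_label if favorable >= threshold else weak_label
        rules.append(
            FuzzyRule(
                antecedents=tuple((v.name, label) for v, label in zip(input_vars, combo)),
                consequent=(output.name, consequent_label),
            )
        )
    return rules


# ---------------------------------------------------------------------------
# Default model definition
# ---------------------------------------------------------------------------


def _propensity_output(name: str = "propensity") -> FuzzyVariable:
    dom = (0.0, 100.0)
    return FuzzyVariable(
        name=name,
        domain=dom,
        units="score",
        terms={
            "strong": MembershipFunction("linear_two_point", ((0.0, 0.0), (100.0, 1.0)), dom),
            "weak": MembershipFunction("linear_two_point", ((0.0, 1.0), (100.0, 0.0)), dom),
        },
    )


def build_default_components() -> Dict[str, FuzzyComponent]:
    """The three shipped components with every published parameter.

    Variable inventory (favorable label listed first):

    * access_barriers — age (easy: line (0,0)-(100,1); difficult: line
      (0,1)-(100,0)); income €/yr (easy: max of gaussians at 0 and 100,000,
      σ=17,000; difficult: gaussian at 50,000, σ=17,000); location score
      (easy: line (0,1)-(100,0); difficult: line (0,0)-(100,1));
      urbanization (easy: max of gaussians at 0 and 0.5, σ=0.1; difficult:
      gaussian at 0.3, σ=0.1).
    * disease_knowledge — age (high: gaussian at 65, σ=30; low: max of
      gaussians at 18 and 100, σ=30); education score (high: line
      (0,0)-(100,1)); prior-adherence % (high: line (0,0)-(100,1)).
    * program_quality — reminder score (high: line (0,0)-(100,1)); waiting
      time min (high: line (0,1)-(500,0)); notice lead weeks (high: gaussian
      at 4, σ=2; low: max of gaussians at 0 and 8, σ=2).
    """
    d100 = (0.0, 100.0)

    age_b = FuzzyVariable(
        "age_barrier",
        d100,
        units="years",
        terms={
            "easy": MembershipFunction("linear_two_point", ((0.0, 0.0), (100.0, 1.0)), d100),
            "difficult": MembershipFunction("linear_two_point", ((0.0, 1.0), (100.0, 0.0)), d100),
        },
    )
    dinc = (0.0, 100000.0)
    income = FuzzyVariable(
        "income",
        dinc,
        units="EUR/year",
        terms={
            "easy": MembershipFunction("max_of_gaussians", (0.0, 100000.0, 17000.0), dinc),
            "difficult": MembershipFunction("gaussian", (50000.0, 17000.0), dinc),
        },
    )
    location = FuzzyVariable(
        "location",
        d100,
        units="difficulty score",
        terms={
            "easy": MembershipFunction("linear_two_point", ((0.0, 1.0), (100.0, 0.0)), d100),
            "difficult": MembershipFunction("linear_two_point", ((0.0, 0.0), (100.0, 1.0)), d100),
        },
    )
    durb = (0.0, 1.0)
    urbanization = FuzzyVariable(
        "urbanization",
        durb,
        units="degree",
        terms={
            "easy": MembershipFunction("max_of_gaussians", (0.0, 0.5, 0.1), durb),
            "difficult": MembershipFunction("gaussian", (0.3, 0.1), durb),
        },
    )

    age_k = FuzzyVariable(
        "age_knowledge",
        d100,
        units="years",
        terms={
            "high": MembershipFunction("gaussian", (65.0, 30.0), d100),
            "low": MembershipFunction("max_of_gaussians", (18.0, 100.0, 30.0), d100),
        },
    )
    education = FuzzyVariable(
        "education",
        d100,
        units="qualification score",
        terms={
            "high": MembershipFunction("linear_two_point", ((0.0, 0.0), (100.0, 1.0)), d100),
            "low": MembershipFunction("linear_two_point", ((0.0, 1.0), (100.0, 0.0)), d100),
        },
    )
    prior_adherence = FuzzyVariable(
        "prior_adherence",
        d100,
        units="%",
        terms={
            "high": MembershipFunction("linear_two_point", ((0.0, 0.0), (100.0, 1.0)), d100),
            "low": MembershipFunction("linear_two_point", ((0.0, 1.0), (100.0, 0.0)), d100),
        },
    )

    reminders = FuzzyVariable(
        "reminders",
        d100,
        units="intensity score",
        terms={
            "high": MembershipFunction("linear_two_point", ((0.0, 0.0), (100.0, 1.0)), d100),
            "low": MembershipFunction("linear_two_point", ((0.0, 1.0), (100.0, 0.0)), d100),
        },
    )
    dwait = (0.0, 500.0)
    waiting_time = FuzzyVariable(
        "waiting_time",
        dwait,
        units="minutes",
        terms={
            "high": MembershipFunction("linear_two_point", ((0.0, 1.0), (500.0, 0.0)), dwait),
            "low": MembershipFunction("linear_two_point", ((0.0, 0.0), (500.0, 1.0)), dwait),
        },
    )
    dnotice = (0.0, 12.0)
    notice = FuzzyVariable(
        "notice",
        dnotice,
        units="weeks",
        terms={
            "high": MembershipFunction("gaussian", (4.0, 2.0), dnotice),
            "low": MembershipFunction("max_of_gaussians", (0.0, 8.0, 2.0), dnotice),
        },
    )

    out = _propensity_output()

    barriers_inputs = (age_b, income, location, urbanization)
    barriers = FuzzyComponent(
        name="access_barriers",
        inputs=barriers_inputs,
        output=out,
        rules=tuple(
            generate_majority_rules(
                barriers_inputs,
                {"age_barrier": "easy", "income": "easy", "location": "easy", "urbanization": "easy"},
                out,
            )
        ),
    )
    knowledge_inputs = (age_k, education, prior_adherence)
    knowledge = FuzzyComponent(
        name="disease_knowledge",
        inputs=knowledge_inputs,
        output=out,
        rules=tuple(
            generate_majority_rules(
                knowledge_inputs,
                {"age_knowledge": "high", "education": "high", "prior_adherence": "high"},
                out,
            )
        ),
    )
    quality_inputs = (reminders, waiting_time, notice)
    quality = FuzzyComponent(
        name="program_quality",
        inputs=quality_inputs,
        output=out,
        rules=tuple(
            generate_majority_rules(
                quality_inputs,
                {"reminders": "high", "waiting_time": "high", "notice": "high"},
                out,
            )
        ),
    )
    return {c.name: c for c in (barriers, knowledge, quality)}


def components_to_json(components: Mapping[str, FuzzyComponent], path=None) -> str:
    """Serialize components (variables, parameters, rules) to JSON text."""
    text = json.dumps({k: c.to_dict() for k, c in components.items()}, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def components_from_json(source: str) -> Dict[str, FuzzyComponent]:
    """Inverse of :func:`components_to_json`; accepts JSON text."""
    data = json.loads(source)
    return {k: FuzzyComponent.from_dict(v) for k, v in data.items()}
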