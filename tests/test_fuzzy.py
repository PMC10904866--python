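"""Mamdani machinery: memberships, rules, COG, rule generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drscreen.fuzzy import (
    ConfigurationError,
    FuzzyRule,
    FuzzyVariable,
    MembershipFunction,
    aggregate_and_defuzzify,
    build_default_components,
    component_scores,
    components_from_json,
    components_to_json,
    evaluate_membership,
    fire_rule,
    generate_majority_rules,
)

from _cog_oracle import cog_score, random_inputs


# ---------------------------------------------------------------------------
# membership functions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mf, x, expected",
    [
        # line through (0,1),(100,0) at its midpoint
        (MembershipFunction("linear_two_point", ((0, 1), (100, 0)), (0, 100)), 50.0, 0.5),
        # gaussian peak is exactly 1 at the centre (call-notice "high quality")
        (MembershipFunction("gaussian", (4.0, 2.0), (0, 12)), 4.0, 1.0),
        # max of gaussians at 0 and 8 (σ=2) evaluated at 4 → exp(−2)
        (MembershipFunction("max_of_gaussians", (0.0, 8.0, 2.0), (0, 12)), 4.0, math.exp(-2)),
        # income "difficult" gaussian (c=50000, σ=17000) at 33000 → exp(−0.5)
        (MembershipFunction("gaussian", (50000.0, 17000.0), (0, 100000)), 33000.0, math.exp(-0.5)),
        # linear clamps to [0,1] outside the anchor range
        (MembershipFunction("linear_two_point", ((20, 0), (80, 1)), (0, 100)), 95.0, 1.0),
        (MembershipFunction("linear_two_point", ((20, 0), (80, 1)), (0, 100)), 5.0, 0.0),
    ],
)
def test_membership_values(mf, x, expected):
    assert evaluate_membership(mf, x) == pytest.approx(expected, abs=1e-12)


def test_membership_configuration_errors():
    with pytest.raises(ConfigurationError):
        MembershipFunction("triangular", (0, 1, 2), (0, 100))
    with pytest.raises(ConfigurationError):
        MembershipFunction("gaussian", (50.0, 0.0), (0, 100))
    with pytest.raises(ConfigurationError):
        MembershipFunction("max_of_gaussians", (0.0, 8.0, -1.0), (0, 12))


def test_out_of_domain_inputs_clamped(caplog):
    mf = MembershipFunction("linear_two_point", ((0, 1), (100, 0)), (0, 100))
    with caplog.at_level("WARNING", logger="drscreen.fuzzy"):
        assert evaluate_membership(mf, 150.0) == evaluate_membership(mf, 100.0)
    assert any("clamped" in rec.message for rec in caplog.records)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    x=st.floats(min_value=0.0, max_value=100.0),
    kind=st.sampled_from(["linear_two_point", "gaussian", "max_of_gaussians"]),
)
def test_membership_always_in_unit_interval(x, kind):
    if kind == "linear_two_point":
        mf = MembershipFunction(kind, ((0, 1.0), (100, -0.5)), (0, 100))
    elif kind == "gaussian":
        mf = MembershipFunction(kind, (37.0, 11.0), (0, 100))
    else:
        mf = MembershipFunction(kind, (10.0, 90.0, 14.0), (0, 100))
    assert 0.0 <= evaluate_membership(mf, x) <= 1.0


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


def _binary_var(name, lo=0.0, hi=100.0):
    dom = (lo, hi)
    return FuzzyVariable(
        name,
        dom,
        terms={
            "high": MembershipFunction("linear_two_point", ((lo, 0.0), (hi, 1.0)), dom),
            "low": MembershipFunction("linear_two_point", ((lo, 1.0), (hi, 0.0)), dom),
        },
    )


def test_fire_rule_is_min_of_antecedent_memberships():
    vars_ = {f"v{i}": _binary_var(f"v{i}") for i in range(4)}
    rule = FuzzyRule(
        antecedents=tuple((f"v{i}", "high") for i in range(4)), consequent=("out", "strong")
    )
    crisp = {"v0": 80.0, "v1": 60.0, "v2": 90.0, "v3": 50.0}
    assert fire_rule(rule, crisp, vars_) == pytest.approx(0.5)


def test_fire_rule_zero_membership_absorbs():
    vars_ = {"v0": _binary_var("v0"), "v1": _binary_var("v1")}
    rule = FuzzyRule(antecedents=(("v0", "high"), ("v1", "high")), consequent=("out", "strong"))
    assert fire_rule(rule, {"v0": 0.0, "v1": 100.0}, vars_) == 0.0


def test_fire_rule_single_antecedent_is_identity():
    vars_ = {"v0": _binary_var("v0")}
    rule = FuzzyRule(antecedents=(("v0", "high"),), consequent=("out", "strong"))
    assert fire_rule(rule, {"v0": 73.0}, vars_) == pytest.approx(0.73)


def test_fire_rule_missing_input_names_the_variable():
    vars_ = {"v0": _binary_var("v0"), "v1": _binary_var("v1")}
    rule = FuzzyRule(antecedents=(("v0", "high"), ("v1", "high")), consequent=("out", "strong"))
    with pytest.raises(KeyError, match="v1"):
        fire_rule(rule, {"v0": 50.0}, vars_)


# ---------------------------------------------------------------------------
# aggregation and defuzzification
# ---------------------------------------------------------------------------


def test_cog_of_pure_strong_term_matches_closed_form(components):
    # age 65 peaks the "high knowledge" gaussian; education and prior
    # adherence at 100 zero out every weak rule, so the aggregate is exactly
    # the strong consequent μ(x)=x/100, whose centroid is 200/3.
    score = aggregate_and_defuzzify(
        components["disease_knowledge"],
        {"age_knowledge": 65.0, "education": 100.0, "prior_adherence": 100.0},
    )
    assert score == pytest.approx(200.0 / 3.0, abs=0.01)


def test_cog_symmetric_aggregate_is_midpoint(components):
    # at the crossing point of the two linear terms every input membership is
    # 0.5, so strong and weak are clipped at the same level and the aggregate
    # is symmetric about 50
    comp = components["disease_knowledge"]
    # age 41.5 is the crossing of the high (centre 65) and low (centre 18)
    # gaussians, so every variable has equal memberships in its two terms
    score = aggregate_and_defuzzify(
        comp, {"age_knowledge": 41.5, "education": 50.0, "prior_adherence": 50.0}
    )
    assert score == pytest.approx(50.0, abs=0.05)


def test_cog_empty_aggregate_falls_back_to_midpoint():
    dom = (0.0, 100.0)
    v = _binary_var("v")
    out = FuzzyVariable(
        "out",
        dom,
        terms={
            # both consequent terms vanish where the single rule can fire
            "strong": MembershipFunction("gaussian", (50.0, 5.0), dom),
            "weak": MembershipFunction("gaussian", (60.0, 5.0), dom),
        },
    )
    from drscreen.fuzzy import FuzzyComponent

    comp = FuzzyComponent(
        name="access_barriers",
        inputs=(v,),
        output=out,
        rules=(FuzzyRule(antecedents=(("v", "high"),), consequent=("out", "strong")),),
    )
    assert aggregate_and_defuzzify(comp, {"v": 0.0}) == pytest.approx(50.0)


def test_cog_within_output_domain_random_inputs(components):
    rng = np.random.default_rng(0)
    for comp in components.values():
        for _ in range(25):
            score = aggregate_and_defuzzify(comp, random_inputs(comp, rng))
            assert 0.0 <= score <= 100.0


def test_cog_agrees_with_bruteforce_oracle(components):
    rng = np.random.default_rng(2024)
    for comp in components.values():
        for _ in range(40):
            crisp = random_inputs(comp, rng)
            assert aggregate_and_defuzzify(comp, crisp) == pytest.approx(
                cog_score(comp, crisp), abs=0.1
            )


def test_component_scores_vectorized_matches_scalar(components):
    comp = components["program_quality"]
    rng = np.random.default_rng(3)
    batch = {v.name: rng.uniform(v.domain[0], v.domain[1], size=20) for v in comp.inputs}
    vec = component_scores(comp, batch)
    for i in range(20):
        scalar = aggregate_and_defuzzify(comp, {k: float(v[i]) for k, v in batch.items()})
        assert vec[i] == pytest.approx(scalar, abs=1e-9)


def test_monotone_in_prior_adherence(components):
    # prior adherence enters only through monotone linear terms, so raising
    # it can never lower the knowledge score
    comp = components["disease_knowledge"]
    xs = np.linspace(0, 100, 41)
    scores = component_scores(
        comp, {"age_knowledge": np.full_like(xs, 55.0), "education": np.full_like(xs, 30.0), "prior_adherence": xs}
    )
    assert np.all(np.diff(scores) >= -1e-9)


# ---------------------------------------------------------------------------
# rule generation
# ---------------------------------------------------------------------------


def test_majority_rules_counts_and_exhaustive(components):
    for comp, expected in (("access_barriers", 16), ("disease_knowledge", 8), ("program_quality", 8)):
        rules = components[comp].rules
        assert len(rules) == expected
        antecedent_tuples = {r.antecedents for r in rules}
        assert len(antecedent_tuples) == expected  # duplicate-free
        assert len(rules[0].antecedents) == int(np.log2(expected))


def test_majority_rule_consequents(components):
    favorable = {
        "access_barriers": {"age_barrier": "easy", "income": "easy", "location": "easy", "urbanization": "easy"},
        "disease_knowledge": {"age_knowledge": "high", "education": "high", "prior_adherence": "high"},
        "program_quality": {"reminders": "high", "waiting_time": "high", "notice": "high"},
    }
    for name, comp in components.items():
        n = len(comp.inputs)
        threshold = -(-n // 2)  # ceil
        for rule in comp.rules:
            count = sum(1 for var, label in rule.antecedents if favorable[name][var] == label)
            expected = "strong" if count >= threshold else "weak"
            assert rule.consequent[1] == expected


def test_two_of_three_favorable_is_strong():
    vars_ = [_binary_var(f"v{i}") for i in range(3)]
    out = _binary_var("out")
    rules = generate_majority_rules(vars_, {v.name: "high" for v in vars_}, out, "high", "low")
    assert len(rules) == 8
    combo = tuple((f"v{i}", lab) for i, lab in enumerate(("high", "high", "low")))
    rule = next(r for r in rules if r.antecedents == combo)
    assert rule.consequent[1] == "high"


def test_majority_rules_reject_nonbinary_variable():
    dom = (0.0, 100.0)
    with pytest.raises(ConfigurationError):
        FuzzyVariable("v", dom, terms={"a": MembershipFunction("gaussian", (50, 10), dom)})


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_components_json_round_trip(components):
    text = components_to_json(components)
    restored = components_from_json(text)
    assert set(restored) == set(components)
    for name in components:
        assert restored[name].to_dict() == components[name].to_dict()
    # restored machinery behaves identically
    crisp = {"reminders": 10.0, "waiting_time": 10.0, "notice": 4.0}
    assert aggregate_and_defuzzify(restored["program_quality"], crisp) == pytest.approx(
        aggregate_and_defuzzify(components["program_quality"], crisp)
    )


def test_shipped_definition_file_reproduces_builder(components):
    from pathlib import Path

    shipped = Path(components_to_json.__globals__["__file__"]).parent / "data" / "fuzzy_components.json"
    restored = components_from_json(shipped.read_text())
    for name in components:
        assert restored[name].to_dict() == components[name].to_dict()
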