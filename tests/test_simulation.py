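"""Weekly engine: state machine, outcome sampling, replicates, conservation."""

import math

import numpy as np
import pandas as pd
import pytest

from drscreen.decision import DecisionConfig, LogisticModel
from drscreen.population import ROSTER_COLUMNS
from drscreen.simulate import (
    RunResult,
    ScreeningConfig,
    SimulationError,
    run_replicates,
    run_simulation,
    sample_outcome,
    sample_outcomes,
)

ALWAYS = LogisticModel(intercept=40.0, coefficients={})
NEVER = LogisticModel(intercept=-40.0, coefficients={})
CONSTANT_P = lambda p: LogisticModel(intercept=math.log(p / (1 - p)), coefficients={})


def one_agent_roster(**overrides):
    row = {
        "id": 0,
        "subregion": "Ave",
        "age": 60.0,
        "gender": "female",
        "income": 9800.0,
        "education_score": 40.0,
        "urbanization": 0.6,
        "occupation": "retired",
        "student_flag": False,
        "cluster": 2,
        "times_called": 0,
        "times_attended": 0,
        "pct_prior_adherence": 0.0,
        "last_result": "none",
        "state": "not_called",
        "next_call_week": 0,
    }
    row.update(overrides)
    return pd.DataFrame([row])[ROSTER_COLUMNS]


# ---------------------------------------------------------------------------
# outcome sampling
# ---------------------------------------------------------------------------


def test_marginal_outcome_fractions():
    cfg = ScreeningConfig()
    out = sample_outcomes(cfg, np.random.default_rng(0), 100_000)
    p_pos = (out == "positive").mean()
    p_neg = (out == "negative").mean()
    se_pos = math.sqrt(0.04 * 0.96 / 100_000)
    se_neg = math.sqrt(0.93 * 0.07 / 100_000)
    assert abs(p_pos - 0.04) < 3 * se_pos
    assert abs(p_neg - 0.93) < 3 * se_neg


def test_diagnostic_outcome_limits():
    rng = np.random.default_rng(1)
    all_disease = ScreeningConfig(outcome_mode="diagnostic", disease_prevalence=1.0)
    out = sample_outcomes(all_disease, rng, 50_000)
    assert (out == "positive").mean() == pytest.approx(0.96, abs=0.01)
    no_disease = ScreeningConfig(outcome_mode="diagnostic", disease_prevalence=0.0)
    out = sample_outcomes(no_disease, rng, 50_000)
    assert (out == "positive").mean() == pytest.approx(1 - 0.94, abs=0.01)


def test_single_outcome_in_closed_set():
    assert sample_outcome(ScreeningConfig(), np.random.default_rng(2)) in (
        "positive",
        "negative",
        "inconclusive",
    )


def test_invalid_probability_configuration():
    with pytest.raises(SimulationError, match="sum to 1"):
        ScreeningConfig(p_positive=0.5, p_negative=0.5, p_inconclusive=0.5)
    with pytest.raises(SimulationError):
        ScreeningConfig(interval_weeks=0)


# ---------------------------------------------------------------------------
# state machine
# ---------------------------------------------------------------------------


def test_always_adherent_agent_calls_52_weeks_apart():
    cfg = ScreeningConfig(n_cycles=2)
    res = run_simulation(one_agent_roster(), cfg, DecisionConfig(mode="logistic"),
                         seed=0, logistic_model=ALWAYS)
    calls = res.events[res.events["event"] == "call"]
    attends = res.events[res.events["event"] == "attend"]
    assert list(calls["week"]) == [0, 52]
    assert list(attends["week"]) == [4, 56]  # screening = call + notice_weeks
    agent = res.agents.iloc[0]
    assert agent["times_called"] == 2 and agent["times_attended"] == 2
    assert agent["pct_prior_adherence"] == 100.0
    assert agent["last_result"] in ("positive", "negative", "inconclusive")


def test_never_adherent_agent_history():
    cfg = ScreeningConfig(n_cycles=10)
    res = run_simulation(one_agent_roster(), cfg, DecisionConfig(mode="logistic"),
                         seed=0, logistic_model=NEVER)
    agent = res.agents.iloc[0]
    assert agent["times_called"] == 10
    assert agent["times_attended"] == 0
    assert agent["pct_prior_adherence"] == 0.0
    assert agent["last_result"] == "none"
    assert res.overall_adherence() == 0.0


def test_zero_cycles_produces_no_events(small_roster):
    res = run_simulation(small_roster, ScreeningConfig(n_cycles=0), DecisionConfig(), seed=0)
    assert len(res.events) == 0
    assert len(res.summary) == 0


def test_conservation_per_cycle_and_subregion(small_roster):
    cfg = ScreeningConfig(n_cycles=3)
    res = run_simulation(small_roster, cfg, DecisionConfig(mode="logistic"), seed=5)
    s = res.summary
    assert (s["attended"] + s["not_attended"] == s["calls"]).all()
    # every agent is called exactly once per cycle
    per_cycle = s.groupby("cycle")["calls"].sum()
    assert (per_cycle == len(small_roster)).all()


def test_deterministic_under_seed(small_roster):
    cfg = ScreeningConfig(n_cycles=2)
    a = run_simulation(small_roster, cfg, DecisionConfig(mode="combined"), seed=9)
    b = run_simulation(small_roster, cfg, DecisionConfig(mode="combined"), seed=9)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.agents, b.agents)


def test_invalid_initial_state_rejected(small_roster):
    bad = small_roster.copy()
    bad.loc[0, "state"] = "abducted"
    with pytest.raises(SimulationError, match="impossible state"):
        run_simulation(bad, ScreeningConfig(n_cycles=1), DecisionConfig(), seed=0)


def test_constant_probability_rate_converges():
    # 2,000 homogeneous agents at p = 0.6 over 5 cycles: the cumulative rate
    # sits within 3 binomial SEs of p
    roster = pd.concat([one_agent_roster(id=i) for i in range(2000)], ignore_index=True)
    cfg = ScreeningConfig(n_cycles=5)
    res = run_simulation(roster, cfg, DecisionConfig(mode="logistic"),
                         seed=17, logistic_model=CONSTANT_P(0.6))
    n = 2000 * 5
    se = math.sqrt(0.6 * 0.4 / n)
    assert abs(res.overall_adherence() / 100.0 - 0.6) < 3 * se


def test_cumulative_trajectory_stabilizes():
    # per-cycle change of the cumulative rate shrinks roughly like 1/cycles
    roster = pd.concat([one_agent_roster(id=i) for i in range(1000)], ignore_index=True)
    cfg = ScreeningConfig(n_cycles=8)
    res = run_simulation(roster, cfg, DecisionConfig(mode="logistic"),
                         seed=3, logistic_model=CONSTANT_P(0.7))
    s = res.summary.groupby("cycle")[["attended", "not_attended"]].sum()
    cum = (s["attended"].cumsum() / (s["attended"] + s["not_attended"]).cumsum()).to_numpy()
    deltas = np.abs(np.diff(cum))
    assert deltas[-1] < 0.01
    assert np.mean(deltas[4:]) < np.mean(deltas[:3]) + 0.005


# ---------------------------------------------------------------------------
# replicates
# ---------------------------------------------------------------------------


def test_replicates_distinct_and_reproducible(small_roster):
    cfg = ScreeningConfig(n_cycles=1)
    runs = run_replicates(small_roster, cfg, DecisionConfig(), n_replicates=5, base_seed=1)
    assert len(runs) == 5
    assert len({r.seed for r in runs}) == 5
    runs2 = run_replicates(small_roster, cfg, DecisionConfig(), n_replicates=5, base_seed=1)
    for a, b in zip(runs, runs2):
        assert a.seed == b.seed
        pd.testing.assert_frame_equal(a.events, b.events)


def test_single_replicate_equals_plain_run(small_roster):
    cfg = ScreeningConfig(n_cycles=1)
    (rep,) = run_replicates(small_roster, cfg, DecisionConfig(), n_replicates=1, base_seed=4)
    direct = run_simulation(small_roster, cfg, DecisionConfig(), seed=rep.seed)
    pd.testing.assert_frame_equal(rep.events, direct.events)
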