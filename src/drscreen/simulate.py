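"""Discrete-time (weekly) agent-based screening engine.

Each agent cycles through four states: *not called* → *called* (invitation
issued) → *attended* / *did not attend* (resolved on the screening date,
``notice_weeks`` after the call) → back to *not called* until the next
invitation, issued ``interval_weeks`` after the previous one so that
consecutive calls are exactly one screening interval apart.  A run of
``n_cycles`` cycles therefore spans ``n_cycles × interval_weeks`` weeks
(10 × 52 = 520 by default).

On the screening date the decision engine produces the agent's probability
of attending (logistic, fuzzy or combined; optionally modified by active
intervention scenarios), the decision is drawn, the screening outcome is
sampled for attenders, and the agent's history (times called, times
attended, % prior adherence, last result) is updated.

To keep paired-seed scenario comparisons aligned, the engine draws the same
number of random variates per decision batch regardless of who attends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .decision import (
    DEFAULT_LOGISTIC_MODEL,
    DecisionConfig,
    LogisticModel,
    combined_probability,
    logistic_probabilities,
)
from .fuzzy import FuzzyComponent, build_default_components, component_scores

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningConfig",
    "RunResult",
    "World",
    "DecisionEngine",
    "sample_outcome",
    "sample_outcomes",
    "step_week",
    "run_simulation",
    "run_replicates",
]

OUTCOMES = ("positive", "negative", "inconclusive")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening-programme strategy parameters.

    Defaults reproduce the published programme description: 52-week
    interval, test sensitivity 96% and specificity 94%, marginal outcome
    probabilities 4% positive / 93% negative / 3% inconclusive, calls sent
    4 weeks ahead, 10-minute waiting time, reminders still incipient (low
    score), screening in primary-care units (low location difficulty),
    ten cycles, five replicates.
    """

    interval_weeks: int = 52
    sensitivity: float = 0.96
    specificity: float = 0.94
    outcome_mode: str = "marginal"  # or "diagnostic"
    p_positive: float = 0.04
    p_negative: float = 0.93
    p_inconclusive: float = 0.03
    disease_prevalence: float = 0.05
    reminder_score: float = 10.0
    waiting_time_minutes: float = 10.0
    notice_weeks: int = 4
    location_score: float = 20.0
    n_cycles: int = 10
    n_replicates: int = 5
    stagger_first_call: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_positive, self.p_negative, self.p_inconclusive)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise SimulationError(
                f"marginal outcome probabilities must be >= 0 and sum to 1, got {probs}"
            )
        for name in ("sensitivity", "specificity", "disease_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.interval_weeks < 1:
            raise SimulationError("interval_weeks must be >= 1")
        if self.outcome_mode not in ("marginal", "diagnostic"):
            raise SimulationError(f"unknown outcome_mode {self.outcome_mode!r}")
        if not 0 <= self.notice_weeks < self.interval_weeks:
            raise SimulationError("notice_weeks must be in [0, interval_weeks)")
        if self.n_cycles < 0 or self.n_replicates < 1:
            raise SimulationError("n_cycles must be >= 0 and n_replicates >= 1")


def sample_outcomes(
    config: ScreeningConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw ``size`` screening outcomes.

    Marginal mode draws directly from the (positive, negative, inconclusive)
    probabilities.  Diagnostic mode draws a latent disease state from the
    prevalence and declares a positive with probability ``sensitivity``
    (diseased) or ``1 − specificity`` (healthy); the non-positive mass is
    split between negative and inconclusive in their marginal proportions,
    so P(positive | diseased) equals the sensitivity exactly.
    """
    if config.outcome_mode == "marginal":
        return rng.choice(
            OUTCOMES, size=size, p=(config.p_positive, config.p_negative, config.p_inconclusive)
        )
    diseased = rng.uniform(size=size) < config.disease_prevalence
    p_pos = np.where(diseased, config.sensitivity, 1.0 - config.specificity)
    positive = rng.uniform(size=size) < p_pos
    denom = config.p_negative + config.p_inconclusive
    p_inc = config.p_inconclusive / denom if denom > 0 else 0.0
    inconclusive = rng.uniform(size=size) < p_inc
    out = np.where(positive, "positive", np.where(inconclusive, "inconclusive", "negative"))
    return out


def sample_outcome(config: ScreeningConfig, rng: np.random.Generator) -> str:
    """One screening-test outcome for an attending agent."""
    return str(sample_outcomes(config, rng, 1)[0])


# ---------------------------------------------------------------------------
# Decision engine over a roster
# ---------------------------------------------------------------------------


class DecisionEngine:
    """Vectorized decision probabilities for batches of deciding agents.

    Static fuzzy inputs (access barriers per agent, programme quality for
    the whole run) are precomputed; only the knowledge component, which
    depends on the evolving prior-adherence percentage, is re-evaluated at
    decision time.
    """

    def __init__(
        self,
        decision_config: DecisionConfig,
        screening_config: ScreeningConfig,
        roster: pd.DataFrame,
        logistic_model: Optional[LogisticModel] = None,
        components: Optional[Mapping[str, FuzzyComponent]] = None,
    ) -> None:
        self.config = decision_config
        self.model = logistic_model or DEFAULT_LOGISTIC_MODEL
        self.components = dict(components) if components is not None else build_default_components()
        self._needs_fuzzy = decision_config.mode in ("fuzzy", "combined")
        if self._needs_fuzzy:
            barriers = self.components["access_barriers"]
            self._barrier_scores = np.asarray(
                component_scores(
                    barriers,
                    {
                        "age_barrier": roster["age"].to_numpy(),
                        "income": np.clip(roster["income"].to_numpy(), 0.0, 100000.0),
                        "location": np.full(len(roster), screening_config.location_score),
                        "urbanization": roster["urbanization"].to_numpy(),
                    },
                )
            )
            quality = self.components["program_quality"]
            self._quality_score = float(
                np.asarray(
                    component_scores(
                        quality,
                        {
                            "reminders": screening_config.reminder_score,
                            "waiting_time": screening_config.waiting_time_minutes,
                            "notice": float(screening_config.notice_weeks),
                        },
                    )
                ).reshape(-1)[0]
            )
            self._age = roster["age"].to_numpy(dtype=float)
            self._education = roster["education_score"].to_numpy(dtype=float)

    def probabilities(
        self,
        idx: np.ndarray,
        pct_prior: np.ndarray,
        times_called: np.ndarray,
        last_result: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Decision probability for the agents at positional indices ``idx``.

        History features reflect the current call (``times_called`` already
        counts it; ``pct_prior`` does not).
        """
        cfg = self.config
        p_log = p_fuzzy = np.zeros(len(idx))
        if cfg.mode in ("logistic", "combined"):
            p_log = logistic_probabilities(self.model, pct_prior, times_called, last_result)
        if self._needs_fuzzy:
            knowledge = self.components["disease_knowledge"]
            k_scores = np.asarray(
                component_scores(
                    knowledge,
                    {
                        "age_knowledge": self._age[idx],
                        "education": self._education[idx],
                        "prior_adherence": np.asarray(pct_prior, dtype=float),
                    },
                )
            )
            score = (self._barrier_scores[idx] + k_scores + self._quality_score) / 3.0
            p_fuzzy = score / 100.0
            # noise drawn for every decider to keep paired streams aligned
            noise = rng.uniform(-cfg.variability / 2.0, cfg.variability / 2.0, size=len(idx))
            if cfg.variability > 0:
                p_fuzzy = np.clip(p_fuzzy + noise, 0.0, 1.0)
        return np.asarray(combined_probability(cfg, p_log, p_fuzzy), dtype=float)


# ---------------------------------------------------------------------------
# World state and weekly stepping
# ---------------------------------------------------------------------------


@dataclass
class World:
    """Mutable simulation state: the roster plus pending-screening bookkeeping."""

    roster: pd.DataFrame
    screening: ScreeningConfig
    engine: DecisionEngine
    scenarios: Sequence = ()
    week: int = 0
    screening_week: np.ndarray = field(init=False)
    events: List[dict] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        self.roster = self.roster.reset_index(drop=True).copy()
        n = len(self.roster)
        self.screening_week = np.full(n, -1, dtype=int)
        self._state = self.roster["state"].to_numpy(dtype=object)
        self._next_call = self.roster["next_call_week"].to_numpy(dtype=int).copy()
        self._tc = self.roster["times_called"].to_numpy(dtype=int).copy()
        self._ta = self.roster["times_attended"].to_numpy(dtype=int).copy()
        self._pct = self.roster["pct_prior_adherence"].to_numpy(dtype=float).copy()
        self._last = self.roster["last_result"].to_numpy(dtype=object).copy()
        self._sub = self.roster["subregion"].to_numpy(dtype=object)
        self._ids = self.roster["id"].to_numpy(dtype=int)
        bad = ~np.isin(self._state, ("not_called", "called", "attended", "not_attended"))
        if bad.any():
            raise SimulationError(f"agents in impossible state: {set(self._state[bad])}")

    def finalize(self) -> pd.DataFrame:
        out = self.roster.copy()
        out["state"] = self._state
        out["next_call_week"] = self._next_call
        out["times_called"] = self._tc
        out["times_attended"] = self._ta
        out["pct_prior_adherence"] = self._pct
        out["last_result"] = self._last
        return out


def step_week(world: World, week: int, rng: np.random.Generator) -> World:
    """Advance the world by one week (calls, decisions, history updates)."""
    state = world._state
    cfg = world.screening

    # resolved agents re-enter the pool once their screening week has passed
    resolved = np.isin(state, ("attended", "not_attended")) & (world.screening_week < week)
    state[resolved] = "not_called"

    # issue invitations
    due_call = (state == "not_called") & (world._next_call == week)
    if due_call.any():
        state[due_call] = "called"
        world.screening_week[due_call] = week + cfg.notice_weeks
        world._next_call[due_call] = week + cfg.interval_weeks
        for i in np.nonzero(due_call)[0]:
            world.events.append(
                {
                    "week": week,
                    "agent_id": int(world._ids[i]),
                    "subregion": world._sub[i],
                    "event": "call",
                    "outcome": "",
                    "prior_last_result": world._last[i],
                    "p": np.nan,
                }
            )

    # resolve decisions on the screening date
    due = (state == "called") & (world.screening_week == week)
    if due.any():
        idx = np.nonzero(due)[0]
        # the current call enters the denominator only after the decision
        tc_at_decision = world._tc[idx] + 1
        pct_prior = world._pct[idx]
        last = world._last[idx]
        p = world.engine.probabilities(idx, pct_prior, tc_at_decision, last, rng)
        if world.scenarios:
            # selectors see the agent's history as it stands at decision time
            view = world.roster.iloc[idx].copy()
            view["times_called"] = tc_at_decision
            view["times_attended"] = world._ta[idx]
            view["pct_prior_adherence"] = pct_prior
            view["last_result"] = last
            for scenario in world.scenarios:
                p = scenario.apply(view, p)
        u = rng.uniform(size=len(idx))
        if world.engine.config.decision_policy == "threshold":
            adhere = p > world.engine.config.threshold
        else:
            adhere = u < p
        # outcomes drawn for every decider so paired-seed streams stay aligned
        outcomes = sample_outcomes(cfg, rng, len(idx))

        world._tc[idx] = tc_at_decision
        att_idx = idx[adhere]
        world._ta[att_idx] += 1
        world._last[att_idx] = outcomes[adhere]
        world._pct[idx] = 100.0 * world._ta[idx] / world._tc[idx]
        state[att_idx] = "attended"
        state[idx[~adhere]] = "not_attended"
        for k, i in enumerate(idx):
            attended = bool(adhere[k])
            world.events.append(
                {
                    "week": week,
                    "agent_id": int(world._ids[i]),
                    "subregion": world._sub[i],
                    "event": "attend" if attended else "miss",
                    "outcome": outcomes[k] if attended else "",
                    "prior_last_result": last[k],
                    "p": float(p[k]),
                }
            )
    world.week = week + 1
    return world


@dataclass
class RunResult:
    """Event log, final roster and per-subregion/cycle summary of one run."""

    events: pd.DataFrame
    agents: pd.DataFrame
    summary: pd.DataFrame
    n_weeks: int
    seed: int
    replicate: int = 0

    def adherence_rates(self) -> pd.Series:
        """Cumulative adherence % per subregion (attended / called)."""
        dec = self.events[self.events["event"].isin(("attend", "miss"))]
        if len(dec) == 0:
            return pd.Series(dtype=float)
        grp = dec.groupby("subregion")["event"]
        return 100.0 * grp.apply(lambda s: (s == "attend").mean())

    def overall_adherence(self) -> float:
        dec = self.events[self.events["event"].isin(("attend", "miss"))]
        if len(dec) == 0:
            return float("nan")
        return float(100.0 * (dec["event"] == "attend").mean())


EVENT_COLUMNS = ["week", "agent_id", "subregion", "event", "outcome", "prior_last_result", "p"]


def _summarize(events: pd.DataFrame, interval_weeks: int) -> pd.DataFrame:
    if len(events) == 0:
        return pd.DataFrame(
            columns=["subregion", "cycle", "calls", "attended", "not_attended", "cumulative_rate_pct"]
        )
    ev = events.copy()
    ev["cycle"] = ev["week"] // interval_weeks
    rows = []
    for (sub, cyc), g in ev.groupby(["subregion", "cycle"], sort=True):
        rows.append(
            {
                "subregion": sub,
                "cycle": int(cyc),
                "calls": int((g["event"] == "call").sum()),
                "attended": int((g["event"] == "attend").sum()),
                "not_attended": int((g["event"] == "miss").sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values(["subregion", "cycle"]).reset_index(drop=True)
    cum_att = out.groupby("subregion")["attended"].cumsum()
    cum_dec = out.groupby("subregion")[["attended", "not_attended"]].cumsum().sum(axis=1)
    out["cumulative_rate_pct"] = 100.0 * cum_att / cum_dec.replace(0, np.nan)
    return out


def run_simulation(
    roster: pd.DataFrame,
    screening_config: ScreeningConfig,
    decision_config: DecisionConfig,
    scenarios: Sequence = (),
    seed: int = 0,
    logistic_model: Optional[LogisticModel] = None,
    components: Optional[Mapping[str, FuzzyComponent]] = None,
    replicate: int = 0,
) -> RunResult:
    """Run ``n_cycles × interval_weeks`` weekly steps; deterministic per seed."""
    rng = np.random.default_rng(seed)
    engine = DecisionEngine(decision_config, screening_config, roster, logistic_model, components)
    world = World(roster=roster, screening=screening_config, engine=engine, scenarios=scenarios)
    if screening_config.stagger_first_call:
        world._next_call[:] = rng.integers(0, screening_config.interval_weeks, size=len(world._next_call))
    n_weeks = screening_config.n_cycles * screening_config.interval_weeks
    for week in range(n_weeks):
        step_week(world, week, rng)
    events = pd.DataFrame(world.events, columns=EVENT_COLUMNS)
    summary = _summarize(events, screening_config.interval_weeks)
    return RunResult(
        events=events,
        agents=world.finalize(),
        summary=summary,
        n_weeks=n_weeks,
        seed=seed,
        replicate=replicate,
    )


def run_replicates(
    roster: pd.DataFrame,
    screening_config: ScreeningConfig,
    decision_config: DecisionConfig,
    scenarios: Sequence = (),
    n_replicates: Optional[int] = None,
    base_seed: int = 0,
    logistic_model: Optional[LogisticModel] = None,
    components: Optional[Mapping[str, FuzzyComponent]] = None,
) -> List[RunResult]:
    """Independent replicate runs with seeds spawned from ``base_seed``."""
    n = n_replicates if n_replicates is not None else screening_config.n_replicates
    if n < 1:
        raise SimulationError("n_replicates must be >= 1")
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(base_seed).spawn(n)]
    return [
        run_simulation(
            roster,
            screening_config,
            decision_config,
            scenarios=scenarios,
            seed=seeds[i],
            logistic_model=logistic_model,
            components=components,
            replicate=i,
        )
        for i in range(n)
    ]
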