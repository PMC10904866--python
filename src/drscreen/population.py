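"""Synthetic population of diabetics structured like a regional registry.

The generator emulates the structure — not the confidential content — of a
northern-Portugal diabetic-screening registry: eight subregions with
configurable shares, per-subregion demographic and socioeconomic marginals,
two demographic clusters (cluster 1 younger and mostly active, cluster 2
older and mostly retired) and per-agent screening histories.

The roster is a pandas DataFrame (one row per agent, schema in
:data:`ROSTER_COLUMNS`); :class:`Agent` gives the single-agent view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SUBREGIONS",
    "TRAIN_SUBREGIONS",
    "TEST_SUBREGIONS",
    "Agent",
    "SubregionProfile",
    "ClusterProfile",
    "HistorySpec",
    "PopulationSpec",
    "generate_population",
    "split_train_test",
    "read_population",
    "write_population",
    "roster_to_agents",
    "SchemaError",
]

#: The eight subregions of the screening programme.
SUBREGIONS = (
    "Alto Minho",
    "Ave",
    "Cávado",
    "Douro",
    "Entre Douro e Vouga",
    "Metropolitan Area of Porto",
    "Tâmega e Sousa",
    "Trás-os-Montes",
)

#: The published training/testing geography split (5 vs 3 subregions).
TRAIN_SUBREGIONS = frozenset(
    {"Tâmega e Sousa", "Cávado", "Douro", "Trás-os-Montes", "Metropolitan Area of Porto"}
)
TEST_SUBREGIONS = frozenset({"Alto Minho", "Ave", "Entre Douro e Vouga"})

OCCUPATIONS = ("active", "retired", "student", "other")
LAST_RESULTS = ("none", "negative", "positive", "inconclusive")
STATES = ("not_called", "called", "attended", "not_attended")

ROSTER_COLUMNS = [
    "id",
    "subregion",
    "age",
    "gender",
    "income",
    "education_score",
    "urbanization",
    "occupation",
    "student_flag",
    "cluster",
    "times_called",
    "times_attended",
    "pct_prior_adherence",
    "last_result",
    "state",
    "next_call_week",
]


class SchemaError(ValueError):
    """Raised when a roster file does not match the documented schema."""


@dataclass
class Agent:
    """One diabetic: demographics, history and current simulation state."""

    id: int
    subregion: str
    age: float
    gender: str
    income: float
    education_score: float
    urbanization: float
    occupation: str
    student_flag: bool
    cluster: int
    times_called: int = 0
    times_attended: int = 0
    pct_prior_adherence: float = 0.0
    last_result: str = "none"
    state: str = "not_called"
    next_call_week: int = 0

    def __post_init__(self) -> None:
        if self.times_attended > self.times_called:
            raise ValueError("times_attended cannot exceed times_called")


@dataclass(frozen=True)
class SubregionProfile:
    """Share and attribute marginals for one subregion (synthetic defaults)."""

    share: float
    income_median: float  # EUR/year, lognormal median
    income_sigma: float = 0.45
    education_mean: float = 40.0  # on the 0-100 qualification score
    urbanization_mean: float = 0.5


@dataclass(frozen=True)
class ClusterProfile:
    """Age and occupation mix for one demographic cluster."""

    share: float
    age_mean: float
    age_sd: float
    occupation_probs: Tuple[float, float, float, float]  # active/retired/student/other


@dataclass(frozen=True)
class HistorySpec:
    """Initial screening histories at week 0."""

    never_called_fraction: float = 0.30
    times_called_poisson_mean: float = 2.0  # times_called ~ 1 + Poisson(mean)
    adherence_per_call: float = 0.66
    result_probs: Tuple[float, float, float] = (0.04, 0.93, 0.03)  # pos/neg/inconclusive


def _default_subregions() -> Dict[str, SubregionProfile]:
    # Shares put 66.5% of agents in the five training subregions, matching
    # the published 66.41/33.59 population split; attribute levels are
    # synthetic but ordered like the real coastal/interior gradient.
    return {
        "Alto Minho": SubregionProfile(0.075, 9200.0, education_mean=38.0, urbanization_mean=0.45),
        "Ave": SubregionProfile(0.125, 9800.0, education_mean=40.0, urbanization_mean=0.65),
        "Cávado": SubregionProfile(0.100, 10200.0, education_mean=44.0, urbanization_mean=0.70),
        "Douro": SubregionProfile(0.060, 8600.0, education_mean=34.0, urbanization_mean=0.25),
        "Entre Douro e Vouga": SubregionProfile(0.135, 10000.0, education_mean=41.0, urbanization_mean=0.65),
        "Metropolitan Area of Porto": SubregionProfile(0.330, 11000.0, education_mean=48.0, urbanization_mean=0.90),
        "Tâmega e Sousa": SubregionProfile(0.130, 9000.0, education_mean=35.0, urbanization_mean=0.50),
        "Trás-os-Montes": SubregionProfile(0.045, 8400.0, education_mean=33.0, urbanization_mean=0.20),
    }


def _default_clusters() -> Dict[int, ClusterProfile]:
    return {
        1: ClusterProfile(0.509, age_mean=48.0, age_sd=12.0, occupation_probs=(0.75, 0.08, 0.05, 0.12)),
        2: ClusterProfile(0.491, age_mean=71.0, age_sd=9.0, occupation_probs=(0.10, 0.82, 0.0, 0.08)),
    }


@dataclass(frozen=True)
class PopulationSpec:
    """Everything needed to draw a reproducible synthetic roster."""

    total_size: int = 10_000
    subregions: Mapping[str, SubregionProfile] = field(default_factory=_default_subregions)
    clusters: Mapping[int, ClusterProfile] = field(default_factory=_default_clusters)
    history: HistorySpec = field(default_factory=HistorySpec)
    age_bounds: Tuple[float, float] = (18.0, 100.0)
    male_fraction: float = 0.52
    urbanization_concentration: float = 25.0  # beta concentration around the mean
    education_concentration: float = 8.0

    def __post_init__(self) -> None:
        if self.total_size <= 0:
            raise ValueError("total_size must be positive")
        share_sum = sum(p.share for p in self.subregions.values())
        if abs(share_sum - 1.0) > 1e-9:
            raise ValueError(f"subregion shares must sum to 1, got {share_sum}")
        cshare = sum(p.share for p in self.clusters.values())
        if abs(cshare - 1.0) > 1e-9:
            raise ValueError(f"cluster shares must sum to 1, got {cshare}")
        h = self.history
        if not 0.0 <= h.never_called_fraction <= 1.0:
            raise ValueError("never_called_fraction must be in [0, 1]")
        if abs(sum(h.result_probs) - 1.0) > 1e-9:
            raise ValueError("history result_probs must sum to 1")


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    # rejection sampling is plenty fast at these sizes and keeps the shape
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _beta_around(rng, mean, concentration, size):
    mean = float(np.clip(mean, 1e-3, 1 - 1e-3))
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


def generate_population(spec: PopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``spec.total_size`` agents; reproducible under a fixed generator.

    Subregion and cluster labels are multinomial around the configured
    shares; ages come from cluster-conditional truncated normals (students
    are re-aged to 18–24), incomes from subregion log-normals parameterized
    by their median, education and urbanization from subregion beta laws.
    Initial histories follow :class:`HistorySpec`.
    """
    n = spec.total_size
    sub_names = list(spec.subregions)
    sub_probs = np.array([spec.subregions[s].share for s in sub_names])
    subregion = rng.choice(sub_names, size=n, p=sub_probs)

    cluster_ids = np.array(sorted(spec.clusters))
    cluster_probs = np.array([spec.clusters[c].share for c in cluster_ids])
    cluster = rng.choice(cluster_ids, size=n, p=cluster_probs)

    lo, hi = spec.age_bounds
    age = np.empty(n)
    occupation = np.empty(n, dtype=object)
    for cid in cluster_ids:
        mask = cluster == cid
        prof = spec.clusters[cid]
        age[mask] = _truncated_normal(rng, prof.age_mean, prof.age_sd, lo, hi, int(mask.sum()))
        occupation[mask] = rng.choice(OCCUPATIONS, size=int(mask.sum()), p=prof.occupation_probs)
    student = occupation == "student"
    if student.any():
        age[student] = rng.uniform(18.0, 25.0, size=int(student.sum()))

    gender = np.where(rng.uniform(size=n) < spec.male_fraction, "male", "female")

    income = np.empty(n)
    education = np.empty(n)
    urbanization = np.empty(n)
    for name in sub_names:
        mask = subregion == name
        prof = spec.subregions[name]
        m = int(mask.sum())
        income[mask] = rng.lognormal(np.log(prof.income_median), prof.income_sigma, size=m)
        education[mask] = 100.0 * _beta_around(
            rng, prof.education_mean / 100.0, spec.education_concentration, m
        )
        urbanization[mask] = _beta_around(
            rng, prof.urbanization_mean, spec.urbanization_concentration, m
        )

    h = spec.history
    called_before = rng.uniform(size=n) >= h.never_called_fraction
    times_called = np.where(called_before, 1 + rng.poisson(h.times_called_poisson_mean, size=n), 0)
    times_attended = rng.binomial(times_called, h.adherence_per_call)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(times_called > 0, 100.0 * times_attended / np.maximum(times_called, 1), 0.0)
    results = rng.choice(("positive", "negative", "inconclusive"), size=n, p=h.result_probs)
    last_result = np.where(times_attended > 0, results, "none")

    roster = pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "subregion": subregion,
            "age": age,
            "gender": gender,
            "income": income,
            "education_score": education,
            "urbanization": urbanization,
            "occupation": occupation.astype(str),
            "student_flag": student,
            "cluster": cluster.astype(int),
            "times_called": times_called.astype(int),
            "times_attended": times_attended.astype(int),
            "pct_prior_adherence": pct,
            "last_result": last_result.astype(str),
            "state": "not_called",
            "next_call_week": 0,
        }
    )
    return roster[ROSTER_COLUMNS]


def split_train_test(
    roster: pd.DataFrame,
    train_subregions: Iterable[str] = TRAIN_SUBREGIONS,
    test_subregions: Iterable[str] = TEST_SUBREGIONS,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the roster by subregion into training and testing sets."""
    train_set, test_set = set(train_subregions), set(test_subregions)
    overlap = train_set & test_set
    if overlap:
        raise ValueError(f"train/test subregion sets overlap: {sorted(overlap)}")
    present = set(roster["subregion"].unique())
    uncovered = present - train_set - test_set
    if uncovered:
        raise ValueError(f"subregions assigned to neither split: {sorted(uncovered)}")
    train_mask = roster["subregion"].isin(train_set)
    return roster[train_mask].reset_index(drop=True), roster[~train_mask].reset_index(drop=True)


_DTYPES = {
    "id": int,
    "age": float,
    "income": float,
    "education_score": float,
    "urbanization": float,
    "student_flag": bool,
    "cluster": int,
    "times_called": int,
    "times_attended": int,
    "pct_prior_adherence": float,
    "next_call_week": int,
}


def write_population(roster: pd.DataFrame, path) -> None:
    """Write the agent roster as CSV with the documented column schema."""
    _check_schema(roster.columns)
    roster[ROSTER_COLUMNS].to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    """Read a roster CSV; ``read ∘ write`` is the identity on rosters."""
    roster = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_schema(roster.columns)
    if len(roster) == 0:
        return roster.astype({k: v for k, v in _DTYPES.items()})[ROSTER_COLUMNS]
    for col, typ in _DTYPES.items():
        if typ is bool:
            roster[col] = roster[col].map({"True": True, "False": False})
        else:
            roster[col] = roster[col].astype(float).astype(typ) if typ is int else roster[col].astype(typ)
    return roster[ROSTER_COLUMNS]


def _check_schema(columns) -> None:
    missing = [c for c in ROSTER_COLUMNS if c not in columns]
    extra = [c for c in columns if c not in ROSTER_COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns: {missing}")
        if extra:
            parts.append(f"unexpected columns: {extra}")
        raise SchemaError("; ".join(parts))


def roster_to_agents(roster: pd.DataFrame) -> List[Agent]:
    """Materialize the DataFrame roster as :class:`Agent` objects."""
    return [Agent(**row) for row in roster.to_dict("records")]
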