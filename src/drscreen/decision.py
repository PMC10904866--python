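"""The individual adherence decision and its logistic calibration.

Three interchangeable engines produce an agent's probability of attending a
screening appointment:

* ``logistic`` — a logistic regression on the agent's screening history
  (percentage of prior calls adhered to, last screening result, number of
  times called);
* ``fuzzy`` — the mean of the three Mamdani component scores (see
  :mod:`drscreen.fuzzy`), mapped to [0, 1], plus a small uniform noise whose
  magnitude is the ``variability`` parameter;
* ``combined`` — a weighted average of the two probabilities (default 50/50).

The module also provides a synthetic call-record generator (one row per call,
21 candidate covariates, outcome driven only by the three history predictors)
and a forward-stepwise logistic selection procedure used to calibrate the
logistic engine from such records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from sklearn.metrics import roc_auc_score

from .fuzzy import FuzzyComponent, component_scores

logger = logging.getLogger(__name__)

__all__ = [
    "LAST_RESULTS",
    "LogisticModel",
    "DecisionConfig",
    "DEFAULT_LOGISTIC_MODEL",
    "logistic_probability",
    "fuzzy_probability",
    "decide",
    "CANDIDATE_COVARIATES",
    "generate_call_records",
    "StepwiseResult",
    "fit_stepwise_logistic",
]

#: Categories of an agent's last screening result; "none" = never screened
#: and is the reference level of the indicator coding.
LAST_RESULTS = ("none", "negative", "positive", "inconclusive")


class DecisionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Logistic engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticModel:
    """Logistic regression on the linear predictor scale.

    ``coefficients`` maps feature names to slopes.  The shipped default uses
    the three history predictors, with the categorical last result expanded
    into indicators against the "none" reference level
    (``last_result_negative`` etc.).
    """

    intercept: float
    coefficients: Mapping[str, float]

    def linear_predictor(self, features: Mapping[str, float]) -> float:
        z = self.intercept
        for name, coef in self.coefficients.items():
            if name not in features:
                raise DecisionError(f"missing feature {name!r} for logistic model")
            z += coef * features[name]
        return z

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients)}

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(intercept=float(d["intercept"]), coefficients=dict(d["coefficients"]))


def encode_last_result(last_result) -> Dict[str, float]:
    """Indicator coding of the last screening result ("none" = reference)."""
    if last_result not in LAST_RESULTS:
        raise DecisionError(f"unknown last_result {last_result!r}")
    return {f"last_result_{cat}": float(last_result == cat) for cat in LAST_RESULTS[1:]}


#: Default engine coefficients: these are also the generating coefficients of
#: the synthetic call-record generator, so a stepwise refit on its output
#: recovers them.  Signs follow the observed behaviour of the screened
#: population: more prior adherence and more previous calls raise the odds of
#: attending, a previous positive result lowers them.
DEFAULT_LOGISTIC_MODEL = LogisticModel(
    intercept=-0.7,
    coefficients={
        "pct_prior_adherence": 0.012,
        "times_called": 0.06,
        "last_result_negative": 0.15,
        "last_result_positive": -0.40,
        "last_result_inconclusive": -0.10,
    },
)


def logistic_probability(model: LogisticModel, agent_features: Mapping[str, float]) -> float:
    """p = sigmoid(intercept + Σ coefficient · feature), strictly in (0, 1)."""
    return float(expit(model.linear_predictor(agent_features)))


def logistic_probabilities(
    model: LogisticModel,
    pct_prior_adherence: np.ndarray,
    times_called: np.ndarray,
    last_result: np.ndarray,
) -> np.ndarray:
    """Vectorized logistic probabilities for a batch of agents."""
    coefs = model.coefficients
    z = np.full(np.shape(pct_prior_adherence), model.intercept, dtype=float)
    z += coefs.get("pct_prior_adherence", 0.0) * np.asarray(pct_prior_adherence, dtype=float)
    z += coefs.get("times_called", 0.0) * np.asarray(times_called, dtype=float)
    last_result = np.asarray(last_result)
    for cat in LAST_RESULTS[1:]:
        c = coefs.get(f"last_result_{cat}", 0.0)
        if c:
            z += c * (last_result == cat)
    return expit(z)


# ---------------------------------------------------------------------------
# Fuzzy engine
# ---------------------------------------------------------------------------


def fuzzy_scores(
    components: Mapping[str, FuzzyComponent], inputs: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Mean of the three component COG scores (0–100), vectorized."""
    scores = [component_scores(c, inputs) for c in components.values()]
    return np.mean(np.broadcast_arrays(*scores), axis=0)


def fuzzy_probability(
    components: Mapping[str, FuzzyComponent],
    agent_and_program_inputs: Mapping[str, float],
    variability: float,
    rng: np.random.Generator,
) -> float:
    """Average the three component scores, rescale to [0, 1], add noise.

    Noise is Uniform(−variability/2, +variability/2); the result is clipped
    to [0, 1].  With ``variability == 0`` the map is deterministic.
    """
    score = float(np.asarray(fuzzy_scores(components, agent_and_program_inputs)).reshape(-1).mean())
    p = score / 100.0
    if variability > 0:
        p += rng.uniform(-variability / 2.0, variability / 2.0)
    return float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Decision
# ---------------------------------------------------------------------------

MODES = ("logistic", "fuzzy", "combined")
POLICIES = ("bernoulli", "threshold")


@dataclass(frozen=True)
class DecisionConfig:
    """Engine mode, combination weights, noise magnitude and draw policy."""

    mode: str = "logistic"
    weight_logistic: float = 0.5
    weight_fuzzy: float = 0.5
    variability: float = 0.1
    decision_policy: str = "bernoulli"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DecisionError(f"unknown decision mode {self.mode!r}")
        if self.decision_policy not in POLICIES:
            raise DecisionError(f"unknown decision policy {self.decision_policy!r}")
        if self.weight_logistic < 0 or self.weight_fuzzy < 0:
            raise DecisionError("combination weights must be non-negative")
        if abs(self.weight_logistic + self.weight_fuzzy - 1.0) > 1e-9:
            raise DecisionError(
                f"weights must sum to 1, got {self.weight_logistic + self.weight_fuzzy}"
            )
        if self.variability < 0:
            raise DecisionError("variability must be >= 0")


def combined_probability(config: DecisionConfig, p_logistic, p_fuzzy):
    if config.mode == "logistic":
        return p_logistic
    if config.mode == "fuzzy":
        return p_fuzzy
    return config.weight_logistic * np.asarray(p_logistic) + config.weight_fuzzy * np.asarray(p_fuzzy)


def decide(
    config: DecisionConfig,
    p_logistic: float,
    p_fuzzy: float,
    rng: np.random.Generator,
) -> bool:
    """Resolve one adherence decision from the mode-appropriate probability."""
    p = float(combined_probability(config, p_logistic, p_fuzzy))
    if not 0.0 <= p <= 1.0:
        raise DecisionError(f"decision probability {p} outside [0, 1]")
    if config.decision_policy == "threshold":
        return p > config.threshold
    return bool(rng.uniform() < p)


# ---------------------------------------------------------------------------
# Synthetic call records and stepwise calibration
# ---------------------------------------------------------------------------

#: The 21 candidate covariates considered for the adherence model.  Each
#: entry maps a candidate name to the design columns it contributes
#: (categoricals enter/leave selection as one block).
CANDIDATE_COVARIATES: Dict[str, Tuple[str, ...]] = {
    "pct_prior_adherence": ("pct_prior_adherence",),
    "last_result": ("last_result_negative", "last_result_positive", "last_result_inconclusive"),
    "times_called": ("times_called",),
    "age": ("age",),
    "gender_male": ("gender_male",),
    "income": ("income",),
    "education_score": ("education_score",),
    "urbanization": ("urbanization",),
    "occupation": ("occupation_retired", "occupation_student", "occupation_other"),
    "has_phone_contact": ("has_phone_contact",),
    "has_family_doctor": ("has_family_doctor",),
    "primary_care_visits_12m": ("primary_care_visits_12m",),
    "diabetes_type2": ("diabetes_type2",),
    "bmi": ("bmi",),
    "hba1c": ("hba1c",),
    "call_month": ("call_month",),
    "days_between_calls": ("days_between_calls",),
    "payment_exemption": ("payment_exemption",),
    "health_unit_type": ("health_unit_type_family",),
    "aces_list_size": ("aces_list_size",),
    "distance_to_unit_km": ("distance_to_unit_km",),
}

OCCUPATIONS = ("active", "retired", "student", "other")


def generate_call_records(
    n: int,
    rng: np.random.Generator,
    model: LogisticModel = DEFAULT_LOGISTIC_MODEL,
    null_effects: bool = False,
) -> pd.DataFrame:
    """One synthetic row per screening call, with the dichotomous outcome.

    Covariates are drawn independently with plausible marginals; the outcome
    is Bernoulli(sigmoid(z)) where z involves only the three history
    predictors (``model``).  With ``null_effects`` the outcome is
    Bernoulli(0.66) independent of everything.
    """
    tc = 1 + rng.poisson(4.0, size=n)
    pct = 100.0 * rng.beta(2.0, 1.0, size=n)
    last = rng.choice(LAST_RESULTS, size=n, p=(0.15, 0.75, 0.06, 0.04))
    df = pd.DataFrame(
        {
            "times_called": tc,
            "pct_prior_adherence": pct,
            "last_result": last,
            "age": np.clip(rng.normal(62.0, 14.0, size=n), 18.0, 100.0),
            "gender_male": rng.integers(0, 2, size=n),
            "income": rng.lognormal(np.log(10000.0), 0.5, size=n),
            "education_score": 100.0 * rng.beta(2.5, 3.0, size=n),
            "urbanization": rng.beta(3.0, 2.0, size=n),
            "occupation": rng.choice(OCCUPATIONS, size=n, p=(0.45, 0.42, 0.03, 0.10)),
            "has_phone_contact": rng.integers(0, 2, size=n),
            "has_family_doctor": (rng.uniform(size=n) < 0.85).astype(int),
            "primary_care_visits_12m": rng.poisson(3.0, size=n),
            "diabetes_type2": (rng.uniform(size=n) < 0.9).astype(int),
            "bmi": rng.normal(28.0, 4.5, size=n),
            "hba1c": rng.normal(7.2, 1.1, size=n),
            "call_month": rng.integers(1, 13, size=n),
            "days_between_calls": rng.normal(364.0, 45.0, size=n),
            "payment_exemption": (rng.uniform(size=n) < 0.4).astype(int),
            "health_unit_type_family": rng.integers(0, 2, size=n),
            "aces_list_size": rng.normal(50000.0, 12000.0, size=n),
            "distance_to_unit_km": rng.gamma(2.0, 2.5, size=n),
        }
    )
    if null_effects:
        p = np.full(n, 0.66)
    else:
        p = logistic_probabilities(model, pct, tc, last)
    df["adhered"] = (rng.uniform(size=n) < p).astype(int)
    return df


def _design_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Expand categoricals into the indicator columns used by selection."""
    X = records.drop(columns=["adhered"], errors="ignore").copy()
    if "last_result" in X:
        for cat in LAST_RESULTS[1:]:
            X[f"last_result_{cat}"] = (X["last_result"] == cat).astype(float)
        X = X.drop(columns=["last_result"])
    if "occupation" in X:
        for cat in OCCUPATIONS[1:]:
            X[f"occupation_{cat}"] = (X["occupation"] == cat).astype(float)
        X = X.drop(columns=["occupation"])
    return X.astype(float)


@dataclass
class StepwiseResult:
    """Outcome of the forward-stepwise selection."""

    model: LogisticModel
    selected: List[str]
    accuracy: float
    auc: float
    params: pd.Series
    bse: pd.Series


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    try:
        res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises several flavours here
        raise DecisionError(
            "logistic fit failed (possible separation or non-convergence); "
            "consider regularization or more data"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise DecisionError(
            "logistic fit did not converge; consider regularization or more data"
        )
    return res


def fit_stepwise_logistic(
    records: pd.DataFrame,
    candidates: Optional[Sequence[str]] = None,
    entry_p: float = 0.05,
    stay_p: float = 0.10,
    multiplicity: str = "bonferroni",
    test_fraction: float = 0.25,
    min_rows: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> StepwiseResult:
    """Forward-stepwise logistic selection by likelihood-ratio tests.

    At each forward step every remaining candidate is scored by the LR test
    of adding its design columns; the best enters if its p-value — Bonferroni
    adjusted across the candidates examined at that step under the default
    ``multiplicity`` setting, raw with ``multiplicity="none"`` — is below
    ``entry_p``.  After each entry, included candidates whose LR-test p-value
    for removal exceeds ``stay_p`` are dropped.  The per-step adjustment
    keeps the family-wise false-entry rate near ``entry_p`` across the full
    candidate set, so a null data set selects 0–1 covariates.

    Selection and fitting use a train split; accuracy (0.5 cut) and AUC are
    reported on the held-out remainder.
    """
    if "adhered" not in records.columns:
        raise DecisionError("records must contain the dichotomous 'adhered' outcome")
    if len(records) < min_rows:
        raise DecisionError(f"need at least {min_rows} rows, got {len(records)}")
    if multiplicity not in ("bonferroni", "none"):
        raise DecisionError(f"unknown multiplicity adjustment {multiplicity!r}")
    candidates = list(candidates) if candidates is not None else list(CANDIDATE_COVARIATES)
    unknown = [c for c in candidates if c not in CANDIDATE_COVARIATES]
    if unknown:
        raise DecisionError(f"unknown candidate covariates: {unknown}")

    X_all = _design_matrix(records)
    y_all = records["adhered"].to_numpy(dtype=float)
    rng = rng if rng is not None else np.random.default_rng(0)
    idx = rng.permutation(len(records))
    n_test = int(round(test_fraction * len(records)))
    test_idx, train_idx = idx[:n_test], idx[n_test:]
    X, y = X_all.iloc[train_idx], y_all[train_idx]

    selected: List[str] = []

    def cols(names: Sequence[str]) -> List[str]:
        out: List[str] = []
        for name in names:
            out.extend(CANDIDATE_COVARIATES[name])
        return out

    def lr_pvalue(base_names: Sequence[str], extra: str, drop: bool = False) -> float:
        if drop:
            full_names = list(base_names)
            reduced_names = [n for n in base_names if n != extra]
        else:
            full_names = list(base_names) + [extra]
            reduced_names = list(base_names)
        full = _fit_logit(y, X[cols(full_names)])
        reduced = _fit_logit(y, X[cols(reduced_names)])
        stat = 2.0 * (full.llf - reduced.llf)
        df = len(cols(full_names)) - len(cols(reduced_names))
        return float(chi2.sf(max(stat, 0.0), df))

    changed = True
    while changed:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            pvals = {c: lr_pvalue(selected, c) for c in remaining}
            best = min(pvals, key=pvals.get)
            m = len(remaining) if multiplicity == "bonferroni" else 1
            if min(1.0, pvals[best] * m) < entry_p:
                selected.append(best)
                logger.info("stepwise: entered %s (p=%.3g)", best, pvals[best])
                changed = True
        # backward pass at the stay threshold
        removed = True
        while removed and selected:
            removed = False
            drop_p = {c: lr_pvalue(selected, c, drop=True) for c in selected}
            worst = max(drop_p, key=drop_p.get)
            if drop_p[worst] > stay_p:
                selected.remove(worst)
                logger.info("stepwise: removed %s (p=%.3g)", worst, drop_p[worst])
                removed = True
                changed = True

    final = _fit_logit(y, X[cols(selected)])
    params = final.params
    model = LogisticModel(
        intercept=float(params.get("const", 0.0)),
        coefficients={k: float(v) for k, v in params.items() if k != "const"},
    )
    X_test, y_test = X_all.iloc[test_idx], y_all[test_idx]
    if len(test_idx):
        p_test = final.predict(sm.add_constant(X_test[cols(selected)], has_constant="add"))
        accuracy = float(np.mean((p_test > 0.5) == y_test))
        auc = float(roc_auc_score(y_test, p_test)) if len(np.unique(y_test)) == 2 else float("nan")
    else:
        accuracy, auc = float("nan"), float("nan")
    return StepwiseResult(
        model=model,
        selected=selected,
        accuracy=accuracy,
        auc=auc,
        params=params,
        bse=final.bse,
    )
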