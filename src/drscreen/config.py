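"""Hierarchical YAML configuration: loading, validation, run logging.

An empty (or absent) file yields the shipped defaults, which reproduce the
published programme parameters (52-week interval, sensitivity 0.96,
specificity 0.94, outcome probabilities 0.04/0.93/0.03, 4-week notice,
10-minute waiting time, 10 cycles, 5 replicates).  Unknown keys produce a
warning, not an error; out-of-range values are collected into a single
path-qualified validation error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from .decision import DEFAULT_LOGISTIC_MODEL, DecisionConfig, LogisticModel
from .population import ClusterProfile, HistorySpec, PopulationSpec, SubregionProfile
from .scenarios import PRESETS, Scenario
from .simulate import ScreeningConfig

logger = logging.getLogger(__name__)

__all__ = ["RootConfig", "ConfigError", "load_config", "default_config_path", "config_hash"]

DEFAULT_CONFIG_FILE = Path(__file__).parent / "data" / "default_config.yaml"


class ConfigError(ValueError):
    """Aggregated, path-qualified validation failures."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.violations))


@dataclass
class RootConfig:
    """Top-level configuration for a simulation run."""

    population: PopulationSpec = field(default_factory=PopulationSpec)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    logistic_model: LogisticModel = DEFAULT_LOGISTIC_MODEL
    scenarios: List[Scenario] = field(default_factory=list)
    output_dir: str = "runs"
    log_level: str = "INFO"
    seed: int = 0


def default_config_path() -> Path:
    """Path of the shipped canonical default configuration file."""
    return DEFAULT_CONFIG_FILE


def _build_section(cls, data: Mapping, path: str, violations: List[str], **overrides):
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = dict(overrides)
    for key, value in data.items():
        if key not in known:
            logger.warning("unknown configuration key %s.%s ignored", path, key)
            continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        violations.append(f"{path}: {exc}")
        return cls()


def _build_population(data: Mapping, violations: List[str]) -> PopulationSpec:
    data = dict(data)
    overrides: Dict[str, object] = {}
    if "subregions" in data:
        base = PopulationSpec().subregions
        subs = {}
        for name, sub_cfg in data.pop("subregions").items():
            template = dataclasses.asdict(base[name]) if name in base else {}
            template.update(sub_cfg or {})
            try:
                subs[name] = SubregionProfile(**template)
            except TypeError as exc:
                violations.append(f"population.subregions.{name}: {exc}")
        overrides["subregions"] = subs
    if "clusters" in data:
        base_c = PopulationSpec().clusters
        clusters = {}
        for cid, c_cfg in data.pop("clusters").items():
            cid = int(cid)
            template = dataclasses.asdict(base_c[cid]) if cid in base_c else {}
            template.update(
                {
                    k: tuple(v) if k == "occupation_probs" else v
                    for k, v in (c_cfg or {}).items()
                }
            )
            try:
                clusters[cid] = ClusterProfile(**template)
            except TypeError as exc:
                violations.append(f"population.clusters.{cid}: {exc}")
        overrides["clusters"] = clusters
    if "history" in data:
        h = data.pop("history")
        if "result_probs" in h:
            h["result_probs"] = tuple(h["result_probs"])
        overrides["history"] = _build_section(HistorySpec, h, "population.history", violations)
    if "age_bounds" in data:
        data["age_bounds"] = tuple(data["age_bounds"])
    return _build_section(PopulationSpec, data, "population", violations, **overrides)


def _build_scenarios(entries, violations: List[str]) -> List[Scenario]:
    scenarios: List[Scenario] = []
    for i, entry in enumerate(entries or []):
        try:
            if isinstance(entry, str):
                if entry not in PRESETS:
                    raise ValueError(f"unknown scenario preset {entry!r}")
                scenarios.append(PRESETS[entry])
            else:
                scenarios.append(Scenario.from_dict(entry))
        except (KeyError, TypeError, ValueError) as exc:
            violations.append(f"scenarios[{i}]: {exc}")
    return scenarios


def load_config(path=None) -> RootConfig:
    """Parse and validate a YAML configuration file.

    ``path=None`` loads the shipped default file; an empty file gives all
    defaults.  All violations are reported together in one
    :class:`ConfigError`.
    """
    if path is None:
        path = DEFAULT_CONFIG_FILE
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError([f"parse error in {path}: {exc}"]) from exc
    raw = raw or {}
    if not isinstance(raw, Mapping):
        raise ConfigError([f"{path}: top level must be a mapping"])

    violations: List[str] = []
    known_top = {
        "population",
        "screening",
        "decision",
        "logistic_model",
        "scenarios",
        "output_dir",
        "log_level",
        "seed",
    }
    for key in raw:
        if key not in known_top:
            logger.warning("unknown configuration key %s ignored", key)

    population = _build_population(raw.get("population", {}) or {}, violations)
    screening = _build_section(ScreeningConfig, raw.get("screening", {}) or {}, "screening", violations)
    decision = _build_section(DecisionConfig, raw.get("decision", {}) or {}, "decision", violations)
    if "logistic_model" in raw and raw["logistic_model"]:
        try:
            model = LogisticModel.from_dict(raw["logistic_model"])
        except (KeyError, TypeError, ValueError) as exc:
            violations.append(f"logistic_model: {exc}")
            model = DEFAULT_LOGISTIC_MODEL
    else:
        model = DEFAULT_LOGISTIC_MODEL
    scenarios = _build_scenarios(raw.get("scenarios"), violations)

    if violations:
        raise ConfigError(violations)
    return RootConfig(
        population=population,
        screening=screening,
        decision=decision,
        logistic_model=model,
        scenarios=scenarios,
        output_dir=str(raw.get("output_dir", "runs")),
        log_level=str(raw.get("log_level", "INFO")),
        seed=int(raw.get("seed", 0)),
    )


def config_hash(config: RootConfig) -> str:
    """Stable short hash of the fully resolved configuration."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, Mapping):
            return {str(k): encode(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def setup_run_logging(output_dir, config: RootConfig, seed: int) -> Path:
    """Write a per-run log file recording config hash, seed and version."""
    from . import __version__

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("drscreen")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    root.info("drscreen %s | config hash %s | seed %d", __version__, config_hash(config), seed)
    return log_path
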