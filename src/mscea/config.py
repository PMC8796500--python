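"""Model configuration: schema validation and builders for the engine objects.

A configuration is a nested mapping (YAML on disk) holding the transition
table, run settings, willingness-to-pay threshold, per-arm parameters, and
optional blocks for the probabilistic sensitivity analysis, the observed
cost table and the synthetic-cohort targets.  Validation errors name the
offending field with its dotted path.  Sensitivity analyses address scalar
entries through the same dotted paths (``arms.rituximab.drug_cost``).
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from mscea.cea_core import Threshold
from mscea.markov_engine import (
    ArmParameters,
    ModelSettings,
    TransitionTable,
)
from mscea.states import LIVING_STATES


class ConfigError(ValueError):
    """Schema violation, reported with the dotted path of the field."""


def default_config_path() -> Path:
    """Path of the bundled base-case configuration."""
    ref = resources.files("mscea.data") / "base_case.yaml"
    with resources.as_file(ref) as p:
        return Path(p)


def get_path(cfg: dict, path: str) -> Any:
    node: Any = cfg
    for part in path.split("."):
        try:
            node = node[part]
        except (KeyError, TypeError):
            raise ConfigError(f"unknown config path {path!r}") from None
    return node


def set_path(cfg: dict, path: str, value: Any) -> None:
    parts = path.split(".")
    node: Any = cfg
    for part in parts[:-1]:
        try:
            node = node[part]
        except (KeyError, TypeError):
            raise ConfigError(f"unknown config path {path!r}") from None
    if parts[-1] not in node:
        raise ConfigError(f"unknown config path {path!r}")
    node[parts[-1]] = value


_REQUIRED_ARM_FIELDS = ("annual_relapse_prob", "drug_cost", "utilities", "other_costs")


def validate_config(cfg: dict) -> dict:
    """Check the schema; returns the config unchanged on success."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for block in ("transition_table", "settings", "threshold", "arms"):
        if block not in cfg:
            raise ConfigError(f"missing required block {block!r}")
    tt = cfg["transition_table"]
    for sub in ("living_rows", "death_probs"):
        if sub not in tt:
            raise ConfigError(f"missing field transition_table.{sub}")
        for s in LIVING_STATES:
            if s not in tt[sub]:
                raise ConfigError(f"missing field transition_table.{sub}.{s}")
    for key in ("gdp_per_capita", "multiplier"):
        if key not in cfg["threshold"]:
            raise ConfigError(f"missing field threshold.{key}")
    arms = cfg["arms"]
    if not isinstance(arms, dict) or len(arms) != 2:
        raise ConfigError("arms must map exactly two strategy names")
    for arm, spec in arms.items():
        for f in _REQUIRED_ARM_FIELDS:
            if f not in spec:
                raise ConfigError(f"missing field arms.{arm}.{f}")
        for sub in ("utilities", "other_costs"):
            for s in LIVING_STATES:
                if s not in spec[sub]:
                    raise ConfigError(f"missing field arms.{arm}.{sub}.{s}")
    sd = cfg["settings"].get("start_distribution")
    if sd is not None:
        for s in LIVING_STATES:
            if s not in sd:
                raise ConfigError(f"missing field settings.start_distribution.{s}")
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a configuration; ``None`` loads the bundled base case."""
    if path is None:
        ref = resources.files("mscea.data") / "base_case.yaml"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    return validate_config(cfg)


def copy_config(cfg: dict) -> dict:
    return copy.deepcopy(cfg)


# ------------------------------------------------------------------- builders


def build_transition_table(cfg: dict) -> TransitionTable:
    tt = cfg["transition_table"]
    return TransitionTable.from_dicts(tt["living_rows"], tt["death_probs"])


def build_settings(cfg: dict) -> ModelSettings:
    s = cfg["settings"]
    start = s.get("start_distribution")
    kwargs: dict[str, Any] = {}
    if start is not None:
        kwargs["start_distribution"] = tuple(float(start[x]) for x in LIVING_STATES)
    for f in (
        "start_age",
        "max_age",
        "cycle_length",
        "discount_rate_costs",
        "discount_rate_outcomes",
        "survival_floor",
        "half_cycle_correction",
        "discount_first_cycle",
    ):
        if f in s:
            kwargs[f] = s[f]
    return ModelSettings(**kwargs)


def build_arm(cfg: dict, name: str) -> ArmParameters:
    try:
        spec = cfg["arms"][name]
    except KeyError:
        raise ConfigError(f"unknown arm {name!r}") from None
    return ArmParameters(
        name=name,
        annual_relapse_prob=float(spec["annual_relapse_prob"]),
        state_utilities={s: float(spec["utilities"][s]) for s in LIVING_STATES},
        drug_cost=float(spec["drug_cost"]),
        other_costs={s: float(spec["other_costs"][s]) for s in LIVING_STATES},
    )


def build_threshold(cfg: dict) -> Threshold:
    t = cfg["threshold"]
    return Threshold(
        gdp_per_capita=float(t["gdp_per_capita"]),
        multiplier=float(t["multiplier"]),
    )


def arm_names(cfg: dict) -> tuple[str, str]:
    """(intervention, comparator): the cheaper-drug arm is the intervention
    when both are present; otherwise insertion order."""
    names = list(cfg["arms"])
    if set(names) == {"rituximab", "natalizumab"}:
        return "rituximab", "natalizumab"
    return names[0], names[1]


def threshold_grid(cfg: dict) -> np.ndarray:
    """CEAC willingness-to-pay grid from the psa block (or a default)."""
    psa = cfg.get("psa", {})
    th = psa.get("thresholds", {"start": 0, "stop": 75000, "step": 2500})
    if isinstance(th, dict):
        return np.arange(th["start"], th["stop"] + th["step"] / 2, th["step"], float)
    return np.asarray(sorted(float(x) for x in th))


def not_from_paper_paths(cfg: dict) -> list[str]:
    """Dotted paths of placeholder values not taken from study data."""
    return list(cfg.get("not_from_paper", []))
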