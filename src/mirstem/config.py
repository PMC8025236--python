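"""Run configuration: defaults, validation, cross-field constraints.

The config file is YAML with one section per stage.  Validation
materializes defaults, rejects unknown keys, checks referenced paths and
cross-field constraints, and reports every problem at once in a single
aggregated error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "RunConfig", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems)
        )


# section -> {key: default}.  ``None`` defaults mean "stage not requested"
# for path-valued keys.
_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "kind": "derepression",
        "n_genes": 11_000,
        "n_targets": 945,
        "target_shift": 0.10,
        "background_sd": 0.5,
        "n_experiments": 4,
        "ct_mean_hk": 20.0,
        "ct_tech_sd": 0.25,
        "detection_ceiling": 28.0,
    },
    "profile": {
        "ct_path": None,
        "group_a": None,
        "group_b": None,
        "fc_threshold": 0.5,
        "p_threshold": 0.05,
        "detection_ceiling": 28.0,
        "fdr": False,
    },
    "stratify": {
        "matrix_path": None,
        "annot_path": None,
        "k": 3,
        "log_transform": True,
    },
    "derepress": {
        "profile_paths": None,
        "targets_path": None,
        "n_bins": 10,
        "select": "fixed_paper",
        "context_threshold": -0.15,
        "n_bootstrap": 1000,
    },
    "ldassay": {"table_path": None, "compare": None, "ci_method": "wald"},
    "dose": {"table_path": None, "reference": None},
    "run": {"seed": None, "out_dir": "results", "stages": None},
}


@dataclass
class RunConfig:
    """A validated pipeline configuration with all defaults materialized."""

    sections: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: Path = Path("results")

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @property
    def stages(self) -> list[str]:
        return self.sections["run"]["stages"] or []


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw (parsed) configuration mapping.

    Raises a single ConfigError listing every unknown key, missing path and
    violated cross-field constraint.
    """
    problems: list[str] = []
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping of sections"])

    sections: dict = {}
    for name, value in raw.items():
        if name not in _DEFAULTS:
            problems.append(f"unknown section '{name}'")
            continue
        if value is None:
            value = {}
        if not isinstance(value, dict):
            problems.append(f"section '{name}' must be a mapping")
            continue
        for key in value:
            if key not in _DEFAULTS[name]:
                problems.append(f"unknown key '{name}.{key}'")
    for name, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        merged.update({k: v for k, v in (raw.get(name) or {}).items() if k in defaults})
        sections[name] = merged

    # cross-field constraints
    d = sections["derepress"]
    if d["select"] == "fixed_paper" and d["n_bins"] != 10:
        problems.append(
            f"derepress.select=fixed_paper requires n_bins=10 (got {d['n_bins']})"
        )
    s = sections["simulate"]
    if s["n_targets"] > s["n_genes"]:
        problems.append("simulate.n_targets cannot exceed simulate.n_genes")

    requested = sections["run"]["stages"] or []
    known_stages = {"simulate", "profile", "stratify", "derepress", "ldassay", "dose"}
    for st in requested:
        if st not in known_stages:
            problems.append(f"run.stages contains unknown stage '{st}'")

    # referenced paths must exist (only for requested stages, or any stage
    # whose path keys were explicitly set)
    path_keys = {
        "profile": ["ct_path"],
        "stratify": ["matrix_path", "annot_path"],
        "derepress": ["targets_path"],
        "ldassay": ["table_path"],
        "dose": ["table_path"],
    }
    for stage, keys in path_keys.items():
        for key in keys:
            val = sections[stage][key]
            if val is not None and not Path(val).exists():
                problems.append(f"{stage}.{key}: path does not exist: {val}")
    paths = sections["derepress"]["profile_paths"]
    if paths is not None:
        for p in paths:
            if not Path(p).exists():
                problems.append(f"derepress.profile_paths: path does not exist: {p}")

    stochastic = {"simulate"} & set(requested)
    if stochastic and sections["run"]["seed"] is None:
        problems.append("run.seed is required when stochastic stages are requested")

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        sections=sections,
        seed=sections["run"]["seed"],
        out_dir=Path(sections["run"]["out_dir"]),
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw or {})
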