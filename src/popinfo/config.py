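"""Experiment configuration, result writing and run manifests.

Configurations are plain YAML mappings validated against a per-experiment
schema (unknown keys are rejected, missing keys are filled with defaults).
A run is fully determined by its resolved configuration -- the seed is part
of it -- so the manifest written next to the results is sufficient to
reproduce every table cell bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "EXPERIMENTS",
    "default_config",
    "load_config",
    "config_from_dict",
    "write_results",
]

EXPERIMENTS = ("fig2", "fig5", "fig6", "fig7", "family")

_LOG_SIGMA2_GRID = [0.0] + list(np.logspace(-3.0, 2.0, 20))
_EPS_U_GRID = list(np.logspace(-4.0, -1.0, 8))


@dataclass
class ExperimentConfig:
    """Resolved parameters of one experiment run.

    Fields cover all experiments; per-experiment defaults are applied by
    :func:`default_config`.  ``epsilon`` is the rank-1 strength of the
    signal-aligned reference population; ``theta_u`` the tilt angle of the
    companion population; sweep grids are used only by the experiments that
    declare them.
    """

    experiment: str
    seed: int = 0
    profile: str = "paper"
    n_neurons: int = 100
    n_stimuli: int = 100
    epsilon: float = 1e-3
    theta_u: float = 1.0 / 8.0
    sigma2_grid: List[float] = field(default_factory=lambda: list(_LOG_SIGMA2_GRID))
    eps_u_grid: List[float] = field(default_factory=lambda: list(_EPS_U_GRID))
    theta_u_set: List[float] = field(default_factory=lambda: [0.0, 0.05, 0.1, 0.2])
    sigma_zeta2_set: List[float] = field(default_factory=lambda: [0.0])
    alpha_grid: List[float] = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    sigma_y_kind: str = "random"  # family experiment: "iid" or "random"
    sigma_y_scale: float = 1.0
    mc_draws: int = 1_000_000
    fd_step: float = 1e-4
    corr_match_tol: float = 1e-5
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        if self.profile not in ("paper", "test"):
            raise ValueError(f"profile must be 'paper' or 'test', got {self.profile!r}")
        if self.n_neurons < 1 or self.n_stimuli < 1:
            raise ValueError("n_neurons and n_stimuli must be >= 1")
        for name in ("sigma2_grid", "eps_u_grid", "theta_u_set", "sigma_zeta2_set",
                     "alpha_grid"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if not all(math.isfinite(v) for v in vals):
                raise ValueError(f"{name} contains non-finite values")
        if self.sigma_y_kind not in ("iid", "random"):
            raise ValueError("sigma_y_kind must be 'iid' or 'random'")

    def stimulus_grid(self) -> np.ndarray:
        return np.linspace(0.0, 2.0 * math.pi, self.n_stimuli, endpoint=False)

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = [float(x) for x in v]
        return d


_FIELD_TYPES: Dict[str, type] = {
    "experiment": str,
    "seed": int,
    "profile": str,
    "n_neurons": int,
    "n_stimuli": int,
    "epsilon": float,
    "theta_u": float,
    "sigma2_grid": list,
    "eps_u_grid": list,
    "theta_u_set": list,
    "sigma_zeta2_set": list,
    "alpha_grid": list,
    "sigma_y_kind": str,
    "sigma_y_scale": float,
    "mc_draws": int,
    "fd_step": float,
    "corr_match_tol": float,
    "max_attempts": int,
}


def default_config(experiment: str, profile: str = "paper", seed: int = 0) -> ExperimentConfig:
    """Fully defaulted configuration for one experiment.

    The ``paper`` profile uses 100 neurons, 100 stimuli (20 for the spiking
    sweeps) and 10^6 Monte-Carlo draws; the ``test`` profile shrinks the
    spiking experiments to 30 neurons and 10^5 draws so the full suite runs
    in minutes.
    """
    cfg = ExperimentConfig(experiment=experiment, seed=seed, profile=profile)
    if experiment in ("fig5", "fig6"):
        cfg.n_stimuli = 20
        if experiment == "fig6":
            cfg.theta_u_set = [0.0, 0.1]
            cfg.sigma_zeta2_set = [0.0, 1.0, 4.0, 16.0]
        if profile == "test":
            cfg.n_neurons = 30
            cfg.mc_draws = 100_000
            if experiment == "fig6":
                cfg.sigma_zeta2_set = [0.0, 4.0]
    if experiment == "fig7":
        cfg.epsilon = -5e-4
        cfg.theta_u = 1.0 / 4.0
    if experiment == "family":
        cfg.n_neurons = 30
        cfg.n_stimuli = 5
    if profile == "test" and experiment in ("fig2", "fig7"):
        cfg.n_neurons = 30
        cfg.n_stimuli = 40
    return cfg


def config_from_dict(raw: Dict[str, Any]) -> ExperimentConfig:
    """Validate a raw mapping against the schema and fill defaults."""
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    if "experiment" not in raw:
        raise ValueError("configuration must name an 'experiment'")
    unknown = sorted(set(raw) - set(_FIELD_TYPES))
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    cfg = default_config(
        str(raw["experiment"]),
        profile=str(raw.get("profile", "paper")),
        seed=int(raw.get("seed", 0)),
    )
    errors = []
    for key, value in raw.items():
        if key in ("experiment", "profile", "seed"):
            continue
        want = _FIELD_TYPES[key]
        try:
            if want is list:
                value = [float(v) for v in value]
            else:
                value = want(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: cannot coerce {value!r} to {want.__name__}")
            continue
        setattr(cfg, key, value)
    if errors:
        raise ValueError("invalid configuration values: " + "; ".join(errors))
    cfg.__post_init__()  # re-validate after overrides
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML/JSON experiment configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return config_from_dict(raw)


def write_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_results(table: pd.DataFrame, path, columns: Optional[Sequence[str]] = None) -> None:
    """Write a results table as CSV with full float precision.

    Rejects NaN/inf in numeric columns (information values must be finite)
    and, when ``columns`` is given, enforces the declared schema.
    """
    if columns is not None and list(table.columns) != list(columns):
        raise ValueError(
            f"results schema mismatch: expected {list(columns)}, got {list(table.columns)}"
        )
    numeric = table.select_dtypes(include=[np.number])
    if numeric.size and not np.all(np.isfinite(numeric.to_numpy())):
        raise ValueError("results contain non-finite values")
    table.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config, seed, version, warnings."""

    config: Dict[str, Any]
    package_version: str
    timings: Dict[str, float] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)
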