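"""YAML run configuration: experiment descriptors over the reference defaults.

A configuration file overrides any subset of the model parameters and
selects an experiment; unspecified fields keep their defaults, unknown
keys are rejected with their location.  Configurations round-trip
losslessly through :func:`dump_config` / :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .params import ModelParams, params_from_dict, params_to_dict

__all__ = ["RunConfig", "load_config", "dump_config"]

EXPERIMENTS = ("steady_state", "brdu", "clonal", "perturbation", "ablation", "sweep")


@dataclass
class RunConfig:
    """Complete description of one simulation run."""

    schema: int = 1
    params: ModelParams = field(default_factory=ModelParams)
    experiment: str = "steady_state"
    duration: float = 240.0        # h of measurement after warm-up
    warmup: float = 240.0          # h discarded before measurement
    observer_interval: float = 6.0  # h between trajectory samples
    seed: int = 0
    replicates: int = 1
    outdir: str = "out"
    # experiment-specific settings
    perturbation_kind: str = "WNT_UP"
    ablate_lineages: list = field(default_factory=lambda: ["UNDIFFERENTIATED"])
    sweep_param: str = "fate.lp_paneth"
    sweep_values: list = field(default_factory=lambda: [0.2, 0.35, 0.5])
    brdu_sample_times: list = field(default_factory=lambda: [2.0, 24.0])

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.duration < 0 or self.warmup < 0:
            raise ValueError("duration and warmup must be non-negative")


def config_from_dict(data: dict) -> RunConfig:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} at '<root>'")
    kwargs = dict(data)
    if "params" in kwargs:
        kwargs["params"] = params_from_dict(ModelParams, kwargs["params"], "params")
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    out = {f.name: getattr(cfg, f.name) for f in fields(RunConfig)}
    out["params"] = params_to_dict(cfg.params)
    return out


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path) -> None:
    """Serialise a configuration so that load(dump(cfg)) == cfg."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
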