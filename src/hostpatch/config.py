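"""Run configuration: flat key-value files, flag overrides, validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .metapopulation import SimulationParams

__all__ = ["RunConfig", "parse_config"]

_PARAM_FIELDS = {f.name for f in fields(SimulationParams)}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run configuration.

    Wraps the validated :class:`SimulationParams` together with the
    command-level options shared by the CLI entry points.
    """

    params: SimulationParams
    seed: int = 0
    replicates: int = 500
    total_steps: int = 10_000
    n_patches: int = 10_000
    n_cycles: int = 20
    invader: bool = True
    founders_f: int = 4
    founders_s: int = 1
    output: str | None = None
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        doc = dataclasses.asdict(self.params)
        for f in fields(self):
            if f.name != "params":
                doc[f.name] = getattr(self, f.name)
        return doc


_RUN_FIELDS = {f.name for f in fields(RunConfig)} - {"params"}


def parse_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> RunConfig:
    """Resolve a run configuration from an optional file plus overrides.

    The file is a flat key-value YAML document whose keys mirror the CLI
    flags one-to-one; explicit overrides (CLI flags) take precedence over
    file values, which take precedence over defaults.  Unknown keys are
    rejected, and value validation errors name the offending field.
    """
    merged: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} must be a flat key-value document")
        merged.update(doc)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(merged) - _PARAM_FIELDS - _RUN_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    param_kwargs = {k: v for k, v in merged.items() if k in _PARAM_FIELDS}
    run_kwargs = {k: v for k, v in merged.items() if k in _RUN_FIELDS}
    try:
        params = SimulationParams(**param_kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid simulation parameters: {exc}") from exc
    cfg = RunConfig(params=params, **run_kwargs)
    if cfg.replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {cfg.replicates}")
    if cfg.seed < 0:
        raise ValueError(f"seed must be >= 0, got {cfg.seed}")
    return cfg
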