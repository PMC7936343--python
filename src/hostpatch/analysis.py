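"""Summary statistics, parameter sweeps, and delimited-text output.

Cycle records and sweep results are exchanged as headered CSV with stable
column schemas; run manifests are flat YAML key-value documents capturing
the full parameterization plus the master seed, enabling bit-exact reruns.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metapopulation import (
    CycleRecord,
    SimulationParams,
    estimate_fixation_probability,
)

__all__ = [
    "SWEEPABLE",
    "SweepSpec",
    "enrichment_summary",
    "point_seed",
    "run_sweep",
    "write_records",
    "read_records",
    "write_sweep",
    "read_sweep",
    "write_manifest",
    "read_manifest",
]

RECORD_COLUMNS = [
    "cycle",
    "f_patch",
    "f_host",
    "occupied_patches",
    "mature_hosts",
    "pool_size",
    "live_hosts_total",
]

SWEEP_COLUMNS = [
    "param",
    "value",
    "fixation",
    "ci_lo",
    "ci_hi",
    "mean_f_patch",
    "mean_f_host",
    "censored",
    "replicates",
    "seed",
]

SWEEPABLE = ("b", "D", "c", "m", "tau", "delta_s")


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter scan: grid of values, replicates per point, base run.

    ``seed`` is the master seed; every grid point derives its own logged
    integer seed (see :func:`point_seed`) from which replicate streams are
    spawned, so any row of the output can be re-run in isolation.
    """

    param: str
    values: tuple
    replicates: int
    base: SimulationParams
    seed: int

    def __post_init__(self) -> None:
        if self.param not in SWEEPABLE:
            raise ValueError(
                f"unknown sweep parameter {self.param!r}; choose from {SWEEPABLE}"
            )
        if len(self.values) == 0:
            raise ValueError("sweep grid must be non-empty")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


def enrichment_summary(
    records: list[CycleRecord],
) -> tuple[float, float, float]:
    """Mean f_patch, mean f_host and their mean difference over a run.

    Averages are taken over cycles where both fractions are defined; the
    difference ``f_host - f_patch`` is the host-enrichment of the slow
    type.  All three are NaN when no cycle has both defined.
    """
    if not records:
        raise ValueError("enrichment_summary requires at least one record")
    fp = np.array([r.f_patch for r in records])
    fh = np.array([r.f_host for r in records])
    ok = ~np.isnan(fp) & ~np.isnan(fh)
    if not np.any(ok):
        return math.nan, math.nan, math.nan
    return (
        float(np.mean(fp[ok])),
        float(np.mean(fh[ok])),
        float(np.mean(fh[ok] - fp[ok])),
    )


def point_seed(master_seed: int, index: int) -> int:
    """Derived integer seed for grid point ``index`` of a sweep.

    Hashes ``(master_seed, index)`` through ``numpy.random.SeedSequence``
    and truncates to 31 bits, so the logged value is a plain int that fully
    determines the point's replicate streams.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Estimate fixation probability along the grid of a :class:`SweepSpec`.

    One row per grid point with the fixation estimate, its 95% Wilson CI,
    the run-averaged slow fractions in patches and hosts (mean over
    replicates of each replicate's cycle-mean), the censored-replicate
    count and the logged per-point seed.
    """
    rows = []
    for i, value in enumerate(spec.values):
        params = dataclasses.replace(spec.base, **{spec.param: value})
        seed = point_seed(spec.seed, i)
        est, all_records = estimate_fixation_probability(
            params, spec.replicates, seed, collect_records=True
        )
        per_rep = [enrichment_summary(recs) for recs in all_records if recs]
        mfp = [s[0] for s in per_rep if not math.isnan(s[0])]
        mfh = [s[1] for s in per_rep if not math.isnan(s[1])]
        rows.append(
            {
                "param": spec.param,
                "value": value,
                "fixation": est.estimate,
                "ci_lo": est.ci_low,
                "ci_hi": est.ci_high,
                "mean_f_patch": float(np.mean(mfp)) if mfp else math.nan,
                "mean_f_host": float(np.mean(mfh)) if mfh else math.nan,
                "censored": est.censored,
                "replicates": est.replicates,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def write_records(records: list[CycleRecord], path: str | Path) -> None:
    """Write cycle records as headered CSV (header-only file when empty)."""
    df = pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=RECORD_COLUMNS
    )
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write cycle records to {path}: {exc}") from exc


def read_records(path: str | Path) -> list[CycleRecord]:
    """Read cycle records written by :func:`write_records`."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read cycle records from {path}: {exc}") from exc
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(f"unexpected cycle-record columns in {path}: {list(df.columns)}")
    return [
        CycleRecord(
            cycle=int(r.cycle),
            f_patch=float(r.f_patch),
            f_host=float(r.f_host),
            occupied_patches=int(r.occupied_patches),
            mature_hosts=int(r.mature_hosts),
            pool_size=int(r.pool_size),
            live_hosts_total=int(r.live_hosts_total),
        )
        for r in df.itertuples()
    ]


def write_sweep(result: pd.DataFrame, path: str | Path) -> None:
    """Write a sweep result table as headered CSV."""
    if list(result.columns) != SWEEP_COLUMNS:
        raise ValueError(f"unexpected sweep columns: {list(result.columns)}")
    try:
        result.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write sweep result to {path}: {exc}") from exc


def read_sweep(path: str | Path) -> pd.DataFrame:
    """Read a sweep result table written by :func:`write_sweep`."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read sweep result from {path}: {exc}") from exc
    if list(df.columns) != SWEEP_COLUMNS:
        raise ValueError(f"unexpected sweep columns in {path}: {list(df.columns)}")
    return df


def write_manifest(
    params: SimulationParams, seed: int, path: str | Path, **extra
) -> None:
    """Write a flat key-value run manifest (YAML) with params + seed."""
    doc = dataclasses.asdict(params)
    doc["seed"] = int(seed)
    doc.update(extra)
    try:
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
    except OSError as exc:
        raise OSError(f"cannot write manifest to {path}: {exc}") from exc


def read_manifest(path: str | Path) -> dict:
    """Read a run manifest back as a flat dict."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise OSError(f"cannot read manifest from {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"manifest {path} is not a flat key-value document")
    return doc
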