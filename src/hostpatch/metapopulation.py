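"""Metapopulation engines: synchronous cycles, fixation runs, async clock.

The synchronous engine alternates a within-patch growth/decay cycle of
``tau`` steps with a dispersal phase (uptake -> pool -> uniform assignment
to M fresh patches -> founding).  Fixation runs start from a single slow
invader cell and iterate cycles until one microbial type fixes, microbes or
hosts go extinct, or a cycle cap is hit.  The asynchronous engine
generalizes the life cycle to a single global clock with per-host
development times uniform on ``[tau - tau_d, tau + tau_d]`` and renewal
events that replace ``M0`` random patches with empty ones; the synchronous
model is the special case ``tau_d = 0``, ``M0 = M`` with renewal exactly
every ``tau`` steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import dispersal as dsp
from .patch_dynamics import (
    DecayParams,
    GrowthParams,
    PatchState,
    run_patch_cycle_batch,
)

__all__ = [
    "SimulationParams",
    "MetapopState",
    "CycleRecord",
    "FixationOutcome",
    "FixationEstimate",
    "AsyncSnapshot",
    "SLOW_FIXED",
    "FAST_FIXED",
    "MICROBES_EXTINCT",
    "HOSTS_EXTINCT",
    "CENSORED",
    "initialize",
    "synchronous_cycle",
    "run_cycles",
    "run_until_fixation",
    "estimate_fixation_probability",
    "independent_patches_experiment",
    "asynchronous_run",
]

SLOW_FIXED = "slow_fixed"
FAST_FIXED = "fast_fixed"
MICROBES_EXTINCT = "microbes_extinct"
HOSTS_EXTINCT = "hosts_extinct"
CENSORED = "censored"

GEOMETRIC = "geometric"
PERIODIC = "periodic"


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of a metapopulation run.

    Defaults are the standard simulation values used throughout:
    M=50 patches of capacity K=10^4, dispersal pool cap D=100, slow-type
    fitness cost c=0.15, clutch size H0=100, uptake bottleneck b=5,
    development time tau=10^3 steps, decay parameters delta_K=delta_s=0.1
    and N0=5 founder cells per initially colonized patch.  ``m`` free
    migrant cells disperse per cycle (0 by default).  ``tau_d``, ``M0``,
    ``renewal_mean`` and ``renewal_schedule`` only affect the asynchronous
    engine; their defaults make it degenerate to the synchronous model.
    """

    M: int = 50
    K: int = 10_000
    D: int = 100
    c: float = 0.15
    H0: int = 100
    b: int = 5
    tau: int = 1000
    delta_K: float = 0.1
    delta_s: float = 0.1
    N0: int = 5
    m: int = 0
    colonized_fraction: float = 1.0
    tau_d: int = 0
    M0: int | None = None
    renewal_mean: int | None = None
    renewal_schedule: str = PERIODIC
    kernel: str = "pure_birth"
    uptake: str = "proportion"
    max_cycles: int = 2000

    def __post_init__(self) -> None:
        for name in ("M", "K", "D", "H0", "b", "tau", "N0", "m", "max_cycles"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if not 0.0 <= self.colonized_fraction <= 1.0:
            raise ValueError(
                f"colonized_fraction must be in [0, 1], got {self.colonized_fraction}"
            )
        if self.tau_d < 0 or (self.tau > 0 and self.tau_d >= self.tau):
            if self.tau_d != 0:
                raise ValueError(
                    f"tau_d must satisfy 0 <= tau_d < tau, got tau_d={self.tau_d}"
                )
        if self.M0 is not None and not 0 <= self.M0 <= self.M:
            raise ValueError(f"M0 must be in [0, M={self.M}], got {self.M0}")
        if self.renewal_mean is not None and self.renewal_mean < 1:
            raise ValueError(f"renewal_mean must be >= 1, got {self.renewal_mean}")
        if self.renewal_schedule not in (GEOMETRIC, PERIODIC):
            raise ValueError(f"unknown renewal_schedule {self.renewal_schedule!r}")
        if self.uptake not in ("proportion", "hypergeometric"):
            raise ValueError(f"unknown uptake model {self.uptake!r}")
        # delegate range checks on c, K, delta_K, delta_s, kernel
        self.growth()
        self.decay()

    def growth(self) -> GrowthParams:
        return GrowthParams(c=self.c, K=self.K, kernel=self.kernel)

    def decay(self) -> DecayParams:
        return DecayParams(delta_K=self.delta_K, delta_s=self.delta_s)

    @property
    def effective_M0(self) -> int:
        return self.M if self.M0 is None else self.M0

    @property
    def effective_renewal_mean(self) -> int:
        return self.tau if self.renewal_mean is None else self.renewal_mean


@dataclass
class MetapopState:
    """All patches plus the cycle index and the RNG that drives the run."""

    patches: list[PatchState]
    cycle: int
    rng: np.random.Generator


@dataclass(frozen=True)
class CycleRecord:
    """Per-cycle summary, computed at the end of growth before founding.

    ``f_patch`` is the mean slow fraction over occupied patches (unweighted
    by default), ``f_host`` the mean carried slow fraction over pooled
    hosts with at least one microbe; both are NaN when undefined.
    ``live_hosts_total`` counts the developing hosts founding the next
    generation (pooled hosts times clutch size).
    """

    cycle: int
    f_patch: float
    f_host: float
    occupied_patches: int
    mature_hosts: int
    pool_size: int
    live_hosts_total: int


@dataclass(frozen=True)
class FixationOutcome:
    outcome: str
    cycles: int


@dataclass(frozen=True)
class FixationEstimate:
    """Monte-Carlo fixation probability with a Wilson binomial CI.

    Censored runs (hitting ``max_cycles`` undecided) are reported
    separately and never counted as fixations.
    """

    estimate: float
    ci_low: float
    ci_high: float
    replicates: int
    fixed: int
    censored: int


@dataclass(frozen=True)
class AsyncSnapshot:
    """Windowed summary of the asynchronous engine.

    ``f_host`` averages over hosts that matured (and dispersed) since the
    previous snapshot; ``dispersed_hosts`` counts them.
    """

    t: int
    f_patch: float
    f_host: float
    occupied_patches: int
    live_hosts_total: int
    dispersed_hosts: int


def _mean_slow_fraction(
    Nf: np.ndarray, Ns: np.ndarray, weighted: bool = False
) -> float:
    """Mean slow fraction over occupied patches; NaN if none are occupied."""
    total = Nf + Ns
    occ = total > 0
    if not np.any(occ):
        return math.nan
    if weighted:
        return float(Ns[occ].sum() / total[occ].sum())
    return float(np.mean(Ns[occ] / total[occ]))


def initialize(
    params: SimulationParams, invader: bool, rng: np.random.Generator
) -> MetapopState:
    """Build generation 0: colonized patches get N0 fast founder cells.

    A fraction ``colonized_fraction`` of patches (rounded, and at least one
    when an invader is requested) is seeded with ``N0`` all-fast cells; if
    ``invader``, one uniformly chosen colonized patch has exactly one
    founder converted to the slow type.  Every patch receives one virtual
    founding clutch of ``H0`` developing hosts.
    """
    n_col = int(round(params.colonized_fraction * params.M))
    if invader:
        if params.colonized_fraction == 0.0:
            raise ValueError("cannot place an invader with colonized_fraction = 0")
        n_col = max(n_col, 1)
    colonized = rng.choice(params.M, size=n_col, replace=False) if n_col else []
    patches = [PatchState(Nf=0, Ns=0, H=params.H0, t=0) for _ in range(params.M)]
    for i in colonized:
        patches[int(i)] = PatchState(Nf=params.N0, Ns=0, H=params.H0, t=0)
    if invader:
        target = int(rng.choice(np.asarray(colonized)))
        p = patches[target]
        if p.Nf < 1:
            raise ValueError("invader requires N0 >= 1 founder cells")
        patches[target] = PatchState(Nf=p.Nf - 1, Ns=1, H=p.H, t=0)
    return MetapopState(patches=patches, cycle=0, rng=rng)


def synchronous_cycle(
    state: MetapopState,
    params: SimulationParams,
    weighted_f_patch: bool = False,
) -> tuple[MetapopState, CycleRecord]:
    """Advance one full life cycle: grow, pool, disperse, found.

    Runs the within-patch cycle on every patch, turns survivors into
    carriers via uptake, caps the pool at ``D``, assigns pooled hosts
    uniformly onto ``M`` brand-new patches, adds ``m`` host-independent
    migrant cells, and founds the next generation.  The returned record
    summarizes the cycle before founding.
    """
    rng = state.rng
    M = params.M
    Nf0 = np.array([p.Nf for p in state.patches], dtype=np.int64)
    Ns0 = np.array([p.Ns for p in state.patches], dtype=np.int64)
    H0v = np.array([p.H for p in state.patches], dtype=np.int64)
    Nf, Ns, H = run_patch_cycle_batch(
        Nf0, Ns0, H0v, params.tau, params.growth(), params.decay(), rng
    )
    grown = [
        PatchState(int(Nf[i]), int(Ns[i]), int(H[i]), t=params.tau) for i in range(M)
    ]

    # survivors mature and take up b cells by their patch's final proportions
    mature: list[dsp.HostCarrier] = []
    for i, p in enumerate(grown):
        for _ in range(p.H):
            if params.uptake == "hypergeometric":
                bf, bs = dsp.host_uptake_exact(p.Nf, p.Ns, params.b, rng)
            else:
                bf, bs = dsp.host_uptake(p.slow_fraction, params.b, rng)
            mature.append(dsp.HostCarrier(source_patch=i, bf=bf, bs=bs))

    pool = dsp.form_dispersal_pool(mature, params.D, rng)
    assignment = dsp.assign_hosts(pool, M, rng)
    migrants = dsp.host_independent_sample(grown, params.m, M, rng)
    new_patches = dsp.found_patches(
        assignment, migrants, M, params.H0, params.K, rng
    )

    carried = np.array([h.carried for h in pool], dtype=np.int64)
    carried_s = np.array([h.bs for h in pool], dtype=np.int64)
    with_microbes = carried > 0
    f_host = (
        float(np.mean(carried_s[with_microbes] / carried[with_microbes]))
        if np.any(with_microbes)
        else math.nan
    )
    record = CycleRecord(
        cycle=state.cycle,
        f_patch=_mean_slow_fraction(Nf, Ns, weighted=weighted_f_patch),
        f_host=f_host,
        occupied_patches=int(np.count_nonzero(Nf + Ns)),
        mature_hosts=len(mature),
        pool_size=len(pool),
        live_hosts_total=len(pool) * params.H0,
    )
    return MetapopState(new_patches, state.cycle + 1, rng), record


def run_cycles(
    state: MetapopState, params: SimulationParams, n_cycles: int
) -> tuple[MetapopState, list[CycleRecord]]:
    """Run a fixed number of synchronous cycles, collecting records."""
    records = []
    for _ in range(n_cycles):
        state, rec = synchronous_cycle(state, params)
        records.append(rec)
    return state, records


def _classify(state: MetapopState) -> str | None:
    """Terminal condition of the current state, or None if undecided.

    Evaluated at cycle boundaries, where all cells carried by in-transit
    hosts have already been deposited into the founded patches, so patch
    totals cover the whole metapopulation including carriers.
    """
    tot_f = sum(p.Nf for p in state.patches)
    tot_s = sum(p.Ns for p in state.patches)
    eggs = sum(p.H for p in state.patches)
    if tot_f + tot_s == 0:
        return MICROBES_EXTINCT
    if eggs == 0:
        return HOSTS_EXTINCT
    if tot_s == 0:
        return FAST_FIXED
    if tot_f == 0:
        return SLOW_FIXED
    return None


def run_until_fixation(
    params: SimulationParams,
    rng: np.random.Generator,
    invader: bool = True,
    collect_records: bool = False,
) -> FixationOutcome | tuple[FixationOutcome, list[CycleRecord]]:
    """Iterate cycles until one type fixes, a population dies, or the cap.

    Starts from :func:`initialize` (by default with a single slow invader
    cell).  Outcomes: ``slow_fixed`` / ``fast_fixed`` when the slow
    metapopulation frequency reaches 1 / 0 with microbes extant,
    ``microbes_extinct`` / ``hosts_extinct`` on extinctions, ``censored``
    when ``max_cycles`` is exhausted undecided.
    """
    state = initialize(params, invader=invader, rng=rng)
    records: list[CycleRecord] = []
    verdict = _classify(state)
    cycles = 0
    while verdict is None and cycles < params.max_cycles:
        state, rec = synchronous_cycle(state, params)
        cycles += 1
        if collect_records:
            records.append(rec)
        verdict = _classify(state)
    outcome = FixationOutcome(verdict if verdict is not None else CENSORED, cycles)
    return (outcome, records) if collect_records else outcome


def estimate_fixation_probability(
    params: SimulationParams,
    replicates: int,
    seed: int | np.random.SeedSequence,
    invader: bool = True,
    collect_records: bool = False,
) -> FixationEstimate | tuple[FixationEstimate, list[list[CycleRecord]]]:
    """Fraction of independent replicates ending in slow-type fixation.

    Replicate RNG streams are spawned from ``seed`` via
    ``numpy.random.SeedSequence``, so runs are reproducible and
    non-overlapping.  The Wilson 95% interval accompanies the estimate;
    censored replicates are reported but excluded from the numerator.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    fixed = censored = 0
    all_records: list[list[CycleRecord]] = []
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        res = run_until_fixation(
            params, rng, invader=invader, collect_records=collect_records
        )
        if collect_records:
            outcome, recs = res
            all_records.append(recs)
        else:
            outcome = res
        if outcome.outcome == SLOW_FIXED:
            fixed += 1
        elif outcome.outcome == CENSORED:
            censored += 1
    lo, hi = proportion_confint(fixed, replicates, alpha=0.05, method="wilson")
    est = FixationEstimate(
        estimate=fixed / replicates,
        ci_low=float(lo),
        ci_high=float(hi),
        replicates=replicates,
        fixed=fixed,
        censored=censored,
    )
    return (est, all_records) if collect_records else est


def independent_patches_experiment(
    founders: tuple[int, int],
    n_patches: int,
    initial_hosts: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Many uncoupled patches with identical founders; one cycle each.

    Returns ``(final_f, survivors)`` arrays over patches: the final slow
    fractions (NaN for sterile patches) and host survivor counts after one
    development period, for histogramming the variation that dispersal
    later acts upon.  No dispersal coupling between patches.
    """
    if n_patches < 1:
        raise ValueError(f"n_patches must be >= 1, got {n_patches}")
    Nf0, Ns0 = founders
    Nf, Ns, H = run_patch_cycle_batch(
        np.full(n_patches, Nf0, dtype=np.int64),
        np.full(n_patches, Ns0, dtype=np.int64),
        np.full(n_patches, initial_hosts, dtype=np.int64),
        params.tau,
        params.growth(),
        params.decay(),
        rng,
    )
    total = Nf + Ns
    final_f = np.where(total > 0, Ns / np.where(total > 0, total, 1), math.nan)
    return final_f, H


def asynchronous_run(
    params: SimulationParams,
    total_steps: int,
    rng: np.random.Generator,
    invader: bool = True,
    snapshot_every: int | None = None,
) -> list[AsyncSnapshot]:
    """Generalized engine: per-host development times and patch renewal.

    A single global clock drives all patches.  Each step: (1) one birth
    attempt and one mortality thinning per patch; (2) hosts whose
    development time (uniform on ``[tau - tau_d, tau + tau_d]``) has
    elapsed mature and sample ``b`` microbes from their patch; (3) a
    snapshot is recorded if due; (4) at renewal times, ``M0`` uniformly
    chosen patches are replaced by empty patches (their developing hosts
    are lost); (5) each matured host moves to a uniformly random patch,
    deposits its carried cells and lays ``H0`` eggs.  Renewal times are
    either periodic with period ``renewal_mean`` or geometric with that
    mean.  Hosts disperse individually on maturation; the pool cap ``D``
    plays no role here.  With ``tau_d = 0``, ``M0 = M`` and periodic
    renewal every ``tau`` steps this reduces to the synchronous model.
    """
    if total_steps < 0:
        raise ValueError(f"total_steps must be >= 0, got {total_steps}")
    if snapshot_every is None:
        snapshot_every = max(1, params.tau)
    M, K, b, H0 = params.M, params.K, params.b, params.H0
    g, d = params.growth(), params.decay()
    c = g.c
    logistic = g.kernel == "logistic"

    init = initialize(params, invader=invader, rng=rng)
    Nf = np.array([p.Nf for p in init.patches], dtype=np.int64)
    Ns = np.array([p.Ns for p in init.patches], dtype=np.int64)

    def draw_dev_times(n: int) -> np.ndarray:
        return rng.integers(
            params.tau - params.tau_d, params.tau + params.tau_d + 1, size=n
        )

    # flat arrays over live developing hosts
    host_patch = np.repeat(np.arange(M), H0)
    host_deadline = draw_dev_times(M * H0)

    period = params.effective_renewal_mean
    if params.renewal_schedule == GEOMETRIC:
        next_renewal = int(rng.geometric(1.0 / period))
    else:
        next_renewal = period

    snapshots: list[AsyncSnapshot] = []
    window_disp_f: list[float] = []
    window_disp_count = 0

    for t in range(1, total_steps + 1):
        # (1) growth then mortality at post-birth abundances
        total = Nf + Ns
        w = Nf + (1.0 - c) * Ns
        growable = (total > 0) & (total < K) & (w > 0.0)
        if logistic:
            growable &= rng.random(M) < (1.0 - total / K)
        ps = np.divide((1.0 - c) * Ns, w, out=np.zeros(M), where=w > 0.0)
        slow = growable & (rng.random(M) < ps)
        Ns += slow
        Nf += growable & ~slow
        delta = d.delta_K * (Nf + d.delta_s * Ns) / K
        if host_patch.size:
            survive = rng.random(host_patch.size) >= delta[host_patch]
            host_patch = host_patch[survive]
            host_deadline = host_deadline[survive]

        # (2) maturation and uptake from the current patch composition
        due = host_deadline <= t
        mature_src = host_patch[due]
        host_patch = host_patch[~due]
        host_deadline = host_deadline[~due]
        n_mat = mature_src.size
        if n_mat:
            tot_src = (Nf + Ns)[mature_src]
            f_src = np.divide(
                Ns[mature_src].astype(float),
                tot_src,
                out=np.zeros(n_mat),
                where=tot_src > 0,
            )
            bs = np.where(tot_src > 0, rng.binomial(b, f_src), 0)
            bf = np.where(tot_src > 0, b - bs, 0)
            carried = bf + bs
            has = carried > 0
            if np.any(has):
                window_disp_f.extend((bs[has] / carried[has]).tolist())
            window_disp_count += n_mat

        # (3) snapshot before renewal, matching the synchronous record point
        if t % snapshot_every == 0:
            f_host = float(np.mean(window_disp_f)) if window_disp_f else math.nan
            snapshots.append(
                AsyncSnapshot(
                    t=t,
                    f_patch=_mean_slow_fraction(Nf, Ns),
                    f_host=f_host,
                    occupied_patches=int(np.count_nonzero(Nf + Ns)),
                    live_hosts_total=int(host_patch.size) + n_mat,
                    dispersed_hosts=window_disp_count,
                )
            )
            window_disp_f = []
            window_disp_count = 0

        # (4) renewal wipes M0 random patches and their developing hosts
        if t == next_renewal:
            m0 = params.effective_M0
            wiped = rng.choice(M, size=m0, replace=False)
            Nf[wiped] = 0
            Ns[wiped] = 0
            if host_patch.size:
                keep = ~np.isin(host_patch, wiped)
                host_patch = host_patch[keep]
                host_deadline = host_deadline[keep]
            if params.renewal_schedule == GEOMETRIC:
                next_renewal = t + int(rng.geometric(1.0 / period))
            else:
                next_renewal = t + period

        # (5) matured hosts disperse individually and lay H0 eggs
        if n_mat:
            dest = rng.integers(0, M, size=n_mat)
            np.add.at(Nf, dest, bf)
            np.add.at(Ns, dest, bs)
            over = Nf + Ns > K  # overflow guard, b << K in practice
            for i in np.nonzero(over)[0]:
                ns_kept = int(rng.hypergeometric(Ns[i], Nf[i], K))
                Ns[i] = ns_kept
                Nf[i] = K - ns_kept
            host_patch = np.concatenate([host_patch, np.repeat(dest, H0)])
            host_deadline = np.concatenate(
                [host_deadline, t + draw_dev_times(n_mat * H0)]
            )

    return snapshots
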