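"""Within-patch stochastic dynamics: microbial growth and host mortality.

A patch (e.g. a rotting fruit) hosts a two-type microbial population — a
fast-growing type and a slow-growing type whose per-capita birth rate is
reduced by a factor ``1 - c`` — together with a cohort of developing hosts.
Microbes grow by a discrete-time pure-birth (urn) process capped at the
patch carrying capacity ``K``; each time step one individual is chosen to
reproduce with probability proportional to its growth rate.  Microbial load
degrades the patch: every live host dies in a given step with probability

    delta = delta_K * (Nf + delta_s * Ns) / K

so a patch fully occupied by the fast type kills hosts at the maximal rate
``delta_K`` while the slow type's contribution is discounted by ``delta_s``.
Patch quality is the rescaling ``rho = 1 - delta / delta_K``.

All stochastic operations take an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PURE_BIRTH",
    "LOGISTIC",
    "GrowthParams",
    "DecayParams",
    "PatchState",
    "PatchCycleResult",
    "birth_probabilities",
    "growth_step",
    "host_decay_probability",
    "patch_quality",
    "host_decay_step",
    "run_patch_cycle",
    "run_patch_cycle_batch",
    "sample_final_compositions",
    "expected_host_survival",
    "exact_final_composition_distribution",
]

PURE_BIRTH = "pure_birth"
LOGISTIC = "logistic"


@dataclass(frozen=True)
class GrowthParams:
    """Microbial growth parameters.

    Parameters
    ----------
    c
        Fitness cost of the slow type, ``0 <= c <= 1``.  The slow type's
        birth weight is ``1 - c`` per cell.
    K
        Patch carrying capacity (cells); growth stops once reached.
    kernel
        ``"pure_birth"`` (one birth per step below capacity) or
        ``"logistic"`` (the birth attempt additionally succeeds only with
        probability ``1 - N/K``, a density-dependent slowdown).
    """

    c: float
    K: int
    kernel: str = PURE_BIRTH

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"fitness cost c must be in [0, 1], got {self.c}")
        if self.K < 1:
            raise ValueError(f"carrying capacity K must be >= 1, got {self.K}")
        if self.kernel not in (PURE_BIRTH, LOGISTIC):
            raise ValueError(f"unknown growth kernel {self.kernel!r}")


@dataclass(frozen=True)
class DecayParams:
    """Host-mortality (patch decay) parameters.

    ``delta_K`` is the per-step host death probability in a patch fully
    occupied by the fast type; ``delta_s`` discounts the slow type's
    contribution to decay.  Both lie in [0, 1].
    """

    delta_K: float
    delta_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_K <= 1.0:
            raise ValueError(f"delta_K must be in [0, 1], got {self.delta_K}")
        if not 0.0 <= self.delta_s <= 1.0:
            raise ValueError(f"delta_s must be in [0, 1], got {self.delta_s}")


@dataclass
class PatchState:
    """Microbial counts and live developing hosts of a single patch."""

    Nf: int
    Ns: int
    H: int
    t: int = 0

    def __post_init__(self) -> None:
        if self.Nf < 0 or self.Ns < 0:
            raise ValueError(f"negative microbial counts ({self.Nf}, {self.Ns})")
        if self.H < 0:
            raise ValueError(f"negative host count {self.H}")

    @property
    def total(self) -> int:
        return self.Nf + self.Ns

    @property
    def slow_fraction(self) -> float:
        """Relative abundance of the slow type, NaN for a sterile patch.

        The NaN sentinel keeps sterile patches out of averages (use
        ``numpy.nanmean``); a sterile patch has no composition, not a
        slow fraction of zero.
        """
        n = self.total
        return self.Ns / n if n > 0 else math.nan


@dataclass
class PatchCycleResult:
    """Outcome of one within-patch growth/decay cycle."""

    final_state: PatchState
    survivors: int
    initial_hosts: int

    def __post_init__(self) -> None:
        if not 0 <= self.survivors <= self.initial_hosts:
            raise ValueError("survivors must lie in [0, initial_hosts]")


def birth_probabilities(Nf: int, Ns: int, params: GrowthParams) -> tuple[float, float]:
    """Per-step probabilities that the fast / slow count increases by one.

    Below capacity, ``Pf = Nf / (Nf + (1-c) Ns)`` and
    ``Ps = (1-c) Ns / (Nf + (1-c) Ns)``; at or above capacity, and in an
    empty patch, both are zero.  With ``c = 1`` and only slow cells present
    no reproduction is possible and both are zero as well.
    """
    if Nf < 0 or Ns < 0:
        raise ValueError(f"negative microbial counts ({Nf}, {Ns})")
    total = Nf + Ns
    if total == 0 or total >= params.K:
        return 0.0, 0.0
    w = Nf + (1.0 - params.c) * Ns
    if w == 0.0:
        return 0.0, 0.0
    return Nf / w, (1.0 - params.c) * Ns / w


def growth_step(
    state: PatchState, params: GrowthParams, rng: np.random.Generator
) -> PatchState:
    """One microbial birth attempt; returns the post-attempt state.

    Pure-birth kernel: exactly one of ``Nf``, ``Ns`` is incremented when
    the patch is below capacity and non-empty.  Logistic kernel: the birth
    additionally occurs only with acceptance probability ``1 - N/K``.
    Host count and elapsed time are untouched.
    """
    pf, ps = birth_probabilities(state.Nf, state.Ns, params)
    if pf + ps == 0.0:
        return PatchState(state.Nf, state.Ns, state.H, state.t)
    if params.kernel == LOGISTIC:
        if rng.random() >= 1.0 - state.total / params.K:
            return PatchState(state.Nf, state.Ns, state.H, state.t)
    if rng.random() < ps:
        return PatchState(state.Nf, state.Ns + 1, state.H, state.t)
    return PatchState(state.Nf + 1, state.Ns, state.H, state.t)


def host_decay_probability(Nf: int, Ns: int, d: DecayParams, K: int) -> float:
    """Per-step host death probability ``delta_K (Nf + delta_s Ns) / K``."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if Nf < 0 or Ns < 0:
        raise ValueError(f"negative microbial counts ({Nf}, {Ns})")
    if Nf + Ns > K:
        raise ValueError(f"microbial load {Nf + Ns} exceeds capacity {K}")
    return d.delta_K * (Nf + d.delta_s * Ns) / K


def patch_quality(delta: float, d: DecayParams) -> float:
    """Patch quality ``rho = 1 - delta / delta_K``.

    An empty patch (``delta = 0``) has maximal quality 1; a patch fully
    occupied by the fast type has quality 0.  When ``delta_K = 0`` hosts
    never decay and quality is defined as 1.
    """
    if d.delta_K == 0.0:
        if delta != 0.0:
            raise ValueError("delta must be 0 when delta_K is 0")
        return 1.0
    if not 0.0 <= delta <= d.delta_K + 1e-12:
        raise ValueError(f"delta {delta} outside [0, delta_K={d.delta_K}]")
    return 1.0 - delta / d.delta_K


def host_decay_step(H: int, delta: float, rng: np.random.Generator) -> int:
    """Number of host deaths this step, drawn Binomial(H, delta)."""
    if H < 0:
        raise ValueError(f"negative host count {H}")
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be a probability, got {delta}")
    if H == 0:
        return 0
    return int(rng.binomial(H, delta))


def run_patch_cycle_batch(
    Nf0: np.ndarray,
    Ns0: np.ndarray,
    H0: np.ndarray,
    tau: int,
    g: GrowthParams,
    d: DecayParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance many independent patches in lockstep for ``tau`` steps.

    Each step performs one birth attempt per patch, then one binomial
    host-mortality draw at the post-birth abundances.  Returns the final
    ``(Nf, Ns, H)`` arrays.  This is the vectorized engine behind
    :func:`run_patch_cycle` and the metapopulation simulators; all patches
    share the parameter set but evolve independently.
    """
    Nf = np.asarray(Nf0, dtype=np.int64).copy()
    Ns = np.asarray(Ns0, dtype=np.int64).copy()
    H = np.asarray(H0, dtype=np.int64).copy()
    if Nf.shape != Ns.shape or Nf.shape != H.shape:
        raise ValueError("Nf0, Ns0 and H0 must have identical shapes")
    if np.any(Nf < 0) or np.any(Ns < 0) or np.any(H < 0):
        raise ValueError("negative counts in batch input")
    if np.any(Nf + Ns > g.K):
        raise ValueError("initial microbial load exceeds capacity")
    n = Nf.shape[0]
    c = g.c
    K = g.K
    logistic = g.kernel == LOGISTIC
    for _ in range(tau):
        total = Nf + Ns
        w = Nf + (1.0 - c) * Ns
        growable = (total > 0) & (total < K) & (w > 0.0)
        if logistic:
            growable &= rng.random(n) < (1.0 - total / K)
        ps = np.divide((1.0 - c) * Ns, w, out=np.zeros(n), where=w > 0.0)
        slow = growable & (rng.random(n) < ps)
        fast = growable & ~slow
        Ns += slow
        Nf += fast
        delta = d.delta_K * (Nf + d.delta_s * Ns) / K
        H -= rng.binomial(H, delta)
    return Nf, Ns, H


def run_patch_cycle(
    founders: tuple[int, int],
    initial_hosts: int,
    tau: int,
    g: GrowthParams,
    d: DecayParams,
    rng: np.random.Generator,
) -> PatchCycleResult:
    """Run one full within-patch cycle of ``tau`` growth/decay steps.

    ``founders = (Nf0, Ns0)`` seeds the microbial population;
    ``initial_hosts`` developing hosts are exposed to the load-dependent
    mortality.  Growth attempts continue (as no-ops) after capacity is
    reached, and host mortality continues at capacity.
    """
    Nf0, Ns0 = founders
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    Nf, Ns, H = run_patch_cycle_batch(
        np.array([Nf0]), np.array([Ns0]), np.array([initial_hosts]), tau, g, d, rng
    )
    final = PatchState(int(Nf[0]), int(Ns[0]), int(H[0]), t=tau)
    return PatchCycleResult(final, survivors=int(H[0]), initial_hosts=initial_hosts)


def sample_final_compositions(
    Nf0: int,
    Ns0: int,
    g: GrowthParams,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n`` pure-birth trajectories to capacity; return Ns at K.

    Only meaningful for the pure-birth kernel, where capacity is reached in
    exactly ``K - Nf0 - Ns0`` steps.  Used to cross-check the exact
    dynamic-programming distribution.
    """
    if Nf0 + Ns0 < 1:
        raise ValueError("at least one founder cell required")
    steps = g.K - (Nf0 + Ns0)
    Nf, Ns, _ = run_patch_cycle_batch(
        np.full(n, Nf0),
        np.full(n, Ns0),
        np.zeros(n, dtype=np.int64),
        steps,
        g,
        DecayParams(0.0, 0.0),
        rng,
    )
    return Ns


def expected_host_survival(
    founders: tuple[int, int],
    tau: int,
    g: GrowthParams,
    d: DecayParams,
) -> float:
    """Deterministic approximation of a host's survival probability S(tau).

    Propagates the expected microbial trajectory — one expected birth per
    step, split fractionally by the birth probabilities (scaled by the
    logistic acceptance factor for that kernel), capped at K — and returns
    ``S = prod_t (1 - delta(t))`` with delta evaluated on the post-birth
    expected abundances.  Deterministic, in [0, 1] and non-increasing in
    ``tau``; a numerical companion to the stochastic cycle, not an exact
    marginal.
    """
    nf, ns = float(founders[0]), float(founders[1])
    c, K = g.c, g.K
    logistic = g.kernel == LOGISTIC
    S = 1.0
    for _ in range(tau):
        total = nf + ns
        if 0.0 < total < K:
            w = nf + (1.0 - c) * ns
            if w > 0.0:
                inc = min(1.0, K - total)
                if logistic:
                    inc *= 1.0 - total / K
                nf += inc * nf / w
                ns += inc * (1.0 - c) * ns / w
        delta = d.delta_K * (nf + d.delta_s * ns) / K
        S *= 1.0 - delta
    return S


_MAX_EXACT_K = 200


def exact_final_composition_distribution(
    Nf0: int,
    Ns0: int,
    g: GrowthParams,
) -> dict[tuple[int, int], float]:
    """Exact distribution over final compositions of the pure-birth process.

    Forward dynamic-programming recursion on ``(Nf, Ns)``: each layer of
    total abundance distributes its mass according to
    :func:`birth_probabilities` until the capacity ``K`` is reached.
    Returns a dict mapping absorbing compositions ``(Nf, Ns)`` to their
    probabilities (mass that can never advance, e.g. pure-slow with
    ``c = 1``, is reported at its stuck composition).  Intended as a small-K
    testing oracle; refuses ``K > 200``.
    """
    if g.K > _MAX_EXACT_K:
        raise ValueError(
            f"exact enumeration supported only for K <= {_MAX_EXACT_K}, got K={g.K}"
        )
    if g.kernel != PURE_BIRTH:
        raise ValueError("exact enumeration is defined for the pure_birth kernel")
    if Nf0 < 0 or Ns0 < 0 or Nf0 + Ns0 < 1:
        raise ValueError("founders must be non-negative with at least one cell")
    if Nf0 + Ns0 > g.K:
        raise ValueError("founders exceed capacity")

    final: dict[tuple[int, int], float] = {}
    layer: dict[tuple[int, int], float] = {(Nf0, Ns0): 1.0}
    for _total in range(Nf0 + Ns0, g.K):
        nxt: dict[tuple[int, int], float] = {}
        for (nf, ns), p in layer.items():
            pf, psl = birth_probabilities(nf, ns, g)
            if pf + psl == 0.0:  # stuck below capacity (c = 1, no fast cells)
                final[(nf, ns)] = final.get((nf, ns), 0.0) + p
                continue
            if pf > 0.0:
                nxt[(nf + 1, ns)] = nxt.get((nf + 1, ns), 0.0) + p * pf
            if psl > 0.0:
                nxt[(nf, ns + 1)] = nxt.get((nf, ns + 1), 0.0) + p * psl
        layer = nxt
    for state, p in layer.items():
        final[state] = final.get(state, 0.0) + p
    return final
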