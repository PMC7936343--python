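"""Between-cycle dispersal: microbial uptake, the host pool, and founding.

Surviving hosts leave their natal patch carrying a small sample of ``b``
microbial cells drawn by the source patch's type proportions (the dispersal
bottleneck).  A maximum of ``D`` hosts enters a common dispersal pool and is
assigned uniformly at random to fresh patches, where each host lays ``H0``
eggs and its carried cells found the new microbial population.  Optionally
``m`` microbial cells disperse independently of hosts, sampled from the
pooled metapopulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .patch_dynamics import PatchState

__all__ = [
    "HostCarrier",
    "host_uptake",
    "host_uptake_exact",
    "form_dispersal_pool",
    "assign_hosts",
    "host_independent_sample",
    "relative_independent_dispersal",
    "found_patches",
]


@dataclass(frozen=True)
class HostCarrier:
    """A mature host and the microbial sample it carries.

    Hosts from a sterile source patch carry nothing (``bf = bs = 0``);
    hosts from a colonized patch carry exactly ``b`` cells.
    """

    source_patch: int
    bf: int
    bs: int

    def __post_init__(self) -> None:
        if self.bf < 0 or self.bs < 0:
            raise ValueError("carried cell counts must be non-negative")

    @property
    def carried(self) -> int:
        return self.bf + self.bs

    @property
    def slow_fraction(self) -> float:
        """Slow fraction of the carried sample; NaN for a microbe-free host."""
        n = self.carried
        return self.bs / n if n > 0 else math.nan


def host_uptake(
    source_f: float, b: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Sample the ``(bf, bs)`` cells a host takes up from its source patch.

    Uptake is modeled on the type *proportions* of the source patch (valid
    for b << K): the slow count is Binomial(b, source_f).  A sterile source
    (``source_f`` NaN) yields ``(0, 0)``.
    """
    if b < 0:
        raise ValueError(f"sample size b must be >= 0, got {b}")
    if source_f is None or math.isnan(source_f):
        return 0, 0
    if not 0.0 <= source_f <= 1.0:
        raise ValueError(f"source slow fraction must be in [0, 1], got {source_f}")
    bs = int(rng.binomial(b, source_f)) if b > 0 else 0
    return b - bs, bs


def host_uptake_exact(
    Nf: int, Ns: int, b: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Hypergeometric uptake without replacement on absolute counts.

    Exact alternative to :func:`host_uptake` for tiny patches where the
    finite-population correction matters; takes the whole population when
    ``b`` exceeds it.  Sterile source yields ``(0, 0)``.
    """
    if Nf < 0 or Ns < 0:
        raise ValueError(f"negative microbial counts ({Nf}, {Ns})")
    total = Nf + Ns
    if total == 0 or b == 0:
        return 0, 0
    k = min(b, total)
    bs = int(rng.hypergeometric(Ns, Nf, k))
    return k - bs, bs


def form_dispersal_pool(
    mature_hosts: list[HostCarrier], D: int, rng: np.random.Generator
) -> list[HostCarrier]:
    """Uniformly subsample at most ``D`` hosts into the dispersal pool.

    When the number of mature hosts does not exceed the cap, all of them
    disperse (no padding); otherwise a uniform sample of size ``D`` without
    replacement is taken, blind to carried composition and source patch.
    """
    if D < 0:
        raise ValueError(f"pool cap D must be >= 0, got {D}")
    if len(mature_hosts) <= D:
        return list(mature_hosts)
    idx = rng.choice(len(mature_hosts), size=D, replace=False)
    return [mature_hosts[i] for i in idx]


def assign_hosts(
    pool: list[HostCarrier], M: int, rng: np.random.Generator
) -> dict[int, list[HostCarrier]]:
    """Assign each pooled host independently and uniformly to one of M patches.

    Several hosts may land on the same patch and patches may stay
    uncolonized.  Returns a mapping patch index -> assigned hosts (patches
    receiving no host are absent from the mapping).
    """
    if M < 1:
        raise ValueError(f"patch count M must be >= 1, got {M}")
    assignment: dict[int, list[HostCarrier]] = {}
    if not pool:
        return assignment
    targets = rng.integers(0, M, size=len(pool))
    for host, patch in zip(pool, targets):
        assignment.setdefault(int(patch), []).append(host)
    return assignment


def host_independent_sample(
    patches: list[PatchState], m: int, M: int, rng: np.random.Generator
) -> list[tuple[int, bool]]:
    """Disperse ``m`` microbial cells without hosts.

    Each cell is slow with probability equal to the abundance-weighted slow
    fraction pooled over all source patches, then assigned uniformly to one
    of the ``M`` destination patches.  Returns ``(patch, is_slow)`` tuples;
    an entirely sterile source metapopulation disperses nothing.
    """
    if m < 0:
        raise ValueError(f"migrant count m must be >= 0, got {m}")
    if M < 1:
        raise ValueError(f"patch count M must be >= 1, got {M}")
    if m == 0:
        return []
    tot_f = sum(p.Nf for p in patches)
    tot_s = sum(p.Ns for p in patches)
    total = tot_f + tot_s
    if total == 0:
        return []
    f_meta = tot_s / total
    slow = rng.random(m) < f_meta
    targets = rng.integers(0, M, size=m)
    return [(int(t), bool(s)) for t, s in zip(targets, slow)]


def relative_independent_dispersal(m: int, b: int, D: int) -> float:
    """Host-independent dispersal relative to the maximal host-carried flux.

    ``p = m / (b * D)``: the number of free-dispersing cells normalized by
    the most cells that could travel inside hosts in one dispersal event.
    """
    if b * D <= 0:
        raise ValueError(f"b * D must be positive, got b={b}, D={D}")
    return m / (b * D)


def found_patches(
    assignment: dict[int, list[HostCarrier]],
    migrants: list[tuple[int, bool]],
    M: int,
    H0: int,
    K: int,
    rng: np.random.Generator,
) -> list[PatchState]:
    """Found M fresh patches from assigned hosts and free migrants.

    Each patch's founder population is the sum of its hosts' carried cells
    plus its migrant cells; each assigned host lays ``H0`` eggs.  Patches
    with no hosts receive no eggs but may still receive migrants.  Founder
    totals exceeding ``K`` (possible only for large ``n*b`` or ``m``) are
    subsampled uniformly without replacement down to ``K``, preserving
    composition in expectation.
    """
    if H0 < 0:
        raise ValueError(f"clutch size H0 must be >= 0, got {H0}")
    if K < 1:
        raise ValueError(f"capacity K must be >= 1, got {K}")
    founders_f = np.zeros(M, dtype=np.int64)
    founders_s = np.zeros(M, dtype=np.int64)
    n_hosts = np.zeros(M, dtype=np.int64)
    for patch, hosts in assignment.items():
        if not 0 <= patch < M:
            raise ValueError(f"assignment references patch {patch} outside 0..{M-1}")
        n_hosts[patch] = len(hosts)
        founders_f[patch] = sum(h.bf for h in hosts)
        founders_s[patch] = sum(h.bs for h in hosts)
    for patch, is_slow in migrants:
        if not 0 <= patch < M:
            raise ValueError(f"migrant references patch {patch} outside 0..{M-1}")
        if is_slow:
            founders_s[patch] += 1
        else:
            founders_f[patch] += 1
    patches = []
    for i in range(M):
        nf, ns = int(founders_f[i]), int(founders_s[i])
        if nf + ns > K:  # overflow guard; composition preserved in expectation
            ns = int(rng.hypergeometric(ns, nf, K))
            nf = K - ns
        patches.append(PatchState(Nf=nf, Ns=ns, H=int(n_hosts[i]) * H0, t=0))
    return patches
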