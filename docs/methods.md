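# Model and methods

`hostpatch` simulates the joint life cycles of a two-type microbial
population and an animal host on a landscape of ephemeral habitat patches,
to study how a slow-growing microbe can become enriched in dispersing hosts
without providing any direct benefit to them.

## Within-patch dynamics

Each patch holds `Nf` fast-type and `Ns` slow-type microbial cells, capped
at the carrying capacity `K`, and a cohort of `H` live developing hosts.
Time is discrete. Each step:

1. **One birth attempt.** Below capacity, one of the two counts increases
   by one with probabilities

       P(Nf -> Nf+1) = Nf / (Nf + (1-c) Ns)
       P(Ns -> Ns+1) = (1-c) Ns / (Nf + (1-c) Ns)

   and both probabilities are zero at or above `K` (growth simply stops; a
   pure-birth urn process without death). The fitness cost `c ∈ [0, 1]`
   discounts the slow type's birth weight. An optional *logistic* kernel
   accepts the birth attempt only with probability `1 − (Nf+Ns)/K`, the
   standard stochastic analogue of logistic slowing; it changes the
   approach to capacity but not the qualitative results.
2. **Host mortality at the post-birth abundances.** Every live host dies
   with probability

       delta = delta_K (Nf + delta_s Ns) / K

   and the number of deaths is drawn Binomial(H, delta). `delta_K` is the
   per-step death probability in a patch fully occupied by the fast type;
   `delta_s ∈ [0, 1]` discounts the slow type's contribution to patch
   decay. Patch quality is the rescaling `rho = 1 − delta/delta_K` (defined
   as 1 when `delta_K = 0`): 1 for a sterile patch, 0 at full fast
   occupancy, `(1 − delta_s) Ns/K` at full occupancy generally.

The interleaving (birth first, then mortality at the updated abundances) is
a deliberate choice where the event order within a step is otherwise open;
it makes mortality reflect the current load. At the default scales the
capacity cap never binds within one development period (`N0 + tau << K`),
so the choice is immaterial there.

`expected_host_survival` propagates the *expected* trajectory (one expected
birth per step, split fractionally, capped at `K`) and returns
`S(tau) = prod_t (1 − delta(t))`. For founder populations containing a
single type the growth path is deterministic and this is exact; for mixed
founders it is a deterministic companion curve, not the exact marginal, and
tests compare it to simulation only in the deterministic-path case.

`exact_final_composition_distribution` is an exact forward recursion over
`(Nf, Ns)` used as a testing oracle for small `K` (refused above `K = 200`).
With `c = 0` it reproduces the classical Pólya-urn result (final counts
uniform given one founder of each type), which the test suite asserts, and
the simulated process is checked against it by chi-squared at `K = 20`.

## Dispersal

After `tau` steps the surviving hosts mature. Each takes up `b` cells
sampled by its patch's final type *proportions* (slow count
Binomial(b, f)); hosts from sterile patches carry nothing but still
reproduce. Binomial-on-proportions is appropriate for `b << K`; an exact
hypergeometric variant (`host_uptake_exact`) exists for tiny populations.
At most `D` uniformly chosen hosts enter a common dispersal pool
(no stratification by patch); each pooled host is then assigned
independently and uniformly to one of `M` brand-new patches, lays `H0`
eggs there, and its carried cells found the new microbial population.
Optionally `m` cells disperse host-independently: each is slow with
probability equal to the abundance-weighted slow fraction of the whole
source metapopulation and lands on a uniform patch. The scale-free ratio
`p = m/(bD)` compares this flux to the maximal host-carried flux. If a
founding population would exceed `K` (never at default scales), it is
subsampled without replacement down to `K`.

Selection on the slow type emerges *only* through survivor counts: patches
richer in the slow type decay more slowly, contribute more hosts to the
pool, and those hosts carry their source composition. Conditioning on equal
survivor counts, the pool mirrors the patches (asserted as a neutrality
control).

## Engines

**Synchronous engine.** Cycles of `tau` growth/decay steps alternate with a
dispersal phase; every cycle yields a `CycleRecord` with the mean slow
fraction over occupied patches (`f_patch`, unweighted by default, with a
cell-weighted option since the averaging convention is a free choice) and
over pooled microbe-carrying hosts (`f_host`). Sterile patches and
microbe-free hosts are excluded from these means via NaN sentinels, never
counted as zero. Fixation runs start from a single slow invader cell (one
founder cell of one colonized patch converted to slow) and stop when the
metapopulation slow fraction hits 0 or 1, microbes or hosts go extinct, or
`max_cycles` (default 2000) is reached; capped runs are reported as
*censored* and excluded from fixation numerators. Because termination is
checked at cycle boundaries — after carried cells are deposited — cells in
transit can never trigger a false extinction call.

**Asynchronous engine.** A single global clock; each host draws an integer
development time uniform on `[tau − tau_d, tau + tau_d]`, matures
individually, samples its patch, immediately disperses to a uniform patch
and lays `H0` eggs. Renewal events replace `M0` uniformly chosen patches
(microbes and developing hosts) with empty patches, at either geometric
inter-event times with mean `renewal_mean` or a fixed period. There is no
dispersal pool in this engine; `D` is ignored. With `tau_d = 0`, `M0 = M`
and periodic renewal every `tau` steps the engine is distributionally
identical to the synchronous model (verified by a two-sample KS test with
the pool cap set above the host count so that it cannot bind). Note that
patch decay is the model's *only* regulation of host numbers: in a
microbe-free world hosts multiply by `H0` per generation without bound, so
decay-free configurations should use small clutches.

## Parameters

| name | meaning | default |
|------|---------|---------|
| `M` | patches in the landscape | 50 |
| `K` | patch carrying capacity (cells) | 10^4 |
| `D` | dispersal pool cap (hosts) | 100 |
| `c` | slow-type fitness cost | 0.15 |
| `H0` | eggs per dispersing host | 100 |
| `b` | cells carried per host (bottleneck) | 5 |
| `tau` | host development time (steps) | 10^3 |
| `delta_K` | maximal per-step host death probability | 0.1 |
| `delta_s` | slow-type decay discount | 0.1 |
| `N0` | founder cells per colonized patch | 5 |
| `m` | host-independent migrant cells per cycle | 0 |
| `colonized_fraction` | initially colonized patches | 1.0 |
| `tau_d` | development-time half-width (async) | 0 |
| `M0` | patches replaced per renewal (async) | `M` |
| `renewal_mean` | mean steps between renewals (async) | `tau` |
| `max_cycles` | censoring cap for fixation runs | 2000 |

The defaults are the standard set used for all experiments unless a preset
overrides them. Replicate counts are user-set; desk-scale defaults (a few
hundred) are far below the 10^4 used for publication-quality sweeps, so
confidence intervals are correspondingly wider.

## Desk-scale presets and what they show

Tests and the acceptance checks run a scaled landscape, chosen once:
`M = 20, K = 10^3, tau = 200` with defaults otherwise. At this scale a
cycle costs a few milliseconds and full sweeps finish in minutes. The
scaling preserves the qualitative regime — growth far from capacity within
one cycle, an effective dispersal bottleneck, decay strong enough to
differentiate patch compositions — but not every dimensionless quantity:
the cumulative decay load of a colonizing patch,
`sum_t delta(t) ≈ delta_K tau^2 / (2K)`, is ~2.1 here versus ~5.1 at full
scale, so hosts in colonized patches survive more often (S ≈ 0.12 vs
≈ 0.006). For the mostly-sterile scenario — where the claim under test
(microbial collapse within a few cycles) depends precisely on colonized
patches being terrible for hosts relative to sterile ones — the preset
instead uses `tau = 300` at `K = 10^3`, which restores the full-scale
survival regime (S ≈ 0.009). This regime-matching rule is the package's
scaling convention for that scenario.

What passing at desk scale shows: the mechanism (survivor-count-mediated
enrichment of the slow type, its modulation by `b`, `c`, `D`, `m`) operates
as described, with the correct neutral limits and an exactly verified
growth kernel. What it does not show: quantitative fixation probabilities
at the publication parameter set, which require the full `K = 10^4`,
`tau = 10^3`, 10^4-replicate runs.

## Numerical and statistical choices

- All randomness flows through explicit `numpy.random.Generator` handles.
  Replicate streams are spawned via `SeedSequence`; sweep grid points log a
  31-bit derived seed (`SeedSequence([master, index])`, truncated) from
  which every replicate of that row can be reconstructed.
- Fixation estimates carry Wilson 95% intervals; censored replicates are
  reported, never silently dropped or counted.
- Mortality is drawn per step as Binomial(H, delta); survivor counts over a
  cycle are therefore exact sequential thinnings, not a one-shot
  approximation.
- Degenerate inputs: empty patches neither grow nor decay; `tau = 0` cycles
  are identities; `c = 1` with no fast cells present leaves the population
  stuck (birth probabilities are 0/0-free by construction); `delta_K = 0`
  defines `rho = 1`.

## Known limitations

- Two microbial types only; no within-patch microbial death or dormancy;
  no evolution of `c`, `b` or `tau` within a run.
- Hosts have no patch or microbe preference and no mortality in transit.
- The asynchronous engine lacks any dispersal pool semantics, and host
  numbers are unregulated when decay is absent (see above).
- `expected_host_survival` is a deterministic companion, exact only for
  single-type founder populations.
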