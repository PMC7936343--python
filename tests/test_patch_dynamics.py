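"""Within-patch growth, decay and the exact enumeration oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from hostpatch import (
    DecayParams,
    GrowthParams,
    PatchState,
    birth_probabilities,
    exact_final_composition_distribution,
    expected_host_survival,
    growth_step,
    host_decay_probability,
    host_decay_step,
    patch_quality,
    run_patch_cycle,
    run_patch_cycle_batch,
    sample_final_compositions,
)


class TestBirthProbabilities:
    @pytest.mark.parametrize(
        "Nf, Ns, c, K, expected",
        [
            (1, 1, 0.0, 100, (0.5, 0.5)),
            (4, 1, 0.15, 10_000, (4 / 4.85, 0.85 / 4.85)),
            (50, 50, 0.3, 100, (0.0, 0.0)),  # at capacity growth stops
            (0, 0, 0.15, 100, (0.0, 0.0)),  # empty patch cannot grow
            (0, 3, 1.0, 100, (0.0, 0.0)),  # c=1: pure-slow patch is stuck
        ],
    )
    def test_values(self, Nf, Ns, c, K, expected):
        pf, ps = birth_probabilities(Nf, Ns, GrowthParams(c=c, K=K))
        assert pf == pytest.approx(expected[0], abs=1e-12)
        assert ps == pytest.approx(expected[1], abs=1e-12)

    def test_normalization_below_capacity(self):
        g = GrowthParams(c=0.4, K=50)
        for nf, ns in [(1, 0), (0, 1), (7, 3), (20, 29)]:
            pf, ps = birth_probabilities(nf, ns, g)
            assert pf + ps == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            birth_probabilities(-1, 2, GrowthParams(c=0.1, K=10))


class TestGrowthStep:
    def test_at_capacity_unchanged(self, rng):
        g = GrowthParams(c=0.15, K=10)
        state = PatchState(Nf=10, Ns=0, H=3)
        out = growth_step(state, g, rng)
        assert (out.Nf, out.Ns) == (10, 0)

    def test_single_type_self_amplifies(self, rng):
        g = GrowthParams(c=0.15, K=10)
        out = growth_step(PatchState(Nf=0, Ns=3, H=0), g, rng)
        assert (out.Nf, out.Ns) == (0, 4)

    def test_slow_birth_fraction_matches_probabilities(self, rng):
        # Monte-Carlo check of the urn step against the closed form
        g = GrowthParams(c=0.15, K=10_000)
        n = 20_000
        ps = birth_probabilities(4, 1, g)[1]
        slow = sum(
            growth_step(PatchState(4, 1, 0), g, rng).Ns == 2 for _ in range(n)
        )
        se = math.sqrt(ps * (1 - ps) / n)
        assert abs(slow / n - ps) < 3 * se

    def test_logistic_kernel_slows_growth(self, rng):
        # near capacity the logistic acceptance probability is small
        g = GrowthParams(c=0.0, K=100, kernel="logistic")
        grown = sum(
            growth_step(PatchState(90, 0, 0), g, rng).Nf == 91 for _ in range(2000)
        )
        p = grown / 2000
        assert abs(p - 0.1) < 3 * math.sqrt(0.1 * 0.9 / 2000)


class TestDecayAndQuality:
    def test_full_fast_occupancy_gives_delta_K(self, standard_decay):
        assert host_decay_probability(10_000, 0, standard_decay, 10_000) == 0.1

    def test_empty_patch_no_decay(self, standard_decay):
        assert host_decay_probability(0, 0, standard_decay, 10_000) == 0.0

    def test_full_slow_occupancy_discounted(self, standard_decay):
        assert host_decay_probability(0, 10_000, standard_decay, 10_000) == (
            pytest.approx(0.01)
        )

    def test_overfull_patch_rejected(self, standard_decay):
        with pytest.raises(ValueError):
            host_decay_probability(9_000, 2_000, standard_decay, 10_000)

    def test_quality_of_empty_patch_is_one(self, standard_decay):
        assert patch_quality(0.0, standard_decay) == 1.0

    def test_quality_of_full_fast_patch_is_zero(self, standard_decay):
        assert patch_quality(0.1, standard_decay) == pytest.approx(0.0)

    def test_quality_of_full_slow_patch(self, standard_decay):
        delta = host_decay_probability(0, 10_000, standard_decay, 10_000)
        assert patch_quality(delta, standard_decay) == pytest.approx(0.9)

    def test_quality_defined_when_no_decay(self):
        assert patch_quality(0.0, DecayParams(0.0, 0.5)) == 1.0

    def test_quality_rejects_delta_above_delta_K(self, standard_decay):
        with pytest.raises(ValueError):
            patch_quality(0.2, standard_decay)


class TestHostDecayStep:
    def test_zero_delta_no_deaths(self, rng):
        assert host_decay_step(100, 0.0, rng) == 0

    def test_certain_death(self, rng):
        assert host_decay_step(100, 1.0, rng) == 100

    def test_mean_deaths(self, rng):
        n = 10_000
        deaths = np.array([host_decay_step(100, 0.1, rng) for _ in range(n)])
        se = math.sqrt(100 * 0.1 * 0.9 / n)
        assert abs(deaths.mean() - 10.0) < 3 * se


class TestRunPatchCycle:
    def test_sterile_patch_never_decays(self, standard_growth, standard_decay, rng):
        res = run_patch_cycle((0, 0), 100, 500, standard_growth, standard_decay, rng)
        assert res.survivors == 100
        assert (res.final_state.Nf, res.final_state.Ns) == (0, 0)

    def test_zero_steps_is_identity(self, standard_growth, standard_decay, rng):
        res = run_patch_cycle((5, 0), 100, 0, standard_growth, standard_decay, rng)
        assert res.survivors == 100
        assert (res.final_state.Nf, res.final_state.Ns) == (5, 0)

    def test_survival_ordering_in_founder_composition(self, rng):
        # all-slow patches decay ten times slower, so more hosts survive
        g = GrowthParams(c=0.15, K=1000)
        d = DecayParams(0.1, 0.1)
        reps = 200
        surv = {}
        for founders in [(5, 0), (0, 5)]:
            _, _, H = run_patch_cycle_batch(
                np.full(reps, founders[0]),
                np.full(reps, founders[1]),
                np.full(reps, 100),
                200,
                g,
                d,
                rng,
            )
            surv[founders] = H.mean()
        assert surv[(0, 5)] > surv[(5, 0)]

    def test_capacity_never_exceeded_and_hosts_monotone(self, rng):
        g = GrowthParams(c=0.3, K=40)
        d = DecayParams(0.2, 0.5)
        res = run_patch_cycle((3, 2), 50, 100, g, d, rng)
        assert res.final_state.total <= g.K
        assert res.final_state.Nf >= 3 and res.final_state.Ns >= 2
        assert 0 <= res.survivors <= 50


class TestExpectedHostSurvival:
    def test_sterile_patch_survival_is_one(self, standard_growth, standard_decay):
        assert expected_host_survival((0, 0), 1000, standard_growth, standard_decay) == 1.0

    def test_full_fast_patch_closed_form(self, standard_decay):
        g = GrowthParams(c=0.15, K=100)
        S = expected_host_survival((100, 0), 50, g, standard_decay)
        assert S == pytest.approx((1 - 0.1) ** 50)

    def test_monotone_in_tau(self, standard_decay):
        g = GrowthParams(c=0.15, K=1000)
        vals = [expected_host_survival((4, 1), t, g, standard_decay) for t in (0, 50, 200)]
        assert vals[0] == 1.0
        assert vals[0] >= vals[1] >= vals[2]

    def test_matches_monte_carlo_for_deterministic_trajectory(self, rng):
        # a pure-fast founder population has a deterministic growth path,
        # so the semi-analytic survival equals the simulated survivor mean
        g = GrowthParams(c=0.15, K=1000)
        d = DecayParams(0.1, 0.1)
        S = expected_host_survival((5, 0), 200, g, d)
        reps, hosts = 500, 100
        _, _, H = run_patch_cycle_batch(
            np.full(reps, 5), np.zeros(reps, dtype=int), np.full(reps, hosts),
            200, g, d, rng,
        )
        frac = H.sum() / (reps * hosts)
        se = math.sqrt(S * (1 - S) / (reps * hosts))
        assert abs(frac - S) < 3 * se


class TestExactCompositionOracle:
    def test_neutral_polya_uniformity(self):
        # classical result: with one ball of each color the final count of
        # either color is uniform
        dist = exact_final_composition_distribution(1, 1, GrowthParams(c=0.0, K=4))
        assert dist == pytest.approx(
            {(3, 1): 1 / 3, (2, 2): 1 / 3, (1, 3): 1 / 3}
        )

    def test_absent_type_cannot_appear(self):
        dist = exact_final_composition_distribution(1, 0, GrowthParams(c=0.6, K=4))
        assert dist == pytest.approx({(4, 0): 1.0})

    def test_distribution_normalized(self):
        dist = exact_final_composition_distribution(2, 3, GrowthParams(c=0.25, K=30))
        assert sum(dist.values()) == pytest.approx(1.0)
        assert all(nf + ns == 30 for nf, ns in dist)

    def test_refuses_large_K(self):
        with pytest.raises(ValueError):
            exact_final_composition_distribution(1, 1, GrowthParams(c=0.1, K=5000))

    def test_oracle_matches_simulation(self, rng):
        g = GrowthParams(c=0.15, K=20)
        dist = exact_final_composition_distribution(1, 1, g)
        probs = np.zeros(g.K + 1)
        for (_, ns), p in dist.items():
            probs[ns] = p
        n = 30_000
        ns = sample_final_compositions(1, 1, g, n, rng)
        obs = np.bincount(ns, minlength=g.K + 1)
        mask = probs > 0
        res = stats.chisquare(obs[mask], n * probs[mask] / probs[mask].sum())
        assert res.pvalue > 0.01

    def test_neutral_exchangeability(self, rng):
        # with c = 0 relabeling fast <-> slow mirrors the distribution
        g = GrowthParams(c=0.0, K=12)
        d12 = exact_final_composition_distribution(1, 2, g)
        d21 = exact_final_composition_distribution(2, 1, g)
        mirrored = {(ns, nf): p for (nf, ns), p in d21.items()}
        assert d12 == pytest.approx(mirrored)
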