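"""Unit and property tests of the core collapse-driven simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import logsumexp

import ktwsim as k

from .conftest import make_state
from .oracle import simulate_linear


class TestDrawInterval:
    def test_mean_matches_tau(self):
        rng = np.random.default_rng(7)
        draws = np.array([k.draw_interval(rng, 2.0) for _ in range(100_000)])
        assert np.all(draws > 0)
        se = 2.0 / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_exponential_tail(self):
        # P(X > tau) = 1/e for an exponential with mean tau
        rng = np.random.default_rng(8)
        draws = np.array([k.draw_interval(rng, 1.0) for _ in range(100_000)])
        frac = np.mean(draws > 1.0)
        p = np.exp(-1.0)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / draws.size)

    def test_deterministic_under_seed(self):
        a = [k.draw_interval(np.random.default_rng(3), 1.5) for _ in range(5)]
        b = [k.draw_interval(np.random.default_rng(3), 1.5) for _ in range(5)]
        assert a == b

    def test_rejects_bad_tau(self):
        with pytest.raises(k.ConfigError):
            k.draw_interval(np.random.default_rng(0), 0.0)


class TestGrow:
    def test_hand_example(self, two_species):
        # P=(1/2,1/2), g=(1,0), dt=ln4: numerators (2, 1/2) -> (0.8, 0.2)
        out = k.grow(two_species, np.log(4.0))
        np.testing.assert_allclose(np.exp(out.log_abundance), [0.8, 0.2], atol=1e-12)

    def test_zero_dt_identity(self, two_species):
        out = k.grow(two_species, 0.0)
        np.testing.assert_allclose(out.log_abundance, two_species.log_abundance,
                                   atol=1e-12)

    @given(
        dt=st.floats(0.0, 50.0),
        c=st.floats(-5.0, 5.0),
        p1=st.floats(0.01, 0.99),
    )
    @settings(deadline=None, max_examples=50)
    def test_equal_rates_leave_shares_unchanged(self, dt, c, p1):
        state = make_state([p1, 1 - p1], g=[c, c])
        out = k.grow(state, dt)
        np.testing.assert_allclose(out.log_abundance, state.log_abundance, atol=1e-9)

    @given(
        dt=st.floats(0.0, 100.0),
        seed=st.integers(0, 10_000),
        n=st.integers(2, 30),
    )
    @settings(deadline=None, max_examples=50)
    def test_normalisation_invariant(self, dt, seed, n):
        rng = np.random.default_rng(seed)
        state = make_state(rng.dirichlet(np.ones(n)), g=rng.normal(0, 3, n))
        out = k.grow(state, dt)
        assert abs(logsumexp(out.log_abundance)) < 1e-10

    def test_rank_preserved_at_equal_rates(self, rng):
        state = make_state(rng.dirichlet(np.ones(6)), g=np.full(6, 1.3))
        out = k.grow(state, 7.7)
        assert np.array_equal(
            np.argsort(out.log_abundance), np.argsort(state.log_abundance)
        )


class TestSelectWinner:
    def test_degenerate_lottery(self, rng):
        state = make_state([1 - 1e-15, 1e-15])
        assert all(k.select_winner(state, rng) == 0 for _ in range(1000))

    def test_selection_frequency(self):
        rng = np.random.default_rng(5)
        state = make_state([0.8, 0.2])
        hits = sum(k.select_winner(state, rng) == 0 for _ in range(100_000))
        assert abs(hits / 100_000 - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 100_000)

    def test_uniform_frequencies(self):
        rng = np.random.default_rng(6)
        n = 8
        state = make_state(np.ones(n))
        counts = np.bincount(
            [k.select_winner(state, rng) for _ in range(20_000)], minlength=n
        )
        assert stats.chisquare(counts).pvalue > 0.01

    def test_rejects_unnormalised_state(self, rng):
        state = make_state([0.5, 0.5])
        state.log_abundance -= 1.0  # total now e^-1
        with pytest.raises(RuntimeError):
            k.select_winner(state, rng)


class TestCollapse:
    def test_factor_direct(self):
        state = make_state([0.8, 0.2])
        out = k.apply_collapse_factor(state, 0, 1e-3)
        np.testing.assert_allclose(np.exp(out.log_abundance), [8e-4, 0.2], rtol=1e-12)

    def test_factor_composes(self):
        state = make_state([0.8, 0.2])
        out = k.apply_collapse_factor(k.apply_collapse_factor(state, 0, 0.1), 0, 0.1)
        np.testing.assert_allclose(
            out.log_abundance[0], state.log_abundance[0] + np.log(0.01), atol=1e-12
        )

    def test_factor_log10_arithmetic(self):
        state = make_state([0.5, 0.5])
        out = k.apply_collapse_factor(state, 0, 1e-6)
        assert np.isclose(
            (state.log_abundance[0] - out.log_abundance[0]) / np.log(10), 6.0
        )

    def test_threshold_assignment_and_idempotence(self):
        state = make_state([0.8, 0.2])
        out = k.apply_collapse_threshold(state, 0, 1e-6)
        np.testing.assert_allclose(np.exp(out.log_abundance), [1e-6, 0.2], rtol=1e-12)
        again = k.apply_collapse_threshold(out, 0, 1e-6)
        assert again.log_abundance[0] == out.log_abundance[0]

    def test_threshold_raises_tiny_population(self):
        # restart level is independent of history: a victim below gamma moves up
        state = make_state([1.0 - 1e-9, 1e-9])
        out = k.apply_collapse_threshold(state, 1, 1e-6)
        assert out.log_abundance[1] > state.log_abundance[1]

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.5, -0.1])
    def test_rejects_bad_gamma(self, bad):
        state = make_state([0.5, 0.5])
        with pytest.raises(k.ConfigError):
            k.apply_collapse_factor(state, 0, bad)
        with pytest.raises(k.ConfigError):
            k.apply_collapse_threshold(state, 0, bad)


class TestStep:
    def test_single_species_cycles(self):
        params = k.SimulationParams(n_species=1, sigma=0, gamma=1e-2, n_events=20,
                                    seed=0)
        res = k.simulate(params)
        assert all(ev.species_id == 0 for ev in res.event_log)
        # post-collapse the lone species sits at gamma; the next growth step
        # returns it to the full carrying capacity
        assert np.isclose(np.exp(res.state.log_abundance[0]), 1e-2, rtol=1e-10)

    def test_seeded_replay_is_bit_identical(self):
        params = k.SimulationParams(n_species=5, sigma=1, gamma=1e-3, n_events=100,
                                    seed=11)
        a, b = k.simulate(params), k.simulate(params)
        assert np.array_equal(a.state.log_abundance, b.state.log_abundance)
        assert [e.species_id for e in a.event_log] == [e.species_id for e in b.event_log]
        assert a.event_log.dts.tolist() == b.event_log.dts.tolist()

    def test_two_equal_species_split_collapses(self):
        params = k.SimulationParams(
            n_species=2, sigma=0, gamma=1e-3, n_events=20_000, seed=2
        )
        res = k.simulate(params)
        share = res.event_log.victim_counts(2)[0] / len(res.event_log)
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / len(res.event_log)) + 0.01

    def test_event_record_fields(self, rng):
        params = k.SimulationParams(n_species=3, sigma=1, gamma=1e-3, n_events=1,
                                    seed=1)
        res = k.simulate(params)
        ev = res.event_log[0]
        assert ev.dt > 0
        assert ev.log_abundance_after[0] < ev.log_abundance_before[0]
        assert ev.event_index == 0


class TestSimulate:
    def test_fastest_growers_survive(self):
        # N=8, sigma=4, gamma=1e-3: typically only the top few rates survive
        diversities = []
        for seed in range(15):
            params = k.SimulationParams(
                n_species=8, sigma=4, gamma=1e-3, n_events=2000, seed=seed
            )
            res = k.simulate(params)
            D = res.diversity()
            diversities.append(D)
            survivors = set(
                np.flatnonzero(
                    res.state.log_abundance
                    > np.log(params.effective_survival_cutoff())
                )
            )
            top = set(np.argsort(res.state.growth_rate)[::-1][: len(survivors)])
            assert survivors == top  # survivors are an upper set of the rate order
        assert np.median(diversities) <= 4

    def test_equal_rates_balanced_collapse_counts(self):
        # a species one collapse behind is gamma smaller and nearly unhittable,
        # so counts can never spread far
        params = k.SimulationParams(
            n_species=10, sigma=0, gamma=1e-3, n_events=5000, seed=9
        )
        counts = k.simulate(params).event_log.victim_counts(10)
        assert counts.max() - counts.min() <= 3

    def test_continuity_in_sigma_at_fixed_seed(self):
        base = k.SimulationParams(n_species=4, sigma=0.0, gamma=1e-3, n_events=200,
                                  seed=5)
        tiny = base.with_(sigma=1e-300)
        a, b = k.simulate(base), k.simulate(tiny)
        np.testing.assert_allclose(
            a.state.log_abundance, b.state.log_abundance, atol=1e-9
        )

    def test_zero_budget(self):
        params = k.SimulationParams(n_species=3, sigma=1, n_events=0, seed=0)
        res = k.simulate(params)
        assert len(res.event_log) == 0
        np.testing.assert_allclose(np.exp(res.state.log_abundance), np.ones(3) / 3)

    @pytest.mark.parametrize("mode", ["factor", "threshold"])
    def test_matches_linear_space_oracle(self, mode):
        # independent direct-abundance re-implementation, same seed stream
        params = k.SimulationParams(
            n_species=3, sigma=1.0, tau=1.0, gamma=0.05, collapse_mode=mode,
            n_events=300, seed=17
        )
        res = k.simulate(params)
        final = k.grow(res.state, 0.0)  # renormalise after the last collapse
        P_oracle, victims, dts = simulate_linear(
            3, 1.0, 1.0, 0.05, 300, 17, collapse_mode=mode
        )
        assert [e.species_id for e in res.event_log] == victims
        np.testing.assert_allclose(res.event_log.dts, dts, rtol=1e-12)
        np.testing.assert_allclose(np.exp(final.log_abundance), P_oracle, atol=1e-8)

    def test_snapshots_are_post_growth_pre_collapse(self):
        params = k.SimulationParams(n_species=4, sigma=2, gamma=1e-3, n_events=50,
                                    seed=3)
        res = k.simulate(params)
        # every snapshot row is normalised to total abundance 1
        totals = (10.0 ** res.snapshots.log10).sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)
        # and the primary victim's recorded pre-collapse level matches it
        for ev in res.event_log:
            row = res.snapshots.log10[ev.event_index]
            assert np.isclose(
                row[ev.species_id] * np.log(10), ev.log_abundance_before[0]
            )


class TestSurvivingDiversity:
    def test_direct_count(self):
        state = make_state([0.7, 0.3, 1e-40])
        assert k.surviving_diversity(state, 1e-12) == 2

    def test_single_species(self):
        state = make_state([1.0])
        assert k.surviving_diversity(state, 1e-6) == 1

    def test_rejects_cutoff_at_capacity(self):
        state = make_state([0.5, 0.5])
        with pytest.raises(k.ConfigError):
            k.surviving_diversity(state, 1.0)


class TestParams:
    def test_validation_errors(self):
        with pytest.raises(k.ConfigError):
            k.SimulationParams(n_species=0)
        with pytest.raises(k.ConfigError):
            k.SimulationParams(n_species=2, gamma=1.5)
        with pytest.raises(k.ConfigError):
            k.SimulationParams(n_species=2, tau=0.0)
        with pytest.raises(k.ConfigError):
            k.SimulationParams(n_species=2, k_extra=2)

    def test_gamma_broadcast(self):
        p = k.SimulationParams(n_species=3, gamma=1e-4)
        np.testing.assert_allclose(p.gamma_vector(), [1e-4] * 3)
        p = k.SimulationParams(n_species=2, gamma=[1e-3, 1e-5])
        assert p.effective_survival_cutoff() == pytest.approx(1e-8)
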