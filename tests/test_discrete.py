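"""Discrete event engine: single steps, sloughing, trajectories."""

import numpy as np
import pytest

import biofilmdrift as bd
from biofilmdrift.discrete_sim import EventRecord, sloughing_event, step


class TestStep:
    def test_monomorphic_at_source_is_absorbing(self, rng):
        state = bd.DiscreteState(np.array([0, 0, 1000]))
        sel = bd.SelectionParams.neutral(3)
        mig = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 1.0]))
        for _ in range(50):
            state, rec = step(state, sel, mig, rng)
        np.testing.assert_array_equal(state.counts, [0, 0, 1000])

    def test_total_conserved_without_sloughing(self, rng, paper_setup):
        state = paper_setup["init"]
        for _ in range(200):
            state, rec = step(state, paper_setup["sel"], paper_setup["mig"], rng)
            assert state.total == 1000
            assert np.all(state.counts >= 0)
            assert rec.event_type in ("local_birth", "migration")

    def test_migration_event_sampling(self, rng):
        """Forced migration: death ~ composition, birth always from source."""
        state = bd.DiscreteState(np.array([200, 800, 0]))
        sel = bd.SelectionParams.neutral(3)
        mig = bd.MigrationParams(m=1.0, p=np.array([0.0, 0.0, 1.0]))  # all migration
        died = np.zeros(3)
        n = 3000
        for _ in range(n):
            _, rec = step(state, sel, mig, rng)
            assert rec.event_type == "migration"
            assert rec.born_taxon == 2
            died[rec.died_taxon] += 1
        # death draw ~ (0.2, 0.8, 0); binomial SE ~ 0.007
        assert died[2] == 0
        assert died[0] / n == pytest.approx(0.2, abs=0.03)
        assert died[1] / n == pytest.approx(0.8, abs=0.03)

    def test_empty_community_rejected(self):
        with pytest.raises(bd.StateError):
            bd.DiscreteState(np.array([0, 0]))

    def test_mean_drift_matches_expectation(self, rng):
        """Empirical mean one-step change = (1/N)[(1-m) b + m p - d]."""
        counts = np.array([200, 700, 100])
        state = bd.DiscreteState(counts)
        sel = bd.SelectionParams(np.array([0.0, 0.05, 0.0]), np.array([0.0, 0.0, 0.08]))
        mig = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 1.0]))
        N = state.total
        x = state.composition
        b = bd.birth_probabilities(x, sel.alpha)
        d = bd.death_probabilities(x, sel.beta)
        expect = ((1 - mig.m) * b + mig.m * mig.p - d) / N
        K = 100_000
        acc = np.zeros(3)
        for _ in range(K):
            new, _ = step(state, sel, mig, rng)
            acc += new.composition - x
        emp = acc / K
        # per-step sd of each coordinate is O(1/N); 4 standard errors
        se = np.sqrt(2 * np.maximum(x * (1 - x), 1e-4)) / N / np.sqrt(K)
        np.testing.assert_array_less(np.abs(emp - expect), 4 * se)


class TestSloughing:
    def test_expected_value_allocation_bookkeeping(self):
        state = bd.DiscreteState(np.array([200, 800, 0]))
        mig = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 1.0]),
                                 s=1e-6, N_s=1000, p_die=0.5)
        new = sloughing_event(state, mig, expected_alloc=True)
        np.testing.assert_array_equal(new.counts, [700, 800, 500])
        assert new.total == 2000

    def test_stochastic_allocation_counts(self, rng):
        state = bd.DiscreteState(np.array([200, 800, 0]))
        mig = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.1, 0.9]),
                                 s=1e-6, N_s=1000, p_die=0.5)
        new = sloughing_event(state, mig, rng)
        assert new.total == 2000
        # exactly round(N_s*p_die)=500 to the buffer, 500 survivors over p
        survivors = new.counts - state.counts - np.array([500, 0, 0])
        assert survivors.sum() == 500
        assert np.all(survivors >= 0)
        assert survivors[0] == 0  # p[0] = 0

    def test_boundaries(self, rng):
        state = bd.DiscreteState(np.array([200, 800, 0]))
        mig0 = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 1.0]), N_s=0)
        np.testing.assert_array_equal(
            sloughing_event(state, mig0, rng).counts, state.counts
        )
        mig1 = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 1.0]),
                                  N_s=1000, p_die=1.0)
        new = sloughing_event(state, mig1, rng)
        np.testing.assert_array_equal(new.counts, [1200, 800, 0])

    def test_total_growth_under_sloughing_runs(self):
        """After k sloughing events the total is N + k * N_s."""
        init = bd.DiscreteState.from_composition((0.2, 0.8, 0.0), 1000)
        sel = bd.SelectionParams.neutral(3)
        mig = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 1.0]),
                                 s=1e-4, N_s=1000, p_die=0.5)
        traj = bd.simulate_discrete(init, sel, mig, 50_000, seed=11, record_every=100)
        totals = traj.values.sum(axis=1)
        k_slough = (totals[-1] - 1000) // 1000
        assert totals[-1] == 1000 + k_slough * 1000
        assert np.all(np.diff(totals) >= 0)
        assert k_slough >= 1  # s=1e-4 over 5e4 events: ~5 expected


class TestSimulateDiscrete:
    def test_zero_events_returns_initial_state(self, paper_setup):
        traj = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                    paper_setup["mig"], 0, seed=1)
        assert traj.n_records == 1
        np.testing.assert_array_equal(traj.values[0], [200, 800, 0])

    def test_record_count_and_indices(self, paper_setup):
        traj = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                    paper_setup["mig"], 1000, seed=1, record_every=300)
        assert traj.n_records == 1000 // 300 + 1
        np.testing.assert_array_equal(traj.index, [0, 300, 600, 900])

    def test_same_seed_bitwise_identical(self, paper_setup):
        a = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                 paper_setup["mig"], 20_000, seed=42, record_every=50)
        b = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                 paper_setup["mig"], 20_000, seed=42, record_every=50)
        np.testing.assert_array_equal(a.values, b.values)
        c = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                 paper_setup["mig"], 20_000, seed=43, record_every=50)
        assert not np.array_equal(a.values, c.values)

    def test_conservation_without_sloughing(self, paper_setup):
        traj = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                    paper_setup["mig"], 50_000, seed=3, record_every=100)
        np.testing.assert_array_equal(traj.values.sum(axis=1), 1000)
        assert np.all(traj.values >= 0)

    def test_absorbed_taxa_stay_absent(self, paper_setup):
        """A taxon with p_i = 0, count 0 and no sloughing can never return."""
        traj = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                    paper_setup["mig"], 300_000, seed=5, record_every=100)
        for taxon in (0, 1):  # buffer and bulk have p_i = 0
            col = traj.values[:, taxon]
            zeros = np.flatnonzero(col == 0)
            if zeros.size:
                assert np.all(col[zeros[0]:] == 0)

    def test_biofilm_dominates_neutral_run(self, paper_setup):
        """Sufficient migration drives the source taxon to dominance."""
        wins = 0
        for rep in range(10):
            traj = bd.simulate_discrete(paper_setup["init"], paper_setup["sel"],
                                        paper_setup["mig"], 300_000,
                                        seed=600 + rep, record_every=1000)
            if traj.values[-1, 2] >= 990:
                wins += 1
        assert wins >= 9

    def test_neutral_symmetry_of_elimination(self):
        """Two interchangeable taxa with equal counts are eliminated equally often."""
        from biofilmdrift.discrete_sim import time_to_boundary

        init = bd.DiscreteState(np.array([100, 400, 400, 100]))
        sel = bd.SelectionParams.neutral(4)
        mig = bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 0.0, 1.0]))
        horizon = 30_000
        first = sum(
            time_to_boundary(init, sel, mig, taxon=1, fixation=False,
                             max_events=horizon, seed=900 + i) is not None
            for i in range(500)
        )
        second = sum(
            time_to_boundary(init, sel, mig, taxon=2, fixation=False,
                             max_events=horizon, seed=900 + i) is not None
            for i in range(500)
        )
        p1, p2 = first / 500, second / 500
        se = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 500 + 1e-6)
        assert abs(p1 - p2) < 3.5 * se

    def test_event_record_shape(self):
        rec = EventRecord("sloughing", None, None, event_index=7)
        assert rec.died_taxon is None and rec.born_taxon is None
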