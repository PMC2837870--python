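"""Move set, Metropolis/replica-exchange acceptance and the REMC protocol."""

import numpy as np
import pytest

import loopcg as lc
from loopcg.forcefield import ConformationEvaluator, EnergyModel
from loopcg.remc import (MoveSet, Schedule, metropolis_accept, metropolis_step,
                         random_loop_insert, replica_swap, run_remc, run_repeats)
from loopcg.restraints import scaffold_restraints


@pytest.fixture(scope="module")
def small_schedule():
    return Schedule(n_replicas=2, t_high=1.5, t_low=1.0, anneal_factor=0.95,
                    n_macrocycles=4, steps_per_cycle=8, swap_interval=4, seed=42)


class TestRandomLoopInsert:
    def test_inserted_loop_closes_and_validates(self, hlh_case, vset):
        conf = random_loop_insert(hlh_case, vset, seed=3)
        conf.validate()
        assert len(conf) == len(hlh_case.scaffold)

    def test_different_seeds_differ(self, hlh_case, vset):
        a = random_loop_insert(hlh_case, vset, seed=1)
        b = random_loop_insert(hlh_case, vset, seed=2)
        loop = hlh_case.loop_indices
        assert not np.array_equal(a.ca[loop], b.ca[loop])
        a.validate()
        b.validate()

    def test_same_seed_identical(self, hlh_case, vset):
        a = random_loop_insert(hlh_case, vset, seed=9)
        b = random_loop_insert(hlh_case, vset, seed=9)
        np.testing.assert_array_equal(a.ca, b.ca)

    def test_longer_loop_also_closes(self, vset):
        structure, loopspec = lc.make_fixture(lc.FixtureSpec("helix-loop-helix", (12, 12), 8, 1))
        case = lc.excise_loop(structure, loopspec)
        conf = random_loop_insert(case, vset, seed=0)
        conf.validate()


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-0.5, 1.0, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 1.0, rng) for _ in range(100))

    def test_acceptance_rate_matches_boltzmann_factor(self):
        """At dE=1, T=1 the acceptance probability is exp(-1) = 0.368."""
        rng = np.random.default_rng(2024)
        n = 100_000
        acc = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n)) / n
        assert acc == pytest.approx(np.exp(-1.0), abs=0.005)

    def test_zero_temperature_rejects_uphill(self, rng):
        assert not any(metropolis_accept(0.1, 1e-12, rng) for _ in range(50))

    def test_step_preserves_chain_invariant(self, hlh_case, vset, rng):
        conf = random_loop_insert(hlh_case, vset, seed=5)
        model = EnergyModel()
        rs = scaffold_restraints(hlh_case, seed=5)
        n_acc = 0
        for _ in range(60):
            conf, acc = metropolis_step(conf, MoveSet(), model, rs, 2.0, rng)
            n_acc += acc
        conf.validate()
        assert n_acc > 0

    def test_three_state_toy_reaches_boltzmann(self):
        """Empirical occupancy of a 3-state chain matches exp(-E/T) within 3 sigma."""
        energies = np.array([0.0, 1.0, 2.0])
        T = 1.0
        rng = np.random.default_rng(77)
        state = 0
        counts = np.zeros(3)
        n = 100_000
        for _ in range(n):
            prop = (state + rng.integers(1, 3)) % 3  # symmetric proposal
            if metropolis_accept(energies[prop] - energies[state], T, rng):
                state = prop
            counts[state] += 1
        p = np.exp(-energies / T)
        p /= p.sum()
        for k in range(3):
            sigma = np.sqrt(p[k] * (1 - p[k]) / n)
            # serial correlation inflates the error; allow a generous factor
            assert abs(counts[k] / n - p[k]) < 3 * sigma * 6


class TestReplicaSwap:
    def test_equal_energies_always_swap(self, rng):
        assert all(replica_swap(5.0, 5.0, 1.0, 1.5, rng) for _ in range(50))

    def test_lower_energy_at_higher_t_always_swaps(self, rng):
        # configuration at the hotter replica has the lower energy
        assert all(replica_swap(3.0, 1.0, 1.0, 2.0, rng) for _ in range(50))

    def test_long_run_rate_matches_analytic_average(self):
        """For independent Gaussian energies the mean swap acceptance is
        E[min(1, exp(b (X - Y)))] with b = 1/T1 - 1/T2; estimate both by
        Monte Carlo with a closed-form cross-check of the acceptance rule."""
        rng = np.random.default_rng(5)
        t1, t2 = 1.0, 1.4
        b = 1.0 / t1 - 1.0 / t2
        e1 = rng.normal(0.0, 1.0, 40_000)
        e2 = rng.normal(0.5, 1.0, 40_000)
        analytic = np.minimum(1.0, np.exp(b * (e1 - e2))).mean()
        emp = np.mean([replica_swap(a, c, t1, t2, rng) for a, c in zip(e1, e2)])
        assert emp == pytest.approx(analytic, abs=0.01)


class TestRunRemc:
    def test_same_seed_bit_identical(self, hlh_case, small_schedule):
        model = EnergyModel()
        rs = scaffold_restraints(hlh_case, seed=42)
        t1 = run_remc(hlh_case, model, rs, small_schedule)
        t2 = run_remc(hlh_case, model, rs, small_schedule)
        assert len(t1.snapshots) == small_schedule.n_macrocycles
        for a, b in zip(t1.snapshots, t2.snapshots):
            np.testing.assert_array_equal(a.conf.ca, b.conf.ca)
            assert a.energy == b.energy

    def test_every_snapshot_valid_and_finite(self, hlh_case, small_schedule):
        model = EnergyModel()
        rs = scaffold_restraints(hlh_case, seed=42)
        traj = run_remc(hlh_case, model, rs, small_schedule)
        ev = ConformationEvaluator(hlh_case.sequence, model, rs)
        for s in traj.snapshots:
            s.conf.validate()
            assert np.isfinite(s.energy)
            assert ev.total(s.conf.ca_xyz()) == pytest.approx(s.energy, rel=1e-9)

    def test_single_replica_degenerates_to_annealed_mc(self, hlh_case):
        sched = Schedule(n_replicas=1, t_high=1.0, t_low=1.0, anneal_factor=0.9,
                         n_macrocycles=3, steps_per_cycle=5, swap_interval=2, seed=7)
        traj = run_remc(hlh_case, EnergyModel(), scaffold_restraints(hlh_case, seed=7), sched)
        assert len(traj.snapshots) == 3

    def test_annealing_lowers_snapshot_energy(self, hlh_case):
        """Energy trends downward over macro-cycles (negative Spearman rho)."""
        from scipy.stats import spearmanr
        sched = Schedule(n_replicas=3, t_high=2.0, t_low=1.0, anneal_factor=0.9,
                         n_macrocycles=12, steps_per_cycle=10, swap_interval=5, seed=11)
        traj = run_remc(hlh_case, EnergyModel(), scaffold_restraints(hlh_case, seed=11), sched)
        e = [s.energy for s in traj.snapshots]
        rho, _ = spearmanr(np.arange(len(e)), e)
        assert rho < 0

    def test_restraint_satisfaction_improves(self, hlh_case):
        from loopcg.restraints import restraint_energy_xyz
        rs = scaffold_restraints(hlh_case, seed=13)
        sched = Schedule(n_replicas=3, t_high=2.0, t_low=1.0, anneal_factor=0.9,
                        n_macrocycles=10, steps_per_cycle=10, swap_interval=5, seed=13)
        traj = run_remc(hlh_case, EnergyModel(), rs, sched)
        viol = [restraint_energy_xyz(s.conf.ca_xyz(), rs) for s in traj.snapshots]
        # stochastic trend check: second half no worse than first half
        assert np.mean(viol[len(viol) // 2:]) <= np.mean(viol[:len(viol) // 2]) + 1.0


class TestRunRepeats:
    def test_three_repeats_distinct_seeds(self, hlh_case, small_schedule):
        rs = scaffold_restraints(hlh_case, seed=42)
        trajs = run_repeats(hlh_case, EnergyModel(), rs, small_schedule, n_repeats=3)
        assert [t.run_id for t in trajs] == [0, 1, 2]
        seeds = {t.seed for t in trajs}
        assert len(seeds) == 3
        # different streams produce different trajectories
        assert not np.array_equal(trajs[0].snapshots[-1].conf.ca,
                                  trajs[1].snapshots[-1].conf.ca)

    def test_single_repeat(self, hlh_case, small_schedule):
        rs = scaffold_restraints(hlh_case, seed=42)
        trajs = run_repeats(hlh_case, EnergyModel(), rs, small_schedule, n_repeats=1)
        assert len(trajs) == 1

    def test_invalid_repeats(self, hlh_case, small_schedule):
        with pytest.raises(ValueError):
            run_repeats(hlh_case, EnergyModel(), None, small_schedule, n_repeats=0)
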