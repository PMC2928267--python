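"""The Monte Carlo engine: moves, invariants, determinism, sampling."""

import numpy as np
import pytest

from dynloop import (
    InvariantError,
    LoopParams,
    MoveReason,
    PlacementError,
    SystemConfig,
    SystemState,
    init_saw_chain,
)
from dynloop.fixtures import dimer_state

from conftest import random_legal_chain, ref_bond_ok, ref_cubes_overlap, ref_state_ok


class TestInit:
    def test_two_monomer_chain_has_one_legal_bond(self):
        st = init_saw_chain(SystemConfig(N=2, L=16, seed=0))
        assert ref_bond_ok(st.pos[1] - st.pos[0])

    def test_initial_state_satisfies_all_invariants(self):
        st = init_saw_chain(SystemConfig(N=128, L=128, seed=0))
        st.validate()  # raises on breach

    def test_same_seed_reproduces_coordinates(self):
        a = init_saw_chain(SystemConfig(N=32, L=64, seed=7))
        b = init_saw_chain(SystemConfig(N=32, L=64, seed=7))
        assert np.array_equal(a.pos, b.pos)

    def test_box_too_small_is_reported(self):
        with pytest.raises(PlacementError):
            init_saw_chain(SystemConfig(N=5000, L=16, seed=0))

    def test_non_power_of_two_box_rejected(self):
        with pytest.raises(ValueError):
            init_saw_chain(SystemConfig(N=8, L=(48, 32, 32), seed=0))


class TestSingleMoves:
    def test_dimer_bond_2_stretches_to_3(self):
        st = dimer_state(bond=(2, 0, 0))
        res = st.attempt_move(1, (1, 0, 0))  # bond becomes (3,0,0)
        assert res.accepted and res.reason is MoveReason.OK
        st.validate()

    def test_dimer_bond_3_cannot_stretch_to_4(self):
        st = dimer_state(bond=(3, 0, 0))
        before = st.pos.copy()
        res = st.attempt_move(1, (1, 0, 0))  # bond would become (4,0,0)
        assert not res.accepted and res.reason is MoveReason.BOND_VIOLATION
        assert np.array_equal(st.pos, before)

    def test_excluded_volume_blocks_overlap(self):
        # two chains: single monomers at distance (2,0,0), cubes just
        # touching; moving one closer would make the cubes share sites
        pos = np.array([[4, 4, 4], [6, 4, 4]])
        st = SystemState(pos, np.array([0, 1]), (16, 16, 16))
        res = st.attempt_move(0, (1, 0, 0))
        assert not res.accepted and res.reason is MoveReason.EXCLUDED_VOLUME

    def test_loop_constraint_blocks_separation(self, small_chain):
        st = small_chain
        st.run_mcs(500)
        lp = LoopParams(P=1.0, mean_lifetime=1e7)
        # force a loop somewhere, then verify no accepted move ever
        # violates it
        for m in range(st.n_monomers):
            if st.attempt_loop_formation(lp, monomer=m):
                break
        else:
            pytest.skip("no co-localized pair in this configuration")
        st.run_mcs(200, LoopParams(P=0.0, mean_lifetime=0.0))
        st.validate()

    def test_invalid_direction_rejected(self, small_chain):
        with pytest.raises(ValueError):
            small_chain.attempt_move(0, (1, 1, 0))


class TestMoveOracle:
    """Accept/reject decisions equal a from-scratch reference validator."""

    DIRS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def test_oracle_equivalence_on_random_micro_states(self, rng):
        checked = 0
        mismatches = []
        for trial in range(250):
            n = int(rng.integers(2, 7))
            pos = random_legal_chain(rng, n)
            st = SystemState(pos, np.zeros(n, dtype=np.int32), (64, 64, 64))
            for _ in range(45):
                m = int(rng.integers(n))
                d = self.DIRS[rng.integers(6)]
                before = st.pos.copy()
                proposed = before.copy()
                proposed[m] += d
                expect = ref_state_ok(proposed)
                got = st.attempt_move(m, d)
                checked += 1
                if got.accepted != expect:
                    mismatches.append((before, m, d, got))
                # engine must mutate exactly on acceptance
                target = proposed if expect else before
                assert np.array_equal(st.pos, target)
        assert checked >= 10_000
        assert not mismatches, f"{len(mismatches)} oracle mismatches, first: {mismatches[0]}"

    def test_trajectory_invariants_hold_under_long_run(self):
        st = init_saw_chain(SystemConfig(N=24, L=32, seed=9))
        lp = LoopParams(P=0.2, mean_lifetime=300.0)
        for _ in range(20):
            st.run_mcs(500, lp)
            st.validate()


class TestRunMcs:
    def test_zero_steps_is_identity(self, warm_chain):
        before = warm_chain.pos.copy()
        t = warm_chain.mc_time
        warm_chain.run_mcs(0)
        assert np.array_equal(warm_chain.pos, before)
        assert warm_chain.mc_time == t

    def test_mc_clock_advances_by_n_mcs(self):
        st = init_saw_chain(SystemConfig(N=8, L=16, seed=1))
        st.run_mcs(37)
        assert st.mc_time == 37

    def test_same_seed_same_trajectory(self):
        out = []
        for _ in range(2):
            st = init_saw_chain(SystemConfig(N=16, L=32, seed=11))
            st.run_mcs(2000, LoopParams(P=0.1, mean_lifetime=100.0))
            out.append((st.pos.copy(), st.mc_time, tuple(st.loop_log)))
        assert np.array_equal(out[0][0], out[1][0])
        assert out[0][1:] == out[1][1:]

    def test_different_seeds_diverge(self):
        a = init_saw_chain(SystemConfig(N=16, L=32, seed=1))
        b = init_saw_chain(SystemConfig(N=16, L=32, seed=2))
        a.run_mcs(2000)
        b.run_mcs(2000)
        assert not np.array_equal(a.pos, b.pos)


class TestTrimerUniformity:
    """With symmetric proposals and no energy, the stationary law is
    uniform over the reachable shape classes of a 3-monomer chain."""

    @staticmethod
    def trimer_classes_and_transitions():
        """BFS over (b1, b2) shape classes using the reference rules."""
        from itertools import product

        def legal(b1, b2):
            if not (ref_bond_ok(b1) and ref_bond_ok(b2)):
                return False
            p0 = np.zeros(3, dtype=int)
            p1 = p0 + b1
            p2 = p1 + b2
            return not (
                ref_cubes_overlap(p0, p1)
                or ref_cubes_overlap(p1, p2)
                or ref_cubes_overlap(p0, p2)
            )

        dirs = [np.array(d) for d in
                [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]]

        def neighbors(state):
            b1, b2 = np.array(state[0]), np.array(state[1])
            out = []
            for d in dirs:
                cands = [(b1 - d, b2), (b1 + d, b2 - d), (b1, b2 + d)]  # move m0/m1/m2
                for nb1, nb2 in cands:
                    if legal(nb1, nb2):
                        out.append((tuple(nb1), tuple(nb2)))
            return out

        # start from a known-legal state and explore
        start = ((2, 0, 0), (0, 2, 0))
        assert legal(np.array(start[0]), np.array(start[1]))
        seen = {start}
        stack = [start]
        while stack:
            s = stack.pop()
            for nb in neighbors(s):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    def test_trimer_sampling_is_uniform_over_reachable_classes(self):
        from scipy import stats as sps

        classes = self.trimer_classes_and_transitions()
        K = len(classes)
        assert K > 5000  # the reachable component is large
        st = SystemState(
            np.array([[8, 8, 8], [10, 8, 8], [10, 10, 8]]),
            np.zeros(3, dtype=np.int32),
            (16, 16, 16),
            seed=5,
        )
        counts: dict = {}
        n_samp = 8 * K
        for _ in range(n_samp):
            st.run_mcs(25)
            key = (tuple(st.pos[1] - st.pos[0]), tuple(st.pos[2] - st.pos[1]))
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) <= classes  # never leaves the reachable set
        observed = np.array([counts.get(c, 0) for c in sorted(classes)])
        chi2, p = sps.chisquare(observed)
        assert p > 1e-4, f"trimer sampling non-uniform: chi2/df={chi2 / (K - 1):.3f}"


class TestValidator:
    def test_detects_planted_overlap(self):
        pos = np.array([[4, 4, 4], [6, 4, 4], [8, 4, 4]])
        st = SystemState(pos, np.zeros(3, dtype=np.int32), (16, 16, 16))
        st.pos[2] = [5, 4, 4]  # overlap + bond breach, bypassing the engine
        st.fpos[2] = [5, 4, 4]
        with pytest.raises(InvariantError):
            st.validate()

    def test_detects_folded_unfolded_mismatch(self, small_chain):
        small_chain.pos[0] += 32  # breaks pos mod L == fpos
        small_chain.pos[0] -= 31
        with pytest.raises(InvariantError):
            small_chain.validate()
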