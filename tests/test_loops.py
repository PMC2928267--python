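"""Dynamic loops: lifetimes, formation, expiry, constraint, bookkeeping."""

import numpy as np
import pytest
from scipy import stats as sps

from dynloop import LoopParams, SystemConfig, SystemState, init_saw_chain
from dynloop.fixtures import HAND_LOOP_LOG, HAND_LOOP_LOG_MEAN, HAND_LOOP_LOG_WINDOW
from dynloop.loops import draw_lifetime, mean_loop_count


class TestLifetimes:
    def test_zero_mean_lifetime_always_zero(self):
        rng = np.random.default_rng(0)
        lp = LoopParams(P=1.0, mean_lifetime=0.0)
        assert all(draw_lifetime(lp, rng) == 0 for _ in range(100))

    def test_sample_mean_matches_poisson_mean(self):
        rng = np.random.default_rng(1)
        lp = LoopParams(P=1.0, mean_lifetime=50.0)
        draws = np.array([draw_lifetime(lp, rng) for _ in range(100_000)])
        se = np.sqrt(50.0 / draws.size)
        assert abs(draws.mean() - 50.0) < 3 * se

    def test_pmf_matches_closed_form(self):
        """Chi-square against e^-5 5^k / k! for the engine's own draws."""
        from dynloop import _kernel

        _kernel.seed_rng(12345)
        draws = _kernel.draw_poisson(5.0, 200_000)
        kmax = 15
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        pmf = sps.poisson.pmf(np.arange(kmax), 5.0)
        expected = np.append(pmf, 1.0 - pmf.sum()) * draws.size
        chi2, p = sps.chisquare(obs, expected)
        assert p > 1e-4

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            LoopParams(P=1.0, mean_lifetime=-1.0)


class TestFormation:
    def test_colocalized_pair_forms_loop_at_P_1(self):
        pos = np.array([[8, 8, 8], [10, 8, 8], [12, 8, 8], [12, 10, 8],
                        [10, 10, 8]])
        st = SystemState(pos, np.zeros(5, dtype=np.int32), (32, 32, 32), seed=1)
        d = st.pos[4] - st.pos[0]
        assert (d**2).sum() <= 8  # displacement (2,2,0), |v| = sqrt(8) < 3
        lp = LoopParams(P=1.0, mean_lifetime=100.0)
        loop = st.attempt_loop_formation(lp, monomer=0)
        assert loop is not None and (loop.i, loop.j) == (0, 4)

    def test_distance_exactly_3_is_not_colocalized(self):
        # displacement (3,0,0): |v| = 3, strict inequality excludes it
        pos = np.array([[8, 8, 8], [10, 8, 8], [12, 9, 9], [11, 8, 8]])
        st = SystemState(pos, np.zeros(4, dtype=np.int32), (32, 32, 32), seed=1)
        assert ((st.pos[3] - st.pos[0]) ** 2).sum() == 9
        lp = LoopParams(P=1.0, mean_lifetime=100.0)
        assert st.attempt_loop_formation(lp, monomer=0) is None

    def test_P_zero_never_forms(self, warm_chain):
        st = warm_chain.copy()
        lp = LoopParams(P=0.0, mean_lifetime=100.0)
        for m in range(st.n_monomers):
            assert st.attempt_loop_formation(lp, monomer=m) is None
        assert st.n_active_loops == 0

    def test_min_contour_separation_respected(self):
        st = init_saw_chain(SystemConfig(N=16, L=32, seed=4))
        st.run_mcs(5000, LoopParams(P=1.0, mean_lifetime=500.0))
        for lp in st.active_loops():
            assert lp.j - lp.i >= 3

    def test_no_duplicate_pairs(self):
        st = init_saw_chain(SystemConfig(N=16, L=32, seed=5))
        st.run_mcs(5000, LoopParams(P=1.0, mean_lifetime=2000.0))
        pairs = [(lp.i, lp.j) for lp in st.active_loops()]
        assert len(pairs) == len(set(pairs))


class TestExpiry:
    def test_no_loops_zero_removed(self, warm_chain):
        st = warm_chain.copy()
        assert st.expire_loops() == 0

    def test_boundary_expiry_and_idempotence(self):
        pos = np.array([[8, 8, 8], [10, 8, 8], [12, 8, 8], [12, 10, 8],
                        [10, 10, 8]])
        st = SystemState(pos, np.zeros(5, dtype=np.int32), (32, 32, 32), seed=1)
        lp = LoopParams(P=1.0, mean_lifetime=0.0)  # lifetime 0: expires_at = now
        loop = st.attempt_loop_formation(lp, monomer=0)
        assert loop is not None and loop.expires_at == st.mc_time
        assert st.expire_loops() == 1  # removed exactly at expires_at == mc_time
        assert st.expire_loops() == 0  # idempotent
        assert st.n_active_loops == 0

    def test_realized_lifetimes_match_poisson_mean(self):
        tau = 80.0
        st = init_saw_chain(SystemConfig(N=24, L=32, seed=6))
        st.run_mcs(2000)
        st.run_mcs(30_000, LoopParams(P=0.3, mean_lifetime=tau))
        log = np.array(st.loop_log)  # (created, expires, i, j)
        assert log.shape[0] > 300
        lifetimes = (log[:, 1] - log[:, 0]).astype(float)
        se = lifetimes.std(ddof=1) / np.sqrt(len(lifetimes))
        # drawn lifetimes are Poisson(tau); realized removal adds < 1 MCS
        assert abs(lifetimes.mean() - tau) < max(4 * se, 1.5)


class TestConstraint:
    def test_active_loops_always_within_radius(self):
        st = init_saw_chain(SystemConfig(N=24, L=32, seed=7))
        st.run_mcs(2000)
        lp = LoopParams(P=0.5, mean_lifetime=400.0)
        violations = 0
        for _ in range(40):
            st.run_mcs(250, lp)
            for loop in st.active_loops():
                d = st.pos[loop.j] - st.pos[loop.i]
                if (d**2).sum() > 8:
                    violations += 1
        assert violations == 0

    def test_monomer_without_loops_unconstrained(self, warm_chain):
        st = warm_chain.copy()
        # all six directions must be decidable without loop rejections
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            res = st.attempt_move(0, d)
            assert res.reason.name != "LOOP_CONSTRAINT"


class TestLoopLog:
    def test_mean_loop_count_hand_computed(self):
        t0, t1 = HAND_LOOP_LOG_WINDOW
        assert mean_loop_count(HAND_LOOP_LOG, t0, t1) == pytest.approx(
            HAND_LOOP_LOG_MEAN
        )

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            mean_loop_count([])

    def test_event_log_count_matches_removals_plus_active(self):
        st = init_saw_chain(SystemConfig(N=16, L=32, seed=8))
        st.run_mcs(1000)
        st.run_mcs(10_000, LoopParams(P=0.3, mean_lifetime=200.0))
        from dynloop._kernel import C_REMOVED

        assert len(st.loop_log) == int(st.counters[C_REMOVED]) + st.n_active_loops
        assert st.dropped_events == 0

    def test_monotone_loop_count_in_P(self):
        """Mean active loop count is non-decreasing in P at fixed lifetime."""
        means = []
        for P in (1e-4, 3e-3, 0.08):
            st = init_saw_chain(SystemConfig(N=32, L=64, seed=9))
            st.run_mcs(4000)
            lp = LoopParams(P=P, mean_lifetime=300.0)
            st.run_mcs(6000, lp, log_events=False)
            counts = []
            for _ in range(60):
                st.run_mcs(150, lp, log_events=False)
                counts.append(st.n_active_loops)
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]
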