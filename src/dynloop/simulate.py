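"""Production simulation driver.

Implements the run protocol of the model: chains are first equilibrated
as plain self-avoiding walks, looping is then switched on and the
system re-equilibrated, a pilot run measures the decorrelation times
(integrated autocorrelation time of Rg^2 plus the center-of-mass
displacement criterion), and finally decorrelated conformations are
retained at the planned sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LoopParams, MeltConfig, SamplingConfig, SystemConfig
from .equilibration import (
    EquilibrationReport,
    UndersampledError,
    autocorrelation,
    com_decorrelation_time,
    plan_sampling,
    sokal_tau_int,
)
from .state import SystemState, build_melt, init_saw_chain


@dataclass
class Ensemble:
    """Decorrelated conformations plus their active-loop snapshots.

    ``positions`` are unfolded integer coordinates of shape
    (n_samples, n_monomers, 3); ``loops[k]`` is an (n_loops, 2) array of
    (i, j) monomer-index pairs active in sample ``k``.
    """

    positions: np.ndarray
    times: np.ndarray
    chain_id: np.ndarray
    L: tuple[int, int, int]
    loops: list[np.ndarray]
    seed: int
    report: EquilibrationReport | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[1]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1

    def mean_loop_count(self) -> float:
        """Time-average number of simultaneously active loops (per chain)."""
        if not self.loops:
            return 0.0
        per_sample = [lp.shape[0] for lp in self.loops]
        return float(np.mean(per_sample)) / self.n_chains

    def loop_sizes(self) -> np.ndarray:
        """Contour sizes j - i of all loop observations, pooled."""
        if not self.loops:
            return np.empty(0, dtype=np.int64)
        out = [np.abs(lp[:, 1] - lp[:, 0]) for lp in self.loops if lp.size]
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def _chain_view(state: SystemState) -> np.ndarray:
    """Positions reshaped to (n_chains, N, 3); chains have equal length."""
    n_chains = state.n_chains
    return state.pos.reshape(n_chains, -1, 3)


def _active_loop_pairs(state: SystemState) -> np.ndarray:
    pairs = []
    for m in range(state.n_monomers):
        for t in range(state.ninc[m]):
            q = int(state.partners[m, t])
            if q > m:
                pairs.append((m, q))
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


class Simulation:
    """One simulation run: a dilute chain or a dense melt, with looping.

    Parameters
    ----------
    engine : SystemConfig or MeltConfig
    looping : LoopParams, optional (default: no looping)
    sampling : SamplingConfig, optional
    """

    def __init__(
        self,
        engine: SystemConfig | MeltConfig,
        looping: LoopParams | None = None,
        sampling: SamplingConfig | None = None,
    ):
        self.engine = engine
        self.looping = looping or LoopParams()
        self.sampling = sampling or SamplingConfig()
        if isinstance(engine, MeltConfig):
            self.state = build_melt(engine)
        else:
            self.state = init_saw_chain(engine)
        self.report: EquilibrationReport | None = None
        self._saw_equilibrated = False

    # -- helpers -------------------------------------------------------

    def _mean_rg2(self) -> float:
        p = _chain_view(self.state).astype(float)
        c = p.mean(axis=1, keepdims=True)
        return float(((p - c) ** 2).sum(axis=2).mean(axis=1).mean())

    def _coms(self) -> np.ndarray:
        return _chain_view(self.state).mean(axis=1)

    def record(self, n_mcs: int, every: int, looping: bool = True) -> dict:
        """Advance while recording Rg^2 / COM / loop-count time series."""
        lp = self.looping if looping else None
        T = max(1, int(n_mcs // every))
        rg2 = np.empty(T)
        nl = np.empty(T)
        coms = np.empty((T, self.state.n_chains, 3))
        tt = np.empty(T, dtype=np.int64)
        for i in range(T):
            self.state.run_mcs(every, lp, log_events=False)
            rg2[i] = self._mean_rg2()
            coms[i] = self._coms()
            nl[i] = self.state.n_active_loops / self.state.n_chains
            tt[i] = self.state.mc_time
        return {"times": tt, "rg2": rg2, "coms": coms, "loops_per_chain": nl, "every": every}

    # -- protocol ------------------------------------------------------

    def equilibrate_saw(self, n_mcs: int | None = None) -> None:
        """Stage 1: relax the regular initial conformation as a SAW.

        Defaults to ~10x the chain's Rouse-like relaxation time
        (tau_int(Rg^2) is empirically ~2 N^2.2 MCS for dilute chains);
        looping is off during this stage.  Switching looping on before
        the artificial initial conformation has relaxed would glue its
        folds in place.
        """
        if n_mcs is None:
            N = self.engine.N
            n_mcs = int(25 * N**2.2)
        self.state.run_mcs(int(n_mcs), None, log_events=False)
        self._saw_equilibrated = True

    def equilibrate_loops(self, n_mcs: int | None = None) -> None:
        """Stage 2: switch looping on and re-equilibrate.

        Defaults to 20 mean lifetimes (loop occupancy equilibrates on
        the lifetime scale) plus one SAW-stage length for the
        conformational degrees of freedom.
        """
        if not self._saw_equilibrated:
            self.equilibrate_saw()
        if self.looping.P <= 0:
            return
        if n_mcs is None:
            n_mcs = int(20 * max(self.looping.mean_lifetime, 1) + 20 * self.engine.N**1.6)
        self.state.run_mcs(int(n_mcs), self.looping, log_events=False)

    def pilot(
        self,
        n_mcs: int | None = None,
        every: int | None = None,
        max_extensions: int = 6,
        require_tcm: bool = True,
    ) -> EquilibrationReport:
        """Measure decorrelation times on a pilot segment of this run.

        The pilot is extended (up to ``max_extensions`` times) until the
        Sokal window lies well inside the series (window < length/10)
        and, if ``require_tcm``, the center-of-mass criterion is
        reached within the pilot trajectory.
        """
        N = self.engine.N
        if n_mcs is None:
            n_mcs = int(400 * N**1.6)
        if every is None:
            every = max(10, int(n_mcs // 8000))
        rec = self.record(n_mcs, every)
        tau = t_cm = None
        for _ in range(max_extensions + 1):
            try:
                tau_f, M = sokal_tau_int(autocorrelation(rec["rg2"]), self.sampling.sokal_c)
                tau = tau_f * every
                if M > rec["rg2"].size // 10:
                    raise UndersampledError("window not well inside series")
                if require_tcm:
                    coms = rec["coms"]
                    tcms = [
                        com_decorrelation_time(rec["times"], coms[:, c, :], rec["rg2"].mean())
                        for c in range(coms.shape[1])
                    ]
                    t_cm = float(np.mean(tcms))
                else:
                    t_cm = 0.0
                break
            except UndersampledError:
                more = self.record(n_mcs, every)
                for k in ("rg2", "loops_per_chain"):
                    rec[k] = np.concatenate([rec[k], more[k]])
                rec["coms"] = np.concatenate([rec["coms"], more["coms"]])
                rec["times"] = np.concatenate([rec["times"], more["times"]])
        else:
            raise UndersampledError(
                "pilot run too short to determine decorrelation times"
            )
        self.report = plan_sampling(
            tau, M, t_cm, self.sampling.tau_multiplier, self.sampling.burnin_multiplier
        )
        self._pilot_rec = rec
        return self.report

    def sample(
        self,
        n_samples: int,
        interval: int | None = None,
        burn_in_mcs: int | None = None,
    ) -> Ensemble:
        """Retain ``n_samples`` decorrelated conformations."""
        if interval is None:
            if self.report is None:
                raise RuntimeError("run pilot() first or pass an explicit interval")
            interval = int(np.ceil(self.report.sampling_interval))
        interval = max(1, int(interval))
        if burn_in_mcs is None:
            burn_in_mcs = (
                int(np.ceil(self.sampling.burnin_multiplier * self.report.tau_int))
                if self.report
                else 10 * interval
            )
        self.state.run_mcs(int(burn_in_mcs), self.looping, log_events=False)
        S = int(n_samples)
        n = self.state.n_monomers
        positions = np.empty((S, n, 3), dtype=np.int32)
        times = np.empty(S, dtype=np.int64)
        loops: list[np.ndarray] = []
        for k in range(S):
            self.state.run_mcs(interval, self.looping, log_events=False)
            positions[k] = self.state.pos
            times[k] = self.state.mc_time
            loops.append(_active_loop_pairs(self.state))
        report = self.report
        if report is not None:
            report = EquilibrationReport(
                tau_int=report.tau_int,
                window_M=report.window_M,
                t_cm=report.t_cm,
                sampling_interval=float(interval),
                n_samples=S,
            )
        return Ensemble(
            positions=positions,
            times=times,
            chain_id=self.state.chain_id.copy(),
            L=self.state.L,
            loops=loops,
            seed=self.engine.seed,
            report=report,
            meta={
                "P": self.looping.P,
                "mean_lifetime": self.looping.mean_lifetime,
                "engine": type(self.engine).__name__,
                "N": self.engine.N,
                "acceptance": self.state.acceptance_rate,
            },
        )

    def record_trajectory(self, n_frames: int, every: int) -> Ensemble:
        """Time-resolved (correlated) trajectory for dynamics analysis."""
        n = self.state.n_monomers
        positions = np.empty((n_frames, n, 3), dtype=np.int32)
        times = np.empty(n_frames, dtype=np.int64)
        for k in range(n_frames):
            self.state.run_mcs(every, self.looping, log_events=False)
            positions[k] = self.state.pos
            times[k] = self.state.mc_time
        return Ensemble(
            positions=positions,
            times=times,
            chain_id=self.state.chain_id.copy(),
            L=self.state.L,
            loops=[],
            seed=self.engine.seed,
            meta={"every": every, "kind": "trajectory"},
        )


def contact_decorrelation_time(
    sim: "Simulation",
    n_frames: int = 120,
    every: int | None = None,
) -> float:
    """Decorrelation time of the instantaneous contact pattern (MCS).

    For collapsed ensembles the center of mass can be nearly arrested
    while the contact pattern (the observable that h(l) and Pc(s) are
    built from) still turns over on the loop-lifetime scale.  This
    diagnostic tracks the Jaccard overlap of the contact sets at
    increasing lags and returns the lag at which the excess overlap
    over the long-lag plateau has decayed to 10%.
    """
    from .config import COLOCALIZATION_R2, MIN_CONTOUR_SEPARATION

    lp = sim.looping
    if every is None:
        every = max(500, int(2 * lp.mean_lifetime))
    sets = []
    for _ in range(n_frames):
        sim.state.run_mcs(every, lp, log_events=False)
        pos = sim.state.pos
        cid = sim.state.chain_id
        frame = set()
        view = pos.reshape(sim.state.n_chains, -1, 3)
        for c in range(view.shape[0]):
            p = view[c]
            for sep in range(MIN_CONTOUR_SEPARATION, p.shape[0]):
                d = p[sep:] - p[:-sep]
                sq = (d**2).sum(axis=1)
                for i in np.flatnonzero(sq <= COLOCALIZATION_R2):
                    frame.add((c, int(i), int(i + sep)))
        sets.append(frame)
    lags = [1, 2, 4, 8, 16, 32, 48, 64, 80]
    lags = [lag for lag in lags if lag < n_frames - 4]
    overlap = []
    for lag in lags:
        js = []
        for k in range(0, n_frames - lag, max(1, lag // 2)):
            a, b = sets[k], sets[k + lag]
            u = len(a | b)
            js.append(len(a & b) / u if u else 1.0)
        overlap.append(float(np.mean(js)))
    plateau = float(np.mean(overlap[-2:]))
    excess0 = overlap[0] - plateau
    if excess0 <= 0:
        return float(lags[0] * every)
    for lag, j in zip(lags, overlap):
        if j - plateau <= 0.1 * excess0:
            return float(lag * every)
    return float(lags[-1] * every)


def sample_replicas(
    engine: SystemConfig | MeltConfig,
    looping: LoopParams,
    n_replicas: int,
    samples_per_replica: int,
    interval: int,
    equil_mcs: int = 300_000,
    sampling: SamplingConfig | None = None,
) -> Ensemble:
    """Merged ensemble from independent replicas of one parameter point.

    Each replica starts from its own SAW equilibration (seeds
    engine.seed, engine.seed+1, ...), re-equilibrates with looping on,
    and contributes ``samples_per_replica`` conformations spaced by
    ``interval``.  Replicas are fully independent, so the merged
    ensemble covers the true distribution over dynamical branches even
    when individual trajectories are intermittent or arrested near the
    collapse transition.
    """
    positions = []
    times = []
    loops: list[np.ndarray] = []
    chain_id = None
    Lbox = None
    counts = []
    # one fully equilibrated "mother" SAW run supplies the independent
    # starting conformations (spaced by several relaxation times), so
    # the expensive SAW stage is paid once rather than per replica
    mother = Simulation(engine, LoopParams(), sampling)
    mother.equilibrate_saw()
    saw_spacing = int(4 * engine.N**2.2)
    for r in range(n_replicas):
        if r > 0:
            mother.state.run_mcs(saw_spacing, None, log_events=False)
        sim = Simulation.__new__(Simulation)
        sim.engine = engine
        sim.looping = looping
        sim.sampling = sampling or SamplingConfig()
        sim.state = mother.state.copy()
        sim.state.seed = (engine.seed + 7919 * (r + 1)) % (2**31 - 1)
        sim.state._call_count = 0
        sim.report = None
        sim._saw_equilibrated = True
        if looping.P > 0:
            sim.state.run_mcs(equil_mcs, looping, log_events=False)
        ens = sim.sample(samples_per_replica, interval=interval, burn_in_mcs=0)
        positions.append(ens.positions)
        times.append(ens.times)
        loops.extend(ens.loops)
        chain_id = ens.chain_id
        Lbox = ens.L
        counts.append(ens.mean_loop_count())
    return Ensemble(
        positions=np.concatenate(positions),
        times=np.concatenate(times),
        chain_id=chain_id,
        L=Lbox,
        loops=loops,
        seed=engine.seed,
        meta={
            "P": looping.P,
            "mean_lifetime": looping.mean_lifetime,
            "n_replicas": n_replicas,
            "interval": interval,
            "replica_loop_counts": counts,
        },
    )


def tune_probability(
    engine: SystemConfig | MeltConfig,
    target_loops_per_chain: float,
    mean_lifetime: float,
    P0: float,
    n_replicas: int = 4,
    samples_per_replica: int = 8,
    interval: int | None = None,
    equil_mcs: int = 300_000,
    max_rounds: int = 4,
    rel_tol: float = 0.07,
    p_cap: float = 0.05,
) -> tuple[float, float]:
    """Secant-tune P so the replica-averaged realized count hits a target.

    Short warm pilots underestimate the equilibrium loop count near the
    collapse transition, so each evaluation uses a few independent,
    fully equilibrated replicas.  Returns (P, realized count).
    """
    if interval is None:
        interval = max(int(10 * mean_lifetime), 10_000)
    slope = 2.2
    logP = float(np.log(min(P0, p_cap)))
    prev = None
    best = None
    for rnd in range(max_rounds):
        P = float(np.exp(logP))
        eng = type(engine)(**{**engine.__dict__, "seed": engine.seed + 100 * (rnd + 1)})
        ens = sample_replicas(
            eng,
            LoopParams(P=P, mean_lifetime=mean_lifetime),
            n_replicas,
            samples_per_replica,
            interval,
            equil_mcs=equil_mcs,
        )
        mean = ens.mean_loop_count()
        err = abs(mean - target_loops_per_chain)
        if best is None or err < best[0]:
            best = (err, P, mean)
        if err <= rel_tol * target_loops_per_chain:
            break
        logC = float(np.log(max(mean, 0.05)))
        if prev is not None and abs(logP - prev[0]) > 1e-3:
            est = (logC - prev[1]) / (logP - prev[0])
            # the count-P response flattens near saturation: allow
            # shallow slopes so the secant can still make progress
            if np.isfinite(est) and 0.15 <= est <= 6.0:
                slope = est
        prev = (logP, logC)
        logP = min(
            np.log(p_cap),
            logP + (np.log(target_loops_per_chain) - logC) / slope,
        )
    return best[1], best[2]


def saw_relaxation_time(
    engine: SystemConfig | MeltConfig,
    sampling: SamplingConfig | None = None,
    n_mcs: int | None = None,
) -> float:
    """Integrated autocorrelation time of Rg^2 for the loop-free system.

    This is the reference scale for loop lifetimes (lifetime
    multipliers are quoted relative to it).  The windowed estimator has
    high variance on short pilots; pass a generous ``n_mcs`` when a
    stable value matters.
    """
    sim = Simulation(engine, LoopParams(), sampling)
    sim.equilibrate_saw()
    report = sim.pilot(n_mcs=n_mcs, require_tcm=False)
    return report.tau_int


@dataclass
class CalibrationResult:
    P: float
    achieved_mean: float
    achieved_se: float
    target: float
    history: list[tuple[float, float]]


def measure_mean_loop_count(
    sim: Simulation,
    lp: LoopParams,
    n_windows: int = 24,
    window: float | None = None,
) -> tuple[float, float]:
    """Time-averaged loops per chain with a crude standard error.

    Averages ``n_windows`` block means spaced on the lifetime scale
    (loop occupancy decorrelates on the lifetime).
    """
    if window is None:
        window = max(200, int(lp.mean_lifetime))
    every = max(10, int(window // 10))
    vals = []
    for _ in range(n_windows):
        sim.state.run_mcs(every * 10, lp, log_events=False)
        vals.append(sim.state.n_active_loops / sim.state.n_chains)
    v = np.asarray(vals, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def calibrate_loop_probability(
    engine: SystemConfig | MeltConfig,
    target_loops_per_chain: float,
    mean_lifetime: float,
    rel_tol: float = 0.05,
    p_bounds: tuple[float, float] = (1e-6, 1.0),
    max_iter: int = 12,
    sampling: SamplingConfig | None = None,
    base_params: LoopParams | None = None,
) -> CalibrationResult:
    """Find the looping probability P yielding a target mean loop count.

    The mean number of simultaneously active loops per chain is monotone
    non-decreasing in P at fixed lifetime, so a bisection on log10(P)
    with short warm-started pilot measurements converges quickly.
    """
    if target_loops_per_chain <= 0:
        return CalibrationResult(0.0, 0.0, 0.0, 0.0, [])
    base = base_params or LoopParams()

    def params(p):
        return LoopParams(
            P=p,
            mean_lifetime=mean_lifetime,
            colocalization_radius=base.colocalization_radius,
            min_contour_separation=base.min_contour_separation,
        )

    sim = Simulation(engine, params(p_bounds[0]), sampling)
    sim.equilibrate_saw()
    saw_state = sim.state.copy()
    history: list[tuple[float, float]] = []

    def evaluate(p, n_windows=24):
        lp = params(p)
        # warm restart from the SAW state for every trial P
        sim.state = saw_state.copy()
        sim.looping = lp
        sim.state.run_mcs(int(8 * max(mean_lifetime, 200)), lp, log_events=False)
        mean, se = measure_mean_loop_count(sim, lp, n_windows=n_windows)
        history.append((p, mean))
        return mean, se

    lo, hi = np.log10(p_bounds[0]), np.log10(p_bounds[1])
    m_hi, _ = evaluate(10.0**hi)
    if m_hi < target_loops_per_chain:
        # cannot reach the target even at the upper bound
        return CalibrationResult(10.0**hi, m_hi, 0.0, target_loops_per_chain, history)
    m_lo, _ = evaluate(10.0**lo)
    if m_lo > target_loops_per_chain:
        raise ValueError(
            f"lower bound P={10.0 ** lo:g} already yields {m_lo:.1f} loops "
            f"> target {target_loops_per_chain}"
        )
    best = (10.0**hi, m_hi, 0.0)
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = 10.0**mid
        mean, se = evaluate(p, n_windows=24 if it < max_iter - 2 else 48)
        if abs(mean - target_loops_per_chain) < abs(best[1] - target_loops_per_chain):
            best = (p, mean, se)
        if abs(mean - target_loops_per_chain) <= rel_tol * target_loops_per_chain:
            best = (p, mean, se)
            break
        if mean < target_loops_per_chain:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best[0], best[1], best[2], target_loops_per_chain, history)
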