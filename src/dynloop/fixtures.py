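"""Deterministic toy states and trajectories.

These synthetic fixtures have closed-form observables, so every
analysis routine can be exercised without running a simulation:

* ``rod``           -- a rigid rod of (2,0,0) bonds: R^2(s) = (2s)^2.
* ``dimer``         -- two bonded monomers, for move-rule edge cases.
* ``ballistic``     -- a rod translating at constant velocity:
                       g3(t) = (v t)^2, log-log slope exactly 2.
* ``loop_log``      -- a hand-checkable 10-event loop log.
"""

from __future__ import annotations

import numpy as np

from .simulate import Ensemble
from .state import SystemState


def rod_positions(n_beads: int = 32, n_frames: int = 40) -> Ensemble:
    """Static rigid rod along x with (2,0,0) bonds, repeated frames."""
    pos = np.zeros((n_beads, 3), dtype=np.int32)
    pos[:, 0] = 2 * np.arange(n_beads)
    positions = np.repeat(pos[None], n_frames, axis=0)
    return Ensemble(
        positions=positions,
        times=np.arange(n_frames, dtype=np.int64),
        chain_id=np.zeros(n_beads, dtype=np.int32),
        L=(128, 128, 128),
        loops=[np.empty((0, 2), dtype=np.int64)] * n_frames,
        seed=0,
        meta={"fixture": "rod"},
    )


def dimer_state(bond=(2, 0, 0), L: int = 32, seed: int = 0) -> SystemState:
    """Two bonded monomers with a chosen bond vector."""
    pos = np.array([[4, 4, 4], [4 + bond[0], 4 + bond[1], 4 + bond[2]]])
    return SystemState(pos, np.zeros(2, dtype=np.int32), (L, L, L), seed=seed)


def ballistic_trajectory(
    n_beads: int = 8, n_frames: int = 64, velocity: int = 1, dt: int = 1
) -> Ensemble:
    """Rod translating at constant velocity: exactly diffusion exponent 2."""
    base = np.zeros((n_beads, 3), dtype=np.int64)
    base[:, 0] = 2 * np.arange(n_beads)
    frames = np.array(
        [base + np.array([0, 0, velocity * dt * k]) for k in range(n_frames)],
        dtype=np.int32,
    )
    return Ensemble(
        positions=frames,
        times=dt * np.arange(n_frames, dtype=np.int64),
        chain_id=np.zeros(n_beads, dtype=np.int32),
        L=(128, 128, 128),
        loops=[],
        seed=0,
        meta={"fixture": "ballistic", "velocity": velocity},
    )


#: loop log with hand-computed time-averaged occupancy:
#: over the window [0, 100], total active time is
#: 50+30+100+20+40+10+60+25+35+80 = 450, hence mean count 4.5
HAND_LOOP_LOG = [
    (0, 50, 0, 10),
    (10, 40, 2, 12),
    (0, 100, 5, 25),
    (30, 50, 7, 17),
    (50, 90, 1, 21),
    (90, 100, 3, 13),
    (20, 80, 8, 18),
    (25, 50, 4, 24),
    (60, 95, 6, 16),
    (10, 90, 9, 29),
]
HAND_LOOP_LOG_MEAN = 4.5
HAND_LOOP_LOG_WINDOW = (0, 100)


def interdigitated_rods(n_beads: int = 8, L: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Two parallel rods at transverse spacing 2 (every bead in contact).

    Returns (positions, chain_id) for a hand-countable inter-chain
    contact construction: bead k of one rod sits at distance 2 from
    beads k-1, k, k+1 of the other (squared distances 8, 4, 8).
    """
    rod = np.zeros((n_beads, 3), dtype=np.int64)
    rod[:, 0] = 2 * np.arange(n_beads)
    other = rod.copy()
    other[:, 1] += 2
    pos = np.concatenate([rod, other])
    chain_id = np.repeat([0, 1], n_beads).astype(np.int32)
    return pos, chain_id


def ar1_series(phi: float, n: int, seed: int = 0, sigma: float = 1.0) -> np.ndarray:
    """AR(1) series with known ACF rho(t) = phi^t and tau_int = (1+phi)/(2(1-phi))."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0, sigma / np.sqrt(1 - phi**2))
    eps = rng.normal(0, sigma, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x
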