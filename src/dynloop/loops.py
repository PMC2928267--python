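"""Loop lifetime draws and loop-log bookkeeping.

The compiled engine draws lifetimes internally; the functions here are
the reference implementations used for analysis and testing, plus the
observables defined directly on loop event logs.
"""

from __future__ import annotations

import numpy as np

from .config import LoopParams
from .state import Loop

__all__ = ["draw_lifetime", "mean_loop_count", "loop_log_to_array"]


def draw_lifetime(params: LoopParams, rng: np.random.Generator) -> int:
    """One Poisson-distributed loop lifetime (MCS) with mean tau_life."""
    if params.mean_lifetime < 0:
        raise ValueError("mean lifetime must be >= 0")
    if params.mean_lifetime == 0:
        return 0
    return int(rng.poisson(params.mean_lifetime))


def loop_log_to_array(log) -> np.ndarray:
    """Normalize a loop event log to an (n, 4) array.

    Rows are (created_at, expires_at, i, j); accepts lists of tuples,
    lists of :class:`Loop` records, or an array.
    """
    if len(log) == 0:
        return np.empty((0, 4), dtype=np.int64)
    first = log[0]
    if isinstance(first, Loop):
        rows = [(lp.created_at, lp.expires_at, lp.i, lp.j) for lp in log]
        return np.asarray(rows, dtype=np.int64)
    return np.asarray(log, dtype=np.int64).reshape(-1, 4)


def mean_loop_count(log, t0: int | None = None, t1: int | None = None) -> float:
    """Time-averaged number of simultaneously active loops.

    Integrates the occupancy of a loop event log (created_at,
    expires_at, i, j) over the observation window [t0, t1]; by default
    the window spans the first creation to the last expiry.
    """
    arr = loop_log_to_array(log)
    if arr.shape[0] == 0:
        raise ValueError("empty loop log")
    if t0 is None:
        t0 = int(arr[:, 0].min())
    if t1 is None:
        t1 = int(arr[:, 1].max())
    if t1 <= t0:
        raise ValueError("empty observation window")
    start = np.clip(arr[:, 0], t0, t1)
    stop = np.clip(arr[:, 1], t0, t1)
    return float((stop - start).sum() / (t1 - t0))
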