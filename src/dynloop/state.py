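"""Lattice system state: construction, moves, loops, validation.

:class:`SystemState` owns the coordinate, occupancy and loop arrays and
delegates all hot work to the compiled kernel.  Chains are stored
contiguously, so the contour separation of two same-chain monomers is
simply the difference of their indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import _kernel
from ._kernel import KMAX, N_COUNTERS, lattice_geometry
from .bond_vectors import generate_bond_vectors
from .config import LoopParams, MeltConfig, SystemConfig

_BOND_SET = generate_bond_vectors()
_BOND_LUT = _BOND_SET.lookup_table()


class MoveReason(Enum):
    OK = 0
    EXCLUDED_VOLUME = 1
    BOND_VIOLATION = 2
    LOOP_CONSTRAINT = 3


@dataclass(frozen=True)
class MoveResult:
    accepted: bool
    reason: MoveReason

    @classmethod
    def from_code(cls, code: int) -> "MoveResult":
        reason = MoveReason(code)
        return cls(accepted=reason is MoveReason.OK, reason=reason)


@dataclass(frozen=True)
class Loop:
    """An active loop: a lifetime-bearing co-localization constraint."""

    chain: int
    i: int
    j: int
    created_at: int
    expires_at: int

    @property
    def size(self) -> int:
        return self.j - self.i


class InvariantError(RuntimeError):
    """A state invariant was violated."""


class PlacementError(RuntimeError):
    """The requested chains do not fit into the box."""


#: directions accepted by attempt_move
DIRECTIONS = {
    (1, 0, 0): (0, 1),
    (-1, 0, 0): (0, -1),
    (0, 1, 0): (1, 1),
    (0, -1, 0): (1, -1),
    (0, 0, 1): (2, 1),
    (0, 0, -1): (2, -1),
}


class SystemState:
    """Full lattice state of one or more bond-fluctuation chains."""

    def __init__(self, pos: np.ndarray, chain_id: np.ndarray, L, seed: int = 0):
        pos = np.ascontiguousarray(np.asarray(pos, dtype=np.int64))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("pos must be (n, 3)")
        self.L = tuple(int(x) for x in (L if np.ndim(L) else (L, L, L)))
        self._Larr = np.array(self.L, dtype=np.int64)
        self.pos = pos
        self.chain_id = np.ascontiguousarray(np.asarray(chain_id, dtype=np.int32))
        n = self.n_monomers
        self.fpos = np.ascontiguousarray(self.pos % self._Larr)
        self.seed = int(seed)
        self.mc_time = 0
        self._call_count = 0

        self.bonded_prev = np.zeros(n, dtype=np.bool_)
        self.bonded_next = np.zeros(n, dtype=np.bool_)
        self.bonded_prev[1:] = self.chain_id[1:] == self.chain_id[:-1]
        self.bonded_next[:-1] = self.chain_id[1:] == self.chain_id[:-1]

        if n >= 32000:
            raise ValueError("at most 32000 monomers are supported")
        self.geom = np.array(lattice_geometry(self.L), dtype=np.int64)
        nsites = int(np.prod(self.L))
        self.site = np.full(nsites, -1, dtype=np.int16)
        self._build_lattice()

        self.partners = np.full((n, KMAX), -1, dtype=np.int32)
        self.pexp = np.zeros((n, KMAX), dtype=np.int64)
        self.pborn = np.zeros((n, KMAX), dtype=np.int64)
        self.ninc = np.zeros(n, dtype=np.int32)
        self.counters = np.zeros(N_COUNTERS, dtype=np.int64)
        self.loop_log: list[tuple[int, int, int, int]] = []  # (created, expires, i, j)
        self.dropped_events = 0

    # -- construction -------------------------------------------------

    def _flat(self, x, y, z):
        mx, my, mz, shx, shy = self.geom
        return ((x & mx) << shx) | ((y & my) << shy) | (z & mz)

    @property
    def occupancy(self) -> np.ndarray:
        """Boolean per-site occupancy, shaped like the box."""
        return (self.site != -1).reshape(self.L)

    @property
    def anchor_map(self) -> np.ndarray:
        """Per-site anchored monomer id (-1 where none), shaped like the box."""
        a = np.where(self.site >= 0, self.site, -1).astype(np.int32)
        return a.reshape(self.L)

    def _build_lattice(self) -> None:
        for m in range(self.n_monomers):
            fx, fy, fz = (int(v) for v in self.fpos[m])
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        idx = self._flat(fx + dx, fy + dy, fz + dz)
                        if self.site[idx] == -1:
                            self.site[idx] = -2
            idx = self._flat(fx, fy, fz)
            if self.site[idx] >= 0:
                raise InvariantError(f"two monomers anchored at {(fx, fy, fz)}")
            self.site[idx] = m

    @property
    def n_monomers(self) -> int:
        return self.pos.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_monomers else 0

    def chain_slice(self, chain: int) -> slice:
        idx = np.flatnonzero(self.chain_id == chain)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def copy(self) -> "SystemState":
        new = SystemState.__new__(SystemState)
        new.__dict__.update(
            {
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )
        new.loop_log = list(self.loop_log)
        return new

    # -- randomness ---------------------------------------------------

    def _next_stream(self) -> int:
        """Derive a fresh (deterministic) kernel RNG stream for this call."""
        self._call_count += 1
        return (self.seed * 1000003 + self._call_count * 7919) % (2**31 - 1)

    # -- single operations (unit-testable) ----------------------------

    def attempt_move(self, monomer: int, direction, radius_sq: int = 8) -> MoveResult:
        """Attempt a single-lattice-unit move of one monomer."""
        key = tuple(int(x) for x in direction)
        if key not in DIRECTIONS:
            raise ValueError(f"direction must be a unit axis vector, got {direction}")
        ax, sgn = DIRECTIONS[key]
        code = _kernel.try_move(
            self.pos,
            self.fpos,
            self.site,
            self.bonded_prev,
            self.bonded_next,
            _BOND_LUT,
            self.partners,
            self.ninc,
            self.geom,
            radius_sq,
            monomer,
            ax,
            sgn,
        )
        return MoveResult.from_code(code)

    def attempt_loop_formation(self, params: LoopParams, monomer: int | None = None):
        """One formation probe; returns the created :class:`Loop` or None."""
        _kernel.seed_rng(self._next_stream())
        if monomer is None:
            monomer = int(np.random.default_rng(self._next_stream()).integers(self.n_monomers))
        rows = _kernel.scan_rows(params.radius_sq)
        cand = np.empty(int((rows[:, 3] - rows[:, 2] + 1).sum()), dtype=np.int64)
        ev = _make_event_buffers(4)
        before = self.counters[_kernel.C_EVENTS]
        self.counters[_kernel.C_EVENTS] = 0
        created = _kernel.attempt_formation(
            self.pos,
            self.fpos,
            self.site,
            self.chain_id,
            self.partners,
            self.pexp,
            self.pborn,
            self.ninc,
            rows,
            cand,
            self.geom,
            params.radius_sq,
            params.P,
            params.mean_lifetime,
            params.min_contour_separation,
            self.mc_time,
            *ev,
            self.counters,
            monomer,
        )
        got = None
        if created:
            i, j, t0, t1 = int(ev[0][0]), int(ev[1][0]), int(ev[2][0]), int(ev[3][0])
            self.loop_log.append((t0, t1, i, j))
            got = Loop(chain=int(self.chain_id[i]), i=i, j=j, created_at=t0, expires_at=t1)
        self.counters[_kernel.C_EVENTS] = before
        return got

    def expire_loops(self) -> int:
        """Remove every loop whose expiry is due; returns loops removed."""
        removed = _kernel.expire_loops_kernel(
            self.partners, self.pexp, self.pborn, self.ninc, self.mc_time
        )
        self.counters[_kernel.C_REMOVED] += removed
        self.counters[_kernel.C_ACTIVE] -= removed
        return removed

    # -- bulk evolution ------------------------------------------------

    def run_mcs(
        self,
        n_mcs: int,
        loop_params: LoopParams | None = None,
        log_events: bool = True,
        max_events: int | None = None,
    ) -> "SystemState":
        """Advance the system by ``n_mcs`` Monte Carlo steps in place."""
        if n_mcs < 0:
            raise ValueError("n_mcs must be >= 0")
        if n_mcs == 0:
            return self
        lp = loop_params or LoopParams()
        rows = _kernel.scan_rows(lp.radius_sq)
        cand = np.empty(int((rows[:, 3] - rows[:, 2] + 1).sum()), dtype=np.int64)
        if max_events is None:
            max_events = 200_000 if log_events else 0
        ev = _make_event_buffers(max(max_events, 1))
        self.counters[_kernel.C_EVENTS] = 0
        self.counters[_kernel.C_DROPPED] = 0
        _kernel.seed_rng(self._next_stream())
        self.mc_time = _kernel.run_mcs_kernel(
            self.pos,
            self.fpos,
            self.site,
            self.chain_id,
            self.bonded_prev,
            self.bonded_next,
            _BOND_LUT,
            self.partners,
            self.pexp,
            self.pborn,
            self.ninc,
            rows,
            cand,
            self.geom,
            lp.P,
            lp.mean_lifetime,
            lp.min_contour_separation,
            lp.radius_sq,
            int(n_mcs),
            self.mc_time,
            *ev,
            self.counters,
        )
        ne = int(self.counters[_kernel.C_EVENTS])
        if log_events and ne:
            ev_i, ev_j, ev_t0, ev_t1 = ev
            self.loop_log.extend(
                zip(
                    ev_t0[:ne].tolist(),
                    ev_t1[:ne].tolist(),
                    ev_i[:ne].tolist(),
                    ev_j[:ne].tolist(),
                )
            )
        self.dropped_events += int(self.counters[_kernel.C_DROPPED])
        return self

    # -- queries -------------------------------------------------------

    def active_loops(self) -> list[Loop]:
        loops = []
        for m in range(self.n_monomers):
            for t in range(self.ninc[m]):
                q = int(self.partners[m, t])
                if q > m:
                    loops.append(
                        Loop(
                            chain=int(self.chain_id[m]),
                            i=m,
                            j=q,
                            created_at=int(self.pborn[m, t]),
                            expires_at=int(self.pexp[m, t]),
                        )
                    )
        return loops

    @property
    def n_active_loops(self) -> int:
        return int(self.ninc.sum()) // 2

    @property
    def acceptance_rate(self) -> float:
        att = int(self.counters[_kernel.C_ATTEMPTED])
        return int(self.counters[_kernel.C_ACCEPTED]) / att if att else 0.0

    def rg2(self, chain: int | None = None) -> float:
        """Squared radius of gyration (unfolded coordinates)."""
        p = self.pos if chain is None else self.pos[self.chain_slice(chain)]
        c = p.mean(axis=0)
        return float(((p - c) ** 2).sum(axis=1).mean())

    def center_of_mass(self, chain: int | None = None) -> np.ndarray:
        p = self.pos if chain is None else self.pos[self.chain_slice(chain)]
        return p.mean(axis=0)

    # -- validation ----------------------------------------------------

    def validate(self, check_loops: bool = True, radius_sq: int = 8) -> None:
        """Check every structural invariant; raises :class:`InvariantError`."""
        L = self._Larr
        if np.any(self.fpos != self.pos % L):
            raise InvariantError("folded != unfolded mod L")
        # excluded volume: re-derive occupancy from scratch
        seen: dict[tuple[int, int, int], int] = {}
        for m in range(self.n_monomers):
            fx, fy, fz = (int(v) for v in self.fpos[m])
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        site = ((fx + dx) % L[0], (fy + dy) % L[1], (fz + dz) % L[2])
                        if site in seen:
                            raise InvariantError(
                                f"monomers {seen[site]} and {m} share site {site}"
                            )
                        seen[site] = m
        if int((self.site != -1).sum()) != len(seen):
            raise InvariantError("occupancy array inconsistent with coordinates")
        # bonds
        bonds = np.diff(self.pos, axis=0)
        same = self.chain_id[1:] == self.chain_id[:-1]
        for k in np.flatnonzero(same):
            if tuple(int(v) for v in bonds[k]) not in _BOND_SET:
                raise InvariantError(f"illegal bond {bonds[k]} between {k} and {k + 1}")
        if check_loops:
            for lp in self.active_loops():
                if self.chain_id[lp.i] != self.chain_id[lp.j]:
                    raise InvariantError("loop endpoints on different chains")
                d = self.pos[lp.i] - self.pos[lp.j]
                if int((d**2).sum()) > radius_sq:
                    raise InvariantError(
                        f"loop ({lp.i},{lp.j}) violates the distance constraint"
                    )


def _make_event_buffers(n: int):
    return (
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# construction of legal initial states


def _serpentine_anchors(n: int, box, origin=(0, 0, 0)):
    """Anchor positions for ``n`` monomers on a spacing-2 serpentine path.

    Rows run along x, fold back along y, stack along z.  Consecutive
    anchors differ by (+-2,0,0), (0,2,0) or (0,0,2) -- all legal bonds --
    and the 2x2x2 cubes tile space without overlap.
    """
    Lx, Ly, Lz = box
    per_row = Lx // 2
    rows_per_plane = Ly // 2
    if per_row < 1 or rows_per_plane < 1 or Lz < 2:
        raise PlacementError("box too small")
    if n > per_row * rows_per_plane * (Lz // 2):
        raise PlacementError(
            f"cannot place {n} monomers in box {box}: capacity "
            f"{per_row * rows_per_plane * (Lz // 2)}"
        )
    out = np.empty((n, 3), dtype=np.int64)
    ox, oy, oz = origin
    for m in range(n):
        plane, rem = divmod(m, per_row * rows_per_plane)
        row, col = divmod(rem, per_row)
        if row % 2 == 1:  # fold back so consecutive anchors stay bonded
            col = per_row - 1 - col
        if plane % 2 == 1:
            row = rows_per_plane - 1 - row
            if rows_per_plane % 2 == 1:
                col = per_row - 1 - col
        out[m] = (ox + 2 * col, oy + 2 * row, oz + 2 * plane)
    return out


def init_saw_chain(config: SystemConfig, N: int | None = None) -> SystemState:
    """A legal (not equilibrated) single-chain state.

    The chain is laid out as a regular serpentine of (2,0,0)/(0,2,0)
    bonds; equilibration into a self-avoiding walk is a separate run.
    """
    N = config.N if N is None else N
    if N < 2:
        raise ValueError("N must be >= 2")
    pos = _serpentine_anchors(N, config.L)
    state = SystemState(pos, np.zeros(N, dtype=np.int32), config.L, seed=config.seed)
    state.validate()
    return state


def build_melt(config: MeltConfig) -> SystemState:
    """A legal dense multi-chain state on one global serpentine path.

    Chains are consecutive segments of the path, hence non-overlapping
    by construction; randomization is the caller's burn-in run.
    """
    total = config.total_monomers
    pos = _serpentine_anchors(total, config.box)
    chain_id = np.repeat(np.arange(config.n_chains, dtype=np.int32), config.N)
    state = SystemState(pos, chain_id, config.box, seed=config.seed)
    state.validate()
    return state
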