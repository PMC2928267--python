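"""Compiled bond-fluctuation-model kernel.

All hot loops live here as numba-jitted functions operating on plain
arrays; :mod:`dynloop.state` wraps them in a friendly container.  The
kernel is single-threaded and fully deterministic given the seed fed to
:func:`seed_rng` (numba keeps its own Mersenne-Twister state, separate
from numpy's global one).

Conventions:

* monomer positions are *unfolded* integer coordinates ``pos``; the
  folded image ``fpos = pos mod L`` indexes the occupancy and anchor
  lattices;
* box edges must be powers of two so that folding and minimum-image
  arithmetic reduce to bit masks; the lattices are flat arrays indexed
  by ``((x & mx) << shx) | ((y & my) << shy) | (z & mz)``;
* each monomer covers the 2x2x2 site cube with lower corner at its
  folded position; one int16 ``site`` array serves both as occupancy
  flag and anchor map: -1 = empty, -2 = covered but not an anchor,
  otherwise the id of the monomer anchored (folded position) there;
* active loops are stored symmetrically in fixed-width per-monomer
  partner lists; a loop is a hard constraint keeping the pair within the
  co-localization radius.

Move-result codes: 0 = OK, 1 = EXCLUDED_VOLUME, 2 = BOND_VIOLATION,
3 = LOOP_CONSTRAINT.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: maximum number of simultaneous loops per monomer
KMAX = 24

#: counter slots used by :func:`run_mcs_kernel`
C_EVENTS, C_DROPPED, C_ACCEPTED, C_ATTEMPTED, C_REMOVED, C_ACTIVE, C_OVERFLOW = range(7)
N_COUNTERS = 8


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


def lattice_geometry(L):
    """(mx, my, mz, shx, shy) bit-mask geometry for a power-of-two box."""
    Lx, Ly, Lz = (int(v) for v in L)
    for v in (Lx, Ly, Lz):
        if v < 8 or v & (v - 1):
            raise ValueError(f"box edges must be powers of two >= 8, got {L}")
    lz = Lz.bit_length() - 1
    ly = Ly.bit_length() - 1
    return Lx - 1, Ly - 1, Lz - 1, ly + lz, lz


def scan_rows(radius_sq: int) -> np.ndarray:
    """(dx, dy, dz_lo, dz_hi) rows covering the co-localization ball.

    Grouping the neighbourhood scan by (dx, dy) row keeps the innermost
    loop contiguous in the flat lattice arrays.
    """
    r = int(np.floor(np.sqrt(radius_sq)))
    rows = []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            rem = radius_sq - dx * dx - dy * dy
            if rem < 0:
                continue
            dz = int(np.floor(np.sqrt(rem)))
            rows.append((dx, dy, -dz, dz))
    return np.array(rows, dtype=np.int64)


@njit(cache=True, inline="always")
def _minimg(d, mask, L):
    d = d & mask
    if d > L >> 1:
        d -= L
    return d


@njit(cache=True)
def try_move(
    pos,
    fpos,
    site,
    bonded_prev,
    bonded_next,
    bond_lut,
    partners,
    ninc,
    geom,
    radius_sq,
    m,
    ax,
    sgn,
):
    """Attempt to move monomer ``m`` by one lattice unit along axis ``ax``.

    Mutates the state arrays only when the move is legal.  Returns the
    move-result code.
    """
    mx = geom[0]
    my = geom[1]
    mz = geom[2]
    shx = geom[3]
    shy = geom[4]

    qx = pos[m, 0]
    qy = pos[m, 1]
    qz = pos[m, 2]
    if ax == 0:
        qx += sgn
    elif ax == 1:
        qy += sgn
    else:
        qz += sgn

    # bond vectors to chain neighbours (unfolded coordinates, exact)
    if bonded_prev[m]:
        vx = pos[m - 1, 0] - qx
        vy = pos[m - 1, 1] - qy
        vz = pos[m - 1, 2] - qz
        if vx < -3 or vx > 3 or vy < -3 or vy > 3 or vz < -3 or vz > 3:
            return 2
        if bond_lut[(vx + 3) * 49 + (vy + 3) * 7 + (vz + 3)] == 0:
            return 2
    if bonded_next[m]:
        vx = pos[m + 1, 0] - qx
        vy = pos[m + 1, 1] - qy
        vz = pos[m + 1, 2] - qz
        if vx < -3 or vx > 3 or vy < -3 or vy > 3 or vz < -3 or vz > 3:
            return 2
        if bond_lut[(vx + 3) * 49 + (vy + 3) * 7 + (vz + 3)] == 0:
            return 2

    fqx = qx & mx
    fqy = qy & my
    fqz = qz & mz

    # every incident loop must stay within the co-localization radius;
    # loop distances are true (unfolded) same-chain distances, so the
    # chain never feels the periodic box through its loops
    k = ninc[m]
    for t in range(k):
        q = partners[m, t]
        dx = pos[q, 0] - qx
        dy = pos[q, 1] - qy
        dz = pos[q, 2] - qz
        if dx * dx + dy * dy + dz * dz > radius_sq:
            return 3

    # excluded volume: the 4 sites newly covered by the advancing face
    fx = fpos[m, 0]
    fy = fpos[m, 1]
    fz = fpos[m, 2]
    if ax == 0:
        new_p = (fx + 2) & mx if sgn > 0 else (fx - 1) & mx
        old_p = fx if sgn > 0 else (fx + 1) & mx
        a0 = fy
        a1 = (fy + 1) & my
        b0 = fz
        b1 = (fz + 1) & mz
        i00 = (new_p << shx) | (a0 << shy) | b0
        i01 = (new_p << shx) | (a0 << shy) | b1
        i10 = (new_p << shx) | (a1 << shy) | b0
        i11 = (new_p << shx) | (a1 << shy) | b1
        if site[i00] != -1 or site[i01] != -1 or site[i10] != -1 or site[i11] != -1:
            return 1
        j00 = (old_p << shx) | (a0 << shy) | b0
        j01 = (old_p << shx) | (a0 << shy) | b1
        j10 = (old_p << shx) | (a1 << shy) | b0
        j11 = (old_p << shx) | (a1 << shy) | b1
    elif ax == 1:
        new_p = (fy + 2) & my if sgn > 0 else (fy - 1) & my
        old_p = fy if sgn > 0 else (fy + 1) & my
        a0 = fx
        a1 = (fx + 1) & mx
        b0 = fz
        b1 = (fz + 1) & mz
        i00 = (a0 << shx) | (new_p << shy) | b0
        i01 = (a0 << shx) | (new_p << shy) | b1
        i10 = (a1 << shx) | (new_p << shy) | b0
        i11 = (a1 << shx) | (new_p << shy) | b1
        if site[i00] != -1 or site[i01] != -1 or site[i10] != -1 or site[i11] != -1:
            return 1
        j00 = (a0 << shx) | (old_p << shy) | b0
        j01 = (a0 << shx) | (old_p << shy) | b1
        j10 = (a1 << shx) | (old_p << shy) | b0
        j11 = (a1 << shx) | (old_p << shy) | b1
    else:
        new_p = (fz + 2) & mz if sgn > 0 else (fz - 1) & mz
        old_p = fz if sgn > 0 else (fz + 1) & mz
        a0 = fx
        a1 = (fx + 1) & mx
        b0 = fy
        b1 = (fy + 1) & my
        i00 = (a0 << shx) | (b0 << shy) | new_p
        i01 = (a0 << shx) | (b1 << shy) | new_p
        i10 = (a1 << shx) | (b0 << shy) | new_p
        i11 = (a1 << shx) | (b1 << shy) | new_p
        if site[i00] != -1 or site[i01] != -1 or site[i10] != -1 or site[i11] != -1:
            return 1
        j00 = (a0 << shx) | (b0 << shy) | old_p
        j01 = (a0 << shx) | (b1 << shy) | old_p
        j10 = (a1 << shx) | (b0 << shy) | old_p
        j11 = (a1 << shx) | (b1 << shy) | old_p

    # vacated plane becomes empty, advancing plane covered
    site[j00] = -1
    site[j01] = -1
    site[j10] = -1
    site[j11] = -1
    site[i00] = -2
    site[i01] = -2
    site[i10] = -2
    site[i11] = -2
    if sgn < 0:
        # the old anchor site stays covered by the shifted cube
        site[(fx << shx) | (fy << shy) | fz] = -2
    site[(fqx << shx) | (fqy << shy) | fqz] = m
    pos[m, 0] = qx
    pos[m, 1] = qy
    pos[m, 2] = qz
    fpos[m, 0] = fqx
    fpos[m, 1] = fqy
    fpos[m, 2] = fqz
    return 0


@njit(cache=True)
def attempt_formation(
    pos,
    fpos,
    site,
    chain_id,
    partners,
    pexp,
    pborn,
    ninc,
    rows,
    cand,
    geom,
    radius_sq,
    P,
    tau_life,
    min_sep,
    mc_time,
    ev_i,
    ev_j,
    ev_t0,
    ev_t1,
    counters,
    a,
):
    """One loop-formation probe at monomer ``a``.

    A loop forms with probability P per probe, with the partner chosen
    uniformly among the eligible co-localized monomers.  The Bernoulli(P)
    draw is independent of the neighbourhood scan, so it is taken first
    and the scan is skipped on failure -- the per-probe formation law is
    identical, most probes become O(1).  Returns 1 if a loop was created.
    """
    if P < 1.0 and np.random.random() >= P:
        return 0
    return _form_loop(
        pos, fpos, site, chain_id, partners, pexp, pborn, ninc, rows, cand, geom,
        radius_sq, tau_life, min_sep, mc_time, ev_i, ev_j, ev_t0, ev_t1, counters, a,
    )


@njit(cache=True)
def _form_loop(
    pos,
    fpos,
    site,
    chain_id,
    partners,
    pexp,
    pborn,
    ninc,
    rows,
    cand,
    geom,
    radius_sq,
    tau_life,
    min_sep,
    mc_time,
    ev_i,
    ev_j,
    ev_t0,
    ev_t1,
    counters,
    a,
):
    """Scan, pick a partner uniformly, and create the loop (post-Bernoulli).

    The lattice scan nominates candidates by folded proximity; the
    co-localization test itself uses the unfolded distance, so segments
    that only meet through a periodic image never loop.
    """
    mx = geom[0]
    my = geom[1]
    mz = geom[2]
    shx = geom[3]
    shy = geom[4]
    Lz = mz + 1
    fx = fpos[a, 0]
    fy = fpos[a, 1]
    fz = fpos[a, 2]
    ncand = 0
    for r in range(rows.shape[0]):
        x = (fx + rows[r, 0]) & mx
        y = (fy + rows[r, 1]) & my
        base = (x << shx) | (y << shy)
        z_lo = fz + rows[r, 2]
        z_hi = fz + rows[r, 3]
        if z_lo >= 0 and z_hi < Lz:  # contiguous fast path
            for z in range(z_lo, z_hi + 1):
                q = site[base | z]
                if q >= 0 and q != a:
                    cand[ncand] = q
                    ncand += 1
        else:
            for z in range(z_lo, z_hi + 1):
                q = site[base | (z & mz)]
                if q >= 0 and q != a:
                    cand[ncand] = q
                    ncand += 1
    # filter: same chain, contour separation, true distance, not already looped
    nval = 0
    for t in range(ncand):
        q = cand[t]
        if chain_id[q] != chain_id[a]:
            continue
        sep = q - a
        if sep < 0:
            sep = -sep
        if sep < min_sep:
            continue
        dx = pos[q, 0] - pos[a, 0]
        dy = pos[q, 1] - pos[a, 1]
        dz = pos[q, 2] - pos[a, 2]
        if dx * dx + dy * dy + dz * dz > radius_sq:
            continue
        dup = False
        for u in range(ninc[a]):
            if partners[a, u] == q:
                dup = True
                break
        if dup:
            continue
        cand[nval] = q
        nval += 1
    if nval == 0:
        return 0
    q = cand[np.random.randint(0, nval)] if nval > 1 else cand[0]
    if ninc[a] >= KMAX or ninc[q] >= KMAX:
        counters[C_OVERFLOW] += 1
        return 0
    lifetime = np.random.poisson(tau_life) if tau_life > 0.0 else 0
    expires = mc_time + lifetime
    partners[a, ninc[a]] = q
    pexp[a, ninc[a]] = expires
    pborn[a, ninc[a]] = mc_time
    ninc[a] += 1
    partners[q, ninc[q]] = a
    pexp[q, ninc[q]] = expires
    pborn[q, ninc[q]] = mc_time
    ninc[q] += 1
    counters[C_ACTIVE] += 1
    ne = counters[C_EVENTS]
    if ne < ev_i.shape[0]:
        i = a if a < q else q
        j = q if a < q else a
        ev_i[ne] = i
        ev_j[ne] = j
        ev_t0[ne] = mc_time
        ev_t1[ne] = expires
        counters[C_EVENTS] = ne + 1
    else:
        counters[C_DROPPED] += 1
    return 1


@njit(cache=True)
def expire_loops_kernel(partners, pexp, pborn, ninc, mc_time):
    """Remove every loop with expires_at <= mc_time.

    Both symmetric list entries of a loop carry the same expiry, so one
    sweep removes both; the number of loops removed is half the number
    of entries dropped.  Idempotent at fixed mc_time.
    """
    entries = 0
    n = partners.shape[0]
    for m in range(n):
        t = 0
        while t < ninc[m]:
            if pexp[m, t] <= mc_time:
                last = ninc[m] - 1
                partners[m, t] = partners[m, last]
                pexp[m, t] = pexp[m, last]
                pborn[m, t] = pborn[m, last]
                ninc[m] = last
                entries += 1
            else:
                t += 1
    return entries // 2


@njit(cache=True)
def run_mcs_kernel(
    pos,
    fpos,
    site,
    chain_id,
    bonded_prev,
    bonded_next,
    bond_lut,
    partners,
    pexp,
    pborn,
    ninc,
    rows,
    cand,
    geom,
    P,
    tau_life,
    min_sep,
    radius_sq,
    n_mcs,
    mc_time,
    ev_i,
    ev_j,
    ev_t0,
    ev_t1,
    counters,
):
    """Run ``n_mcs`` Monte Carlo steps (one attempted move per monomer each).

    After every trial move one formation probe is made when looping is
    enabled; expired loops are swept once per MCS.  Returns the advanced
    Monte Carlo clock.
    """
    n = pos.shape[0]
    do_loops = P > 0.0
    for _ in range(n_mcs):
        for _ in range(n):
            m = np.random.randint(0, n)
            d = np.random.randint(0, 6)
            ax = d >> 1
            sgn = 1 if (d & 1) == 0 else -1
            r = try_move(
                pos,
                fpos,
                site,
                bonded_prev,
                bonded_next,
                bond_lut,
                partners,
                ninc,
                geom,
                radius_sq,
                m,
                ax,
                sgn,
            )
            counters[C_ATTEMPTED] += 1
            if r == 0:
                counters[C_ACCEPTED] += 1
            if do_loops:
                a = np.random.randint(0, n)
                if P >= 1.0 or np.random.random() < P:
                    _form_loop(
                        pos,
                        fpos,
                        site,
                        chain_id,
                        partners,
                        pexp,
                        pborn,
                        ninc,
                        rows,
                        cand,
                        geom,
                        radius_sq,
                        tau_life,
                        min_sep,
                        mc_time,
                        ev_i,
                        ev_j,
                        ev_t0,
                        ev_t1,
                        counters,
                        a,
                    )
        mc_time += 1
        if do_loops or counters[C_ACTIVE] > 0:
            removed = expire_loops_kernel(partners, pexp, pborn, ninc, mc_time)
            counters[C_REMOVED] += removed
            counters[C_ACTIVE] -= removed
    return mc_time


@njit(cache=True)
def draw_poisson(lam, size):
    out = np.empty(size, dtype=np.int64)
    for i in range(size):
        out[i] = np.random.poisson(lam) if lam > 0.0 else 0
    return out
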