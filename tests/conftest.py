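"""Shared fixtures: small states, brute-force reference rules.

The reference implementations here are deliberately independent of the
package internals: bond legality is decided by the squared-length test,
excluded volume by explicit cube-overlap checks on raw coordinates.
They serve as oracles for the compiled engine.
"""

from __future__ import annotations

import numpy as np
import pytest

from dynloop import LoopParams, SystemConfig, SystemState, init_saw_chain

# squared bond lengths realised by the bond-fluctuation move set
REF_LENGTHS_SQ = {4, 5, 6, 9, 10}


def ref_bond_ok(v) -> bool:
    """Reference bond test: integer vector with squared length in the set."""
    v = np.asarray(v, dtype=int)
    return int((v**2).sum()) in REF_LENGTHS_SQ


def ref_cubes_overlap(a, b) -> bool:
    """Do the 2x2x2 cubes anchored at a and b share a lattice site?"""
    d = np.abs(np.asarray(a, dtype=int) - np.asarray(b, dtype=int))
    return bool(np.all(d < 2))


def ref_state_ok(pos, chain_id=None) -> bool:
    """Reference full-state check on unfolded coordinates (dilute box)."""
    pos = np.asarray(pos, dtype=int)
    n = pos.shape[0]
    chain_id = np.zeros(n, dtype=int) if chain_id is None else np.asarray(chain_id)
    for i in range(n):
        for j in range(i + 1, n):
            if ref_cubes_overlap(pos[i], pos[j]):
                return False
    for i in range(n - 1):
        if chain_id[i] == chain_id[i + 1] and not ref_bond_ok(pos[i + 1] - pos[i]):
            return False
    return True


def random_legal_chain(rng, n, max_tries=2000):
    """Grow a random legal chain with the reference rules only."""
    from itertools import product

    bonds = [
        np.array(v)
        for v in product(range(-3, 4), repeat=3)
        if int(sum(x * x for x in v)) in REF_LENGTHS_SQ
    ]
    for _ in range(max_tries):
        pos = [np.array([20, 20, 20])]
        ok = True
        for _ in range(n - 1):
            for _ in range(50):
                cand = pos[-1] + bonds[rng.integers(len(bonds))]
                if not any(ref_cubes_overlap(cand, p) for p in pos):
                    pos.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(pos)
    raise RuntimeError("could not grow a legal chain")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_chain() -> SystemState:
    return init_saw_chain(SystemConfig(N=16, L=32, seed=1))


@pytest.fixture(scope="session")
def warm_chain() -> SystemState:
    """A briefly evolved N=32 chain used by read-only tests."""
    st = init_saw_chain(SystemConfig(N=32, L=64, seed=2))
    st.run_mcs(3000)
    return st


@pytest.fixture(scope="session")
def looped_chain() -> SystemState:
    st = init_saw_chain(SystemConfig(N=32, L=64, seed=3))
    st.run_mcs(3000)
    st.run_mcs(5000, LoopParams(P=0.05, mean_lifetime=500.0))
    return st
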