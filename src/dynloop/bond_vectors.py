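"""Allowed bond vectors of the 3D bond-fluctuation model.

The bond set is generated from the six canonical base classes
(2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0), (3,1,0) by taking all
coordinate permutations and sign combinations, yielding 108 distinct
integer vectors with squared lengths {4, 5, 6, 9, 10}.  Together with
single-site hops this set guarantees that chains cannot cross.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: canonical base classes of the 108-vector set
BASE_CLASSES: tuple[tuple[int, int, int], ...] = (
    (2, 0, 0),
    (2, 1, 0),
    (2, 1, 1),
    (2, 2, 1),
    (3, 0, 0),
    (3, 1, 0),
)

#: squared bond lengths realised by the set
ALLOWED_LENGTHS_SQ: frozenset[int] = frozenset({4, 5, 6, 9, 10})

# lookup-table geometry: bond components lie in [-3, 3]
_LUT_SHIFT = 3
_LUT_SIDE = 7


@dataclass(frozen=True)
class BondVectorSet:
    """The full set of allowed bond vectors with an exact membership test."""

    vectors: frozenset[tuple[int, int, int]]
    allowed_lengths_sq: frozenset[int] = field(default=ALLOWED_LENGTHS_SQ)

    def __contains__(self, v) -> bool:
        x, y, z = int(v[0]), int(v[1]), int(v[2])
        return (x, y, z) in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def as_array(self) -> np.ndarray:
        """All vectors as a sorted (108, 3) integer array."""
        return np.array(sorted(self.vectors), dtype=np.int64)

    def lookup_table(self) -> np.ndarray:
        """Flat boolean table over the 7x7x7 component cube.

        Index with ``(dx+3)*49 + (dy+3)*7 + (dz+3)`` after verifying
        each component lies in [-3, 3]; used by the compiled engine.
        """
        lut = np.zeros(_LUT_SIDE**3, dtype=np.uint8)
        for x, y, z in self.vectors:
            lut[(x + _LUT_SHIFT) * 49 + (y + _LUT_SHIFT) * 7 + (z + _LUT_SHIFT)] = 1
        return lut


def generate_bond_vectors() -> BondVectorSet:
    """Expand the base classes into the full 108-vector set.

    Deterministic; closed under negation and coordinate permutation.
    """
    vectors: set[tuple[int, int, int]] = set()
    for base in BASE_CLASSES:
        for perm in itertools.permutations(base):
            for signs in itertools.product((1, -1), repeat=3):
                vectors.add((perm[0] * signs[0], perm[1] * signs[1], perm[2] * signs[2]))
    return BondVectorSet(vectors=frozenset(vectors))
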