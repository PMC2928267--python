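"""Dense multi-chain systems: territory statistics and contact maps.

All inter-bead distances in the melt use the minimum-image convention
across the periodic box (chains interact with the nearest image of
every other bead).  Contour-adjacent intra-chain pairs (separation
below ``min_sep``) are excluded from every contact count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import COLOCALIZATION_R2, MIN_CONTOUR_SEPARATION
from .observables import ShapeReport, gyration_shape

__all__ = [
    "TerritoryReport",
    "contact_pairs",
    "classify_contacts",
    "overlap_fraction",
    "multichain_contact_map",
    "territory_report",
]


@dataclass
class TerritoryReport:
    """Territory statistics of one melt ensemble.

    ``inter_fraction`` is the percentage of all counted contacts that
    join different chains; ``overlap_fraction`` is, per chain, the
    fraction of its monomers within contact radius of any other chain.
    """

    intra_contacts: int
    inter_contacts: int
    inter_fraction: float  # percent
    overlap_fraction: np.ndarray  # per chain, in [0, 1]
    shape: ShapeReport | None = None

    @property
    def mean_overlap(self) -> float:
        return float(self.overlap_fraction.mean())


def _frames(positions: np.ndarray) -> np.ndarray:
    p = np.asarray(positions)
    return p[None] if p.ndim == 2 else p


def contact_pairs(
    folded: np.ndarray,
    L,
    radius_sq: int = COLOCALIZATION_R2,
) -> np.ndarray:
    """All unordered bead pairs within the contact radius (minimum image).

    ``folded`` is a single conformation (n, 3) already folded into the
    box; returns an (m, 2) array of index pairs.
    """
    box = np.asarray(L, dtype=float)
    pts = np.asarray(folded, dtype=float) % box
    tree = cKDTree(pts, boxsize=box)
    # integer squared distances: the largest admissible is radius_sq,
    # the next possible value is radius_sq + 1
    r = 0.5 * (np.sqrt(radius_sq) + np.sqrt(radius_sq + 1))
    pairs = tree.query_pairs(r, output_type="ndarray")
    return pairs


def classify_contacts(
    positions: np.ndarray,
    chain_id: np.ndarray,
    L,
    radius_sq: int = COLOCALIZATION_R2,
    min_sep: int = MIN_CONTOUR_SEPARATION,
) -> tuple[int, int, float]:
    """Count intra- and inter-chain contacts over one or many frames.

    Returns (intra, inter, inter_fraction_percent).  Intra-chain pairs
    closer than ``min_sep`` along the contour are not contacts.
    """
    chain_id = np.asarray(chain_id)
    intra = inter = 0
    for frame in _frames(positions):
        pairs = contact_pairs(frame, L, radius_sq)
        if pairs.size == 0:
            continue
        same = chain_id[pairs[:, 0]] == chain_id[pairs[:, 1]]
        sep = np.abs(pairs[:, 0] - pairs[:, 1])
        intra += int((same & (sep >= min_sep)).sum())
        inter += int((~same).sum())
    total = intra + inter
    frac = 100.0 * inter / total if total else 0.0
    return intra, inter, frac


def overlap_fraction(
    positions: np.ndarray,
    chain_id: np.ndarray,
    L,
    radius_sq: int = COLOCALIZATION_R2,
) -> np.ndarray:
    """Per-chain fraction of monomers with >= 1 inter-chain contact.

    Averaged over frames when an ensemble is given.
    """
    chain_id = np.asarray(chain_id)
    n_chains = int(chain_id.max()) + 1
    if n_chains < 2:
        raise ValueError("overlap fraction requires at least 2 chains")
    frames = _frames(positions)
    acc = np.zeros(n_chains)
    for frame in frames:
        pairs = contact_pairs(frame, L, radius_sq)
        touched = np.zeros(chain_id.size, dtype=bool)
        if pairs.size:
            diff = chain_id[pairs[:, 0]] != chain_id[pairs[:, 1]]
            touched[pairs[diff, 0]] = True
            touched[pairs[diff, 1]] = True
        for c in range(n_chains):
            m = chain_id == c
            acc[c] += touched[m].mean()
    return acc / frames.shape[0]


def multichain_contact_map(
    positions: np.ndarray,
    chain_id: np.ndarray,
    L,
    chains: list[int] | None = None,
    radius_sq: int = COLOCALIZATION_R2,
    min_sep: int = MIN_CONTOUR_SEPARATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled contact-count matrix over the beads of a chain subset.

    Beads are numbered consecutively chain by chain (bead 0..N-1 is the
    first requested chain, and so on).  Returns (matrix, bead->chain
    map); the matrix is symmetric with an empty diagonal band.
    """
    chain_id = np.asarray(chain_id)
    if chains is None:
        chains = list(range(int(chain_id.max()) + 1))
    chains = list(chains)
    for c in chains:
        if not np.any(chain_id == c):
            raise ValueError(f"unknown chain id {c}")
    sel = np.concatenate([np.flatnonzero(chain_id == c) for c in chains])
    remap = -np.ones(chain_id.size, dtype=np.int64)
    remap[sel] = np.arange(sel.size)
    sub_chain = chain_id[sel]
    M = np.zeros((sel.size, sel.size), dtype=np.int64)
    for frame in _frames(positions):
        pairs = contact_pairs(frame, L, radius_sq)
        if pairs.size == 0:
            continue
        a = remap[pairs[:, 0]]
        b = remap[pairs[:, 1]]
        keep = (a >= 0) & (b >= 0)
        a, b = a[keep], b[keep]
        same = sub_chain[a] == sub_chain[b]
        near = np.abs(pairs[keep, 0] - pairs[keep, 1]) < min_sep
        keep2 = ~(same & near)
        a, b = a[keep2], b[keep2]
        np.add.at(M, (a, b), 1)
        np.add.at(M, (b, a), 1)
    return M, sub_chain


def territory_report(
    positions: np.ndarray,
    chain_id: np.ndarray,
    L,
    radius_sq: int = COLOCALIZATION_R2,
    min_sep: int = MIN_CONTOUR_SEPARATION,
    unfolded_positions: np.ndarray | None = None,
) -> TerritoryReport:
    """Full territory statistics of a melt ensemble.

    Contact classification uses folded minimum-image distances; the
    per-chain gyration shape uses unfolded coordinates (pass them via
    ``unfolded_positions`` when ``positions`` are folded).
    """
    intra, inter, frac = classify_contacts(positions, chain_id, L, radius_sq, min_sep)
    ov = overlap_fraction(positions, chain_id, L, radius_sq)
    shape = None
    shape_pos = unfolded_positions if unfolded_positions is not None else positions
    try:
        shape = gyration_shape(shape_pos, chain_id)
    except ValueError:
        pass
    return TerritoryReport(
        intra_contacts=intra,
        inter_contacts=inter,
        inter_fraction=frac,
        overlap_fraction=ov,
        shape=shape,
    )
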