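"""Observables: internal distances, contacts, moments, shape, dynamics.

Everything here operates on ensembles of unfolded integer coordinates
(shape ``(S, n, 3)`` or ``(S, C, N, 3)`` after splitting into chains)
and is agnostic of how they were produced.  Contact notions use one
co-localization criterion throughout: squared Euclidean distance at or
below ``radius_sq`` (default 8, i.e. distance < 3 lattice units) with
contour separation of at least ``min_sep`` beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import COLOCALIZATION_R2, MIN_CONTOUR_SEPARATION

__all__ = [
    "DistanceProfile",
    "MomentRatios",
    "ContactStatistics",
    "PowerLawFit",
    "ShapeReport",
    "DynamicsProfile",
    "pair_statistics",
    "internal_msd",
    "moment_ratios",
    "loop_size_distribution",
    "contact_size_distribution",
    "specific_contact_probability",
    "mean_contacts_per_conformation",
    "fit_power_law",
    "fit_loglog_slope",
    "gyration_shape",
    "dynamics_profiles",
    "calibrate_physical",
    "decalibrate_physical",
    "random_walk_extension",
    "size_histogram",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DistanceProfile:
    """Mean squared internal distance R^2(s) per contour separation s."""

    s: np.ndarray
    R2: np.ndarray
    n_obs: np.ndarray
    genomic_kb: np.ndarray | None = None
    r2_phys: np.ndarray | None = None

    def plateau_ratio(self) -> float:
        """R^2(N/2) / R^2(N/4): ~1 on a leveled-off (confined) profile."""
        N = int(self.s.max()) + 1
        i1 = np.argmin(np.abs(self.s - N // 2))
        i2 = np.argmin(np.abs(self.s - N // 4))
        return float(self.R2[i1] / self.R2[i2])


@dataclass
class MomentRatios:
    """Dimensionless moment ratios of the pair-distance distribution.

    ratio4 = <r^4>/<r^2>^2 and ratio6 = <r^6>/<r^2>^3, per contour
    separation.  For a 3-D Gaussian coil ratio4 = 5/3; larger values
    signal stronger cell-to-cell variation.
    """

    s: np.ndarray
    ratio4: np.ndarray
    ratio6: np.ndarray

    def pooled(self, s_min: int | None = None, s_max: int | None = None) -> tuple[float, float]:
        m = np.ones(self.s.size, dtype=bool)
        if s_min is not None:
            m &= self.s >= s_min
        if s_max is not None:
            m &= self.s <= s_max
        return float(np.nanmean(self.ratio4[m])), float(np.nanmean(self.ratio6[m]))


@dataclass
class ContactStatistics:
    """Loop / contact size distributions and the specific contact probability."""

    sizes: np.ndarray  # bin centers (contour size l)
    f_l: np.ndarray | None  # normalized functional-loop size masses
    h_l: np.ndarray | None  # normalized random-contact size masses
    h_density: np.ndarray | None  # h masses / bin width (for power-law fits)
    s: np.ndarray | None = None
    Pc_s: np.ndarray | None = None
    contact_radius_sq: int = COLOCALIZATION_R2


@dataclass
class PowerLawFit:
    """Least-squares power law on log-log axes; exponent positive for decays."""

    exponent: float
    stderr: float
    fit_range: tuple[float, float]
    r_squared: float
    amplitude: float
    n_points: int
    slope: float  # raw log-log slope (negative for decays)


@dataclass
class ShapeReport:
    """Gyration-ellipsoid shape: eigenvalues sorted descending."""

    eigenvalues: np.ndarray
    asphericity: float

    @property
    def eigen_ratios(self) -> np.ndarray:
        # rank-deficient shapes (e.g. a straight rod) have a zero
        # smallest eigenvalue; their ratios are infinite by convention
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.eigenvalues / self.eigenvalues[-1]

    @property
    def axis_ratios(self) -> np.ndarray:
        return np.sqrt(self.eigen_ratios)


@dataclass
class DynamicsProfile:
    """g1 (central-monomer) and g3 (center-of-mass) mean-square displacements."""

    lag_times: np.ndarray
    g1: np.ndarray
    g3: np.ndarray
    exponents: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# core pair statistics


def _as_chains(positions: np.ndarray, chain_id: np.ndarray | None = None) -> np.ndarray:
    """Coerce (S, n, 3) + chain map into (S, C, N, 3); chains must be equal length."""
    p = np.asarray(positions)
    if p.ndim == 2:
        p = p[None]
    if p.ndim == 4:
        return p
    if chain_id is None:
        return p[:, None, :, :]
    chain_id = np.asarray(chain_id)
    n_chains = int(chain_id.max()) + 1
    counts = np.bincount(chain_id, minlength=n_chains)
    if not np.all(counts == counts[0]):
        raise ValueError("chains must have equal length for ensemble statistics")
    return p.reshape(p.shape[0], n_chains, counts[0], 3)


def pair_statistics(
    positions: np.ndarray,
    chain_id: np.ndarray | None = None,
    radius_sq: int = COLOCALIZATION_R2,
) -> dict:
    """Single pass over all same-chain (i, i+s) pairs of an ensemble.

    Returns per-separation arrays: pair counts, moments <r^2>, <r^4>,
    <r^6> and contact counts (squared distance <= radius_sq), pooled
    over conformations, chains and reference points.
    """
    p = _as_chains(positions, chain_id).astype(np.float64)
    S, C, N, _ = p.shape
    smax = N - 1
    out = {
        "s": np.arange(1, smax + 1),
        "n_pairs": np.zeros(smax, dtype=np.int64),
        "r2": np.zeros(smax),
        "r4": np.zeros(smax),
        "r6": np.zeros(smax),
        "contacts": np.zeros(smax, dtype=np.int64),
        "n_conformations": S,
        "n_chains": C,
        "N": N,
    }
    for s in range(1, N):
        d = p[:, :, s:, :] - p[:, :, :-s, :]
        sq = np.einsum("sckx,sckx->sck", d, d)
        k = s - 1
        out["n_pairs"][k] = sq.size
        out["r2"][k] = sq.mean()
        out["r4"][k] = (sq**2).mean()
        out["r6"][k] = (sq**3).mean()
        out["contacts"][k] = int((sq <= radius_sq).sum())
    return out


def internal_msd(
    positions: np.ndarray,
    chain_id: np.ndarray | None = None,
    min_conformations: int = 30,
) -> DistanceProfile:
    """Mean squared distance between beads separated by s along the chain.

    Averaged over conformations, chains and all reference points, on
    unfolded coordinates.
    """
    p = _as_chains(positions, chain_id)
    if p.shape[0] < min_conformations:
        raise ValueError(
            f"need at least {min_conformations} decorrelated conformations, "
            f"got {p.shape[0]}"
        )
    st = pair_statistics(p)
    return DistanceProfile(s=st["s"], R2=st["r2"], n_obs=st["n_pairs"])


def moment_ratios(
    positions: np.ndarray,
    chain_id: np.ndarray | None = None,
    min_samples: int = 100,
) -> MomentRatios:
    """<r^4>/<r^2>^2 and <r^6>/<r^2>^3 per contour separation.

    Dimensionless and invariant under uniform rescaling of all
    distances.
    """
    st = pair_statistics(positions, chain_id)
    if st["n_pairs"].min() * st["n_conformations"] < min_samples and (
        st["n_pairs"].min() < min_samples
    ):
        raise ValueError(f"need >= {min_samples} distance samples per separation")
    with np.errstate(divide="ignore", invalid="ignore"):
        r4 = st["r4"] / st["r2"] ** 2
        r6 = st["r6"] / st["r2"] ** 3
    return MomentRatios(s=st["s"], ratio4=r4, ratio6=r6)


# ---------------------------------------------------------------------------
# histograms over contour sizes


def size_histogram(
    sizes: np.ndarray,
    N: int,
    log_bins_above: int = 16,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of contour sizes: unit bins up to ``log_bins_above``,
    logarithmic bins beyond (stabilizes power-law fits in the tail).

    Returns (bin centers, normalized masses, densities, bin widths);
    masses sum to 1 over the recorded range.
    """
    sizes = np.asarray(sizes)
    if sizes.size == 0:
        raise ValueError("empty size record")
    lo, hi = 1, max(int(sizes.max()), log_bins_above + 1, N - 1)
    edges = np.arange(lo, min(log_bins_above, hi) + 1, dtype=float)
    if hi > log_bins_above:
        nlog = max(3, int(np.ceil(10 * np.log10(hi / log_bins_above))))
        log_edges = np.geomspace(log_bins_above, hi + 1, nlog)
        edges = np.concatenate([edges, log_edges[1:]])
    edges[-1] += 1e-9
    counts, _ = np.histogram(sizes, bins=edges, weights=weights)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])  # geometric centers
    centers[: max(0, min(log_bins_above, hi) - 1)] = edges[
        : max(0, min(log_bins_above, hi) - 1)
    ]  # unit bins: the size itself
    total = counts.sum()
    masses = counts / total
    densities = masses / widths
    return centers, masses, densities, widths


def loop_size_distribution(loop_sizes: np.ndarray, N: int | None = None) -> ContactStatistics:
    """Normalized size distribution f(l) of functional loops.

    f is reported per exact size (unit bins), since the loop record is
    discrete and usually small; log-binning only matters for the
    contact-abundance fits.
    """
    sizes = np.asarray(loop_sizes)
    if sizes.size == 0:
        raise ValueError("empty loop record")
    N = N or int(sizes.max()) + 1
    centers, masses, dens, _ = size_histogram(
        sizes, N, log_bins_above=int(sizes.max()) + 1
    )
    keep = masses > 0
    return ContactStatistics(sizes=centers[keep], f_l=masses[keep], h_l=None, h_density=None)


def contact_size_distribution(
    positions: np.ndarray,
    chain_id: np.ndarray | None = None,
    radius_sq: int = COLOCALIZATION_R2,
    min_sep: int = MIN_CONTOUR_SEPARATION,
) -> ContactStatistics:
    """Relative abundance h(l) of random contacts of contour size l.

    A contact is any same-chain bead pair within the co-localization
    radius, regardless of whether a functional loop connects it.  Each
    contact is weighted by the number of fragments of its size the
    chain offers (N - l), i.e. h is the abundance per available pair,
    so that the decay exponent is not distorted by the vanishing number
    of long fragments near the chain ends.
    """
    st = pair_statistics(positions, chain_id, radius_sq)
    s = st["s"]
    counts = st["contacts"].astype(float)
    m = s >= min_sep
    if counts[m].sum() == 0:
        raise ValueError("no contacts recorded")
    sizes = np.repeat(s[m], st["contacts"][m])
    weights = 1.0 / (st["N"] - sizes)
    centers, masses, dens, _ = size_histogram(sizes, st["N"], weights=weights)
    keep = masses > 0
    return ContactStatistics(
        sizes=centers[keep],
        f_l=None,
        h_l=masses[keep],
        h_density=dens[keep],
        contact_radius_sq=radius_sq,
    )


def specific_contact_probability(
    positions: np.ndarray,
    chain_id: np.ndarray | None = None,
    radius_sq: int = COLOCALIZATION_R2,
) -> ContactStatistics:
    """Pc(s): probability that a specific (i, i+s) pair is in contact."""
    st = pair_statistics(positions, chain_id, radius_sq)
    pc = st["contacts"] / st["n_pairs"]
    return ContactStatistics(
        sizes=st["s"],
        f_l=None,
        h_l=None,
        h_density=None,
        s=st["s"],
        Pc_s=pc,
        contact_radius_sq=radius_sq,
    )


def mean_contacts_per_conformation(
    positions: np.ndarray,
    chain_id: np.ndarray | None = None,
    radius_sq: int = COLOCALIZATION_R2,
    min_sep: int = 1,
) -> float:
    """Mean number of same-chain contacts per conformation (per chain).

    Satisfies the counting identity
    ``sum_s (N - s) * Pc(s) = mean contacts`` exactly when ``min_sep=1``.
    """
    st = pair_statistics(positions, chain_id, radius_sq)
    m = st["s"] >= min_sep
    return float(st["contacts"][m].sum() / (st["n_conformations"] * st["n_chains"]))


# ---------------------------------------------------------------------------
# fits


def fit_power_law(x, y, fit_range: tuple[float, float]) -> PowerLawFit:
    """Least-squares fit of y = A x^(-exponent) on log-log axes.

    The returned exponent is positive for decaying data (it is the
    negative of the raw log-log slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = fit_range
    m = (x >= lo) & (x <= hi)
    if np.any(y[m] <= 0):
        raise ValueError("non-positive values inside the fit range")
    if m.sum() < 2:
        raise ValueError(
            f"fit range [{lo}, {hi}] selects {int(m.sum())} point(s); need >= 2"
        )
    res = stats.linregress(np.log(x[m]), np.log(y[m]))
    return PowerLawFit(
        exponent=-res.slope,
        stderr=res.stderr if np.isfinite(res.stderr) else 0.0,
        fit_range=(lo, hi),
        r_squared=res.rvalue**2,
        amplitude=float(np.exp(res.intercept)),
        n_points=int(m.sum()),
        slope=res.slope,
    )


def fit_loglog_slope(x, y, fit_range: tuple[float, float]) -> PowerLawFit:
    """As :func:`fit_power_law` but with exponent = raw slope (growth laws)."""
    f = fit_power_law(x, y, fit_range)
    return PowerLawFit(
        exponent=f.slope,
        stderr=f.stderr,
        fit_range=f.fit_range,
        r_squared=f.r_squared,
        amplitude=f.amplitude,
        n_points=f.n_points,
        slope=f.slope,
    )


# ---------------------------------------------------------------------------
# shape


def gyration_shape(positions: np.ndarray, chain_id: np.ndarray | None = None) -> ShapeReport:
    """Eigen-decomposition of the gyration tensor (unfolded coordinates).

    For an ensemble (or a melt), eigenvalues are averaged over
    conformations and chains *before* forming ratios.  Eigenvalue
    ratios are the squares of the ellipsoid axis ratios exactly.
    """
    p = _as_chains(positions, chain_id).astype(float)
    S, C, N, _ = p.shape
    if N < 2:
        raise ValueError("need at least 2 monomers")
    c = p.mean(axis=2, keepdims=True)
    d = p - c
    # gyration tensor per conformation and chain
    T = np.einsum("scni,scnj->scij", d, d) / N
    evals = np.linalg.eigvalsh(T)  # ascending
    mean_evals = evals.mean(axis=(0, 1))[::-1]  # descending
    l1, l2, l3 = mean_evals
    tr = mean_evals.sum()
    asph = ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2) / (2 * tr**2)
    return ShapeReport(eigenvalues=mean_evals, asphericity=float(asph))


# ---------------------------------------------------------------------------
# dynamics


def dynamics_profiles(
    positions: np.ndarray,
    times: np.ndarray,
    chain_id: np.ndarray | None = None,
    central_fraction: float = 0.1,
    n_lags: int = 40,
    tau_relax: float | None = None,
) -> DynamicsProfile:
    """g1/g3 mean-square displacements on logarithmically spaced lags.

    g3 is the center-of-mass MSD; g1 averages the individual MSDs of
    the central ``central_fraction`` of monomers (at least the single
    central monomer).  With ``tau_relax`` given, log-log slopes are
    fitted in the three regimes t << tau, t ~ tau and t >> tau.
    """
    p = _as_chains(positions, chain_id).astype(float)
    t = np.asarray(times, dtype=float)
    S, C, N, _ = p.shape
    if S < 4:
        raise ValueError("trajectory too short")
    lags = np.unique(np.round(np.logspace(0, np.log10(S - 1), n_lags)).astype(int))
    lags = lags[lags >= 1]
    com = p.mean(axis=2)  # (S, C, 3)
    half = max(1, int(np.round(central_fraction * N / 2)))
    mid = N // 2
    sel = slice(max(0, mid - half), min(N, mid + half + 1))
    central = p[:, :, sel, :]
    g1 = np.empty(lags.size)
    g3 = np.empty(lags.size)
    for k, lag in enumerate(lags):
        dc = com[lag:] - com[:-lag]
        g3[k] = np.einsum("scx,scx->sc", dc, dc).mean()
        dm = central[lag:] - central[:-lag]
        g1[k] = np.einsum("scnx,scnx->scn", dm, dm).mean()
    lag_times = t[lags] - t[0]
    prof = DynamicsProfile(lag_times=lag_times, g1=g1, g3=g3)
    if tau_relax is not None:
        for name, series in (("g1", g1), ("g3", g3)):
            for regime, (lo, hi) in {
                "short": (0.0, 0.1 * tau_relax),
                "mid": (0.3 * tau_relax, 3.0 * tau_relax),
                "long": (10.0 * tau_relax, np.inf),
            }.items():
                m = (lag_times > lo) & (lag_times <= hi)
                if m.sum() >= 4:
                    fit = fit_loglog_slope(lag_times[m], series[m], (lag_times[m].min(), lag_times[m].max()))
                    prof.exponents[f"{name}_{regime}"] = fit.exponent
    return prof


# ---------------------------------------------------------------------------
# physical calibration


def calibrate_physical(
    profile: DistanceProfile,
    kb_per_bead: float = 400.0,
    nm_per_bead: float = 480.0,
    bead_extent_lattice: float = 1.0,
) -> DistanceProfile:
    """Attach physical axes to a distance profile (pure relabeling).

    ``s`` maps to genomic separation at ``kb_per_bead`` kilobases per
    bead; squared lattice distances scale by
    ``(nm_per_bead / bead_extent_lattice)^2`` so that one bead extent
    (``bead_extent_lattice`` lattice units, by default the lattice unit
    itself) maps to ``nm_per_bead`` nanometres.
    """
    if kb_per_bead <= 0 or nm_per_bead <= 0 or bead_extent_lattice <= 0:
        raise ValueError("calibration constants must be positive")
    scale = nm_per_bead / bead_extent_lattice
    return DistanceProfile(
        s=profile.s,
        R2=profile.R2,
        n_obs=profile.n_obs,
        genomic_kb=profile.s * kb_per_bead,
        r2_phys=profile.R2 * scale**2,
    )


def decalibrate_physical(profile: DistanceProfile) -> DistanceProfile:
    """Drop the physical columns again (exact round trip)."""
    return DistanceProfile(s=profile.s, R2=profile.R2, n_obs=profile.n_obs)


def random_walk_extension(
    contour_mb: float = 100.0,
    kuhn_kb: float = 30.0,
    kuhn_nm: float = 300.0,
) -> float:
    """RMS end-to-end extension (micrometres) of a random-walk chromosome.

    A chromosome of ``contour_mb`` megabases packed at ``kuhn_kb``
    kilobases per Kuhn segment of length ``kuhn_nm`` nanometres extends
    to sqrt(n_segments) * kuhn_nm; for the default human-chromosome
    numbers this gives 17.3 um, well above a 10 um nucleus -- the
    classical argument against unconfined random-walk folding.
    """
    n_segments = contour_mb * 1000.0 / kuhn_kb
    return float(np.sqrt(n_segments) * kuhn_nm / 1000.0)
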