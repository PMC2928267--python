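"""Equilibration and decorrelation diagnostics.

Two criteria decide when retained conformations may be treated as
independent: the integrated autocorrelation time of the squared radius
of gyration (estimated with Sokal's windowing procedure), and the time
after which the chain's center of mass has moved by about one radius of
gyration.  The sampling interval of every production run is the larger
of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateSeriesError(ValueError):
    """The time series has zero variance."""


class UndersampledError(RuntimeError):
    """The series is too short to estimate the requested quantity."""


@dataclass(frozen=True)
class EquilibrationReport:
    """Decorrelation diagnostics of one parameter set.

    All times are in MCS.  ``sampling_interval`` is the spacing between
    retained conformations; ``tau_int`` and ``window_M`` refer to the
    Rg^2 series, ``t_cm`` to the center-of-mass displacement criterion.
    """

    tau_int: float
    window_M: int
    t_cm: float
    sampling_interval: float
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "tau_int": self.tau_int,
            "window_M": self.window_M,
            "t_cm": self.t_cm,
            "sampling_interval": self.sampling_interval,
            "n_samples": self.n_samples,
        }


def autocorrelation(series) -> np.ndarray:
    """Normalized autocorrelation function of a scalar time series.

    Mean-subtracted, variance-normalized, FFT-accelerated, with
    per-lag sample counts (rho(0) = 1 exactly).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("series must be 1-D with length >= 10")
    n = x.size
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0 or not np.isfinite(var):
        raise DegenerateSeriesError("series has zero variance")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real
    acov /= n - np.arange(n)  # per-lag pair counts
    return acov / acov[0]


def sokal_tau_int(acf, c: float = 6.0) -> tuple[float, int]:
    """Windowed integrated autocorrelation time.

    tau_int(M) = 1/2 + sum_{t=1..M} rho(t); the window M is the smallest
    integer with M >= c * tau_int(M).  Raises :class:`UndersampledError`
    when no self-consistent window exists below half the series length.
    """
    rho = np.asarray(acf, dtype=float)
    if c <= 0:
        raise ValueError("window constant c must be positive")
    max_m = rho.size // 2
    tau = 0.5 + np.cumsum(rho[1 : max_m + 1])
    ms = np.arange(1, tau.size + 1)
    ok = np.flatnonzero(ms >= c * tau)
    if ok.size == 0:
        raise UndersampledError(
            f"no window M <= {max_m} satisfies M >= {c}*tau_int(M); "
            "the series is too short for a reliable tau_int"
        )
    m = int(ok[0]) + 1
    return float(tau[m - 1]), m


def msd_profile(times, positions, lags=None) -> tuple[np.ndarray, np.ndarray]:
    """Time-origin-averaged mean-square displacement at integer lag indices.

    ``positions`` is (n_frames, 3) (e.g. a center-of-mass track);
    returns (lag times, msd values) for the requested lag indices.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(positions, dtype=float)
    n = p.shape[0]
    if lags is None:
        lags = np.unique(np.round(np.logspace(0, np.log10(n - 1), 60)).astype(int))
    lags = np.asarray([k for k in np.atleast_1d(lags) if 1 <= k < n], dtype=int)
    if lags.size == 0:
        raise ValueError("no admissible lags below the trajectory length")
    out = np.empty(lags.size)
    for idx, k in enumerate(lags):
        d = p[k:] - p[:-k]
        out[idx] = (d**2).sum(axis=1).mean()
    return t[lags] - t[0], out


def com_decorrelation_time(times, com_positions, rg2_mean: float) -> float:
    """Smallest time with mean-square COM displacement >= <Rg^2>.

    Linear interpolation between sampled lags; raises
    :class:`UndersampledError` if the threshold is never reached.
    """
    n = np.asarray(com_positions).shape[0]
    lags = np.unique(np.round(np.logspace(0, np.log10(n - 1), 120)).astype(int))
    tlag, g3 = msd_profile(times, com_positions, lags)
    above = np.flatnonzero(g3 >= rg2_mean)
    if above.size == 0:
        raise UndersampledError(
            "center of mass never moved one radius of gyration within the "
            f"trajectory (max g3 = {g3.max():.3g} < <Rg^2> = {rg2_mean:.3g})"
        )
    j = int(above[0])
    if j == 0:
        return float(tlag[0])
    # interpolate the crossing between the bracketing lags
    t0, t1 = tlag[j - 1], tlag[j]
    g0, g1 = g3[j - 1], g3[j]
    return float(t0 + (rg2_mean - g0) * (t1 - t0) / (g1 - g0))


def plan_sampling(
    tau_int: float,
    window_M: int,
    t_cm: float,
    k: float = 2.0,
    burnin_multiplier: float = 10.0,
) -> EquilibrationReport:
    """Combine the two decorrelation criteria into a sampling plan."""
    if tau_int <= 0:
        raise ValueError("tau_int must be positive")
    interval = max(k * tau_int, t_cm)
    return EquilibrationReport(
        tau_int=float(tau_int),
        window_M=int(window_M),
        t_cm=float(t_cm),
        sampling_interval=float(interval),
    )


def burn_in(tau_int: float, burnin_multiplier: float = 10.0) -> int:
    return int(np.ceil(burnin_multiplier * tau_int))
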