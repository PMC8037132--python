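"""Mean squared displacement, diffusion and anomalous-exponent fitting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.transform import Rotation

from ..errors import PepmpcError
from ..units import CM2_PER_S_FROM_A2_PER_PS


@dataclass
class MSDResult:
    """Time-and-ensemble averaged MSD with fitted transport parameters.

    ``lags`` in ps, ``msd`` in A^2, ``D_fit`` in cm^2/s, ``alpha`` the
    log-log slope over ``fit_window`` (lag range in ps).
    """

    lags: np.ndarray
    msd: np.ndarray
    D_fit: float
    alpha: float
    fit_window: tuple


def _msd_at_lag(pos: np.ndarray, lag: int) -> float:
    d = pos[lag:] - pos[:-lag]
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


def msd(positions, times=None, dt: float | None = None,
        lags=None, fit_window: tuple | None = None) -> MSDResult:
    """All-origin MSD of a 3D center-of-mass track.

    Parameters
    ----------
    positions
        (n_frames, 3) array in Angstrom, or a list of such arrays
        (replicas, averaged together).
    times, dt
        Uniform frame times in ps (give one of the two).
    lags
        Lag times in ps; defaults to every frame spacing up to a quarter
        of the trajectory.
    fit_window
        (lag_min, lag_max) in ps for the linear ``MSD = 6 D tau`` fit and
        the log-log slope; defaults to the 10-25% span of the maximum lag.
    """
    replicas = positions if isinstance(positions, (list, tuple)) \
        else [positions]
    replicas = [np.asarray(p, float) for p in replicas]
    n = replicas[0].shape[0]
    if any(p.shape != replicas[0].shape for p in replicas):
        raise PepmpcError("replicas must share shape")
    if n < 2:
        raise PepmpcError("need at least two frames")
    if times is not None:
        times = np.asarray(times, float)
        steps = np.diff(times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise PepmpcError("MSD requires uniform time spacing")
        dt = float(steps[0])
    if dt is None or dt <= 0:
        raise PepmpcError("provide times or a positive dt")

    if lags is None:
        max_lag = max(1, n // 4)
        lag_frames = np.arange(1, max_lag + 1)
    else:
        lag_frames = np.unique(np.round(np.asarray(lags, float)
                                        / dt).astype(int))
        lag_frames = lag_frames[(lag_frames >= 1) & (lag_frames < n)]
        if lag_frames.size == 0:
            raise PepmpcError("no valid lags")
    lag_times = lag_frames * dt
    values = np.array([
        np.mean([_msd_at_lag(p, int(lf)) for p in replicas])
        for lf in lag_frames
    ])

    if fit_window is None:
        lo, hi = 0.10 * lag_times[-1], 0.25 * lag_times[-1]
        if not np.any((lag_times >= lo) & (lag_times <= hi)):
            lo, hi = lag_times[0], lag_times[-1]
    else:
        lo, hi = fit_window
    mask = (lag_times >= lo) & (lag_times <= hi) & (values > 0)
    if mask.sum() < 2:
        mask = values > 0
    tau = lag_times[mask]
    m = values[mask]
    if tau.size == 0:     # e.g. a perfectly static particle
        D_fit, alpha = 0.0, float("nan")
    else:
        # MSD = 6 D tau through the origin
        slope = float(np.dot(tau, m) / np.dot(tau, tau))
        D_fit = slope / 6.0 * CM2_PER_S_FROM_A2_PER_PS
        alpha = float(np.polyfit(np.log(tau), np.log(m), 1)[0]) \
            if tau.size >= 2 else float("nan")
    return MSDResult(lags=lag_times, msd=values, D_fit=D_fit,
                     alpha=alpha, fit_window=(float(lo), float(hi)))


def _axis_autocorrelation(u: np.ndarray, max_lag: int) -> np.ndarray:
    """<u(t).u(t+tau)> for tau = 0..max_lag via FFT, all origins."""
    n = u.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    total = np.zeros(n)
    for k in range(3):
        f = np.fft.rfft(u[:, k], nfft)
        c = np.fft.irfft(f * np.conj(f), nfft)[:n]
        total += c
    counts = n - np.arange(n)
    return (total / counts)[:max_lag + 1]


def fit_rotational_diffusion(orientations, dt: float,
                             max_lag: int | None = None,
                             corr_floor: float = 0.95) -> float:
    """Rotational diffusion coefficient (rad^2/ps) from orientation decay.

    Tracks the body z-axis u(t) of a unit-quaternion series and fits
    <u(t).u(t+tau)> = exp(-2 D_r tau).  The fit is restricted to the
    initial decay (correlation above ``corr_floor``) where the
    single-trajectory estimate is statistically reliable; long lags are
    dominated by sampling noise.
    """
    q = np.asarray(orientations, float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise PepmpcError("orientations must be an (n, 4) quaternion array")
    if q.shape[0] < 100:
        raise PepmpcError("need at least 100 frames")
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise PepmpcError("quaternions must be unit norm")
    u = Rotation.from_quat(q).apply(np.array([0.0, 0.0, 1.0]))
    n = u.shape[0]
    if max_lag is None:
        max_lag = n // 2
    corr = _axis_autocorrelation(u, max_lag)
    if abs(corr[0] - 1.0) > 1e-6:
        raise PepmpcError("autocorrelation at zero lag must be 1")
    # frozen orientation: no decay at all
    if np.all(corr > 1.0 - 1e-12):
        return 0.0
    lags = np.arange(max_lag + 1) * dt
    below = np.nonzero(corr < corr_floor)[0]
    cut = int(below[0]) if below.size else max_lag + 1
    cut = max(cut, min(11, max_lag + 1))   # keep at least ~10 points
    tau = lags[1:cut]
    c = np.clip(corr[1:cut], 1e-12, None)
    # log-linear fit: ln C = -2 D tau
    slope = float(np.dot(tau, np.log(c)) / np.dot(tau, tau))
    D = -slope / 2.0
    if D < 0:
        # fall back to a nonlinear fit when noise dominates
        popt, _ = curve_fit(lambda t, d: np.exp(-2 * d * t), tau, c,
                            p0=[1e-4], maxfev=10000)
        D = float(popt[0])
    return float(D)
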