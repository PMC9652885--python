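"""Non-spectral signal features: phase-amplitude coupling, Shannon entropy,
Hjorth parameters, largest Lyapunov exponent, Hurst exponent and normalized
Lempel-Ziv (LZ76) complexity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.spatial import cKDTree

from .bands import Band, BandScheme, DEFAULT_SCHEME
from .spectral import DegenerateSignalError


@dataclass(frozen=True)
class NonlinearParams:
    """Defaults for the non-spectral feature extractors."""

    entropy_bins: int = 64
    lyap_embed_dim: int = 5
    lyap_delay: Optional[int] = None      # None -> first autocorr zero-crossing
    lyap_fit_steps: Optional[int] = None  # None -> half a mean period
    hurst_min_window: int = 32
    hurst_n_sizes: int = 8
    lz_binarize: str = "median"
    lz_log_base: float = 2.0
    pac_filter_order: int = 4

    def __post_init__(self) -> None:
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if self.lyap_embed_dim < 2:
            raise ValueError("lyap_embed_dim must be >= 2")
        if self.lz_binarize not in ("median", "mean"):
            raise ValueError("lz_binarize must be 'median' or 'mean'")


DEFAULT_NONLINEAR = NonlinearParams()


# ---------------------------------------------------------------------------
# phase-amplitude coupling

def high_band_envelope(
    x: np.ndarray, fs: float, high_band: Band, filter_order: int = 4
) -> np.ndarray:
    """Amplitude envelope (analytic-signal magnitude) of the high band."""
    sos = signal.butter(filter_order, high_band, btype="bandpass", fs=fs,
                        output="sos")
    narrow = signal.sosfiltfilt(sos, x, axis=-1)
    return np.abs(signal.hilbert(narrow, axis=-1))


def phase_amplitude_coupling(
    x: np.ndarray,
    fs: float,
    low_band: Band,
    high_band: Band,
    filter_order: int = 4,
) -> np.ndarray:
    """Coupling between the low band's phase and the high band's amplitude.

    Band-passes ``x`` to the high band, takes its amplitude envelope, then
    averages the magnitude-squared coherence between the raw signal and the
    envelope over the low band's frequencies. Values lie in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if np.all(np.ptp(x, axis=-1) == 0):
        raise DegenerateSignalError("PAC undefined for a constant signal")
    n = x.shape[-1]
    nperseg = min(int(fs), n)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    mask = (freqs >= low_band[0]) & (freqs < low_band[1])
    if not mask.any():
        raise ValueError(
            f"no coherence bins inside low band {low_band}; signal too short")
    env = high_band_envelope(x, fs, high_band, filter_order=filter_order)
    _, cxy = signal.coherence(x, env, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, axis=-1)
    return cxy[..., mask].mean(axis=-1)


def pac_from_envelope(
    x: np.ndarray, env: np.ndarray, fs: float, low_band: Band
) -> np.ndarray:
    """PAC given a precomputed envelope (lets callers reuse one envelope for
    several low bands)."""
    n = x.shape[-1]
    nperseg = min(int(fs), n)
    freqs, cxy = signal.coherence(x, env, fs=fs, window="hann",
                                  nperseg=nperseg, noverlap=nperseg // 2,
                                  axis=-1)
    mask = (freqs >= low_band[0]) & (freqs < low_band[1])
    if not mask.any():
        raise ValueError(f"no coherence bins inside low band {low_band}")
    return cxy[..., mask].mean(axis=-1)


# ---------------------------------------------------------------------------
# Shannon entropy

def shannon_entropy(x: np.ndarray, bins: int = 64) -> float:
    """Entropy (nats) of the amplitude histogram with equal-width bins over
    [min, max]. A constant signal occupies a single bin and returns 0."""
    x = np.asarray(x, dtype=float).ravel()
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Hjorth parameters

def hjorth(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hjorth activity, mobility and complexity along the last axis.

    activity = population variance; mobility = sqrt(var(x')/var(x)) with
    x' the first difference; complexity = mobility(x')/mobility(x).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    var0 = x.var(axis=-1)
    if np.any(var0 == 0):
        raise DegenerateSignalError("Hjorth mobility undefined for constant signal")
    dx = np.diff(x, axis=-1)
    var1 = dx.var(axis=-1)
    ddx = np.diff(dx, axis=-1)
    var2 = ddx.var(axis=-1)
    mobility = np.sqrt(var1 / var0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility_dx = np.sqrt(var2 / var1)
        complexity = np.where(mobility > 0, mobility_dx / mobility, np.nan)
    return var0, mobility, complexity


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (nearest-neighbor divergence)

def _first_acf_zero_crossing(x: np.ndarray) -> int:
    x = x - x.mean()
    n = x.size
    denom = float(x @ x)
    if denom == 0:
        raise DegenerateSignalError("autocorrelation undefined for constant signal")
    for lag in range(1, n // 2):
        if float(x[:-lag] @ x[lag:]) / denom <= 0:
            return lag
    return max(1, n // 4)


def _mean_period_samples(x: np.ndarray, fs: float) -> float:
    freqs, psd = signal.periodogram(x, fs=fs)
    pos = freqs > 0
    power = psd[pos]
    total = power.sum()
    if total == 0:
        raise DegenerateSignalError("mean period undefined for constant signal")
    mean_freq = float((freqs[pos] * power).sum() / total)
    return fs / mean_freq


def delay_embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Delay embedding: rows are (x[i], x[i+delay], ..., x[i+(dim-1)delay])."""
    n = x.size - (dim - 1) * delay
    if n < 2:
        raise ValueError("signal too short for the requested embedding")
    return np.stack([x[j * delay: j * delay + n] for j in range(dim)], axis=1)


def lyapunov_exponent(
    x: np.ndarray,
    fs: float = 1.0,
    embed_dim: int = 5,
    delay: Optional[int] = None,
    fit_steps: Optional[int] = None,
    min_sep: Optional[int] = None,
) -> float:
    """Largest Lyapunov exponent (1/s) by nearest-neighbor divergence.

    Embeds ``x``, pairs each point with its nearest neighbor at least a mean
    period away in time, tracks the mean log distance as pairs evolve, and
    returns the slope of its initial linear region divided by the sampling
    period.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise DegenerateSignalError("Lyapunov exponent undefined for constant signal")
    if delay is None:
        delay = _first_acf_zero_crossing(x)
    mean_period = _mean_period_samples(x, fs)
    if min_sep is None:
        min_sep = max(1, int(np.ceil(mean_period)))
    if fit_steps is None:
        fit_steps = max(2, int(round(0.5 * mean_period)))

    Y = delay_embed(x, embed_dim, delay)
    m = Y.shape[0]
    horizon = m - fit_steps
    if horizon < min_sep + 2:
        raise ValueError("signal too short for the requested fit range")

    tree = cKDTree(Y)
    k = min(m, 2 * min_sep + 4)
    dists, idx = tree.query(Y[:horizon], k=k)
    # distances below this are float-rounding duplicates, not true neighbors
    tol = 1e-6 * float(x.std())
    j_col = np.arange(horizon)[:, None]
    valid = ((np.abs(idx - j_col) > min_sep) & (dists > tol)
             & (idx < horizon))
    has = valid.any(axis=1)
    first = np.argmax(valid, axis=1)
    nn = np.full(m, -1, dtype=int)
    nn[:horizon] = np.where(has, idx[np.arange(horizon), first], -1)
    for j in np.flatnonzero(~has):
        # fallback: brute-force over all candidates
        d_all = np.linalg.norm(Y[:horizon] - Y[j], axis=1)
        mask = np.abs(np.arange(horizon) - j) > min_sep
        mask &= d_all > tol
        if mask.any():
            cand = np.flatnonzero(mask)
            nn[j] = cand[np.argmin(d_all[cand])]
    pairs = np.flatnonzero(nn >= 0)
    if pairs.size == 0:
        raise DegenerateSignalError("no valid neighbor pairs for divergence tracking")

    a = pairs
    b = nn[pairs]
    steps = np.arange(fit_steps + 1)
    mean_log_d = np.empty(steps.size)
    tiny = np.finfo(float).tiny
    for i in steps:
        d = np.linalg.norm(Y[a + i] - Y[b + i], axis=1)
        good = d > 0
        if not good.any():
            raise DegenerateSignalError("divergence collapsed to zero distances")
        mean_log_d[i] = np.log(np.maximum(d[good], tiny)).mean()
    t = steps / fs
    slope = np.polyfit(t, mean_log_d, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Hurst exponent (rescaled range)

def _window_ladder(n: int, min_window: int, n_sizes: int) -> np.ndarray:
    max_window = n // 2
    if max_window < min_window:
        raise ValueError(f"signal of length {n} too short for R/S analysis")
    sizes = np.unique(np.geomspace(min_window, max_window, n_sizes).astype(int))
    return sizes


def hurst_exponent(
    x: np.ndarray,
    window_sizes: Optional[Sequence[int]] = None,
    min_window: int = 32,
    n_sizes: int = 8,
) -> float:
    """Hurst exponent by classical rescaled-range (R/S) analysis.

    For each window size the series is split into non-overlapping windows;
    R is the range of the cumulative deviations from the window mean and S
    the window standard deviation. H is the slope of log(mean R/S) against
    log(size). Estimates outside (0, 1) trigger a warning and are clipped
    to (0, 1.2).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if window_sizes is None:
        window_sizes = _window_ladder(n, min_window, n_sizes)
    log_sizes, log_rs = [], []
    for w in window_sizes:
        w = int(w)
        k = n // w
        if k < 1:
            continue
        windows = x[: k * w].reshape(k, w)
        dev = windows - windows.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = windows.std(axis=1)
        ok = s > 0
        if not ok.any():
            continue
        rs = (r[ok] / s[ok]).mean()
        if rs > 0:
            log_sizes.append(np.log(w))
            log_rs.append(np.log(rs))
    if len(log_sizes) < 2:
        raise DegenerateSignalError("R/S analysis degenerate: too few usable windows")
    h = float(np.polyfit(log_sizes, log_rs, 1)[0])
    if not 0.0 < h < 1.0:
        warnings.warn(f"Hurst estimate {h:.3f} outside (0, 1)", RuntimeWarning)
    return float(np.clip(h, np.finfo(float).eps, 1.2))


# ---------------------------------------------------------------------------
# Lempel-Ziv (LZ76) complexity

def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of distinct phrases in the LZ76 exhaustive-history parsing of
    a binary sequence."""
    s = np.asarray(bits).astype(np.uint8).tobytes()
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    i, k, c = 0, 1, 0
    while i + k <= n:
        if s[i: i + k] in s[: i + k - 1]:
            k += 1
        else:
            c += 1
            i += k
            k = 1
    if k > 1:
        c += 1
    return c


def lempel_ziv_complexity(
    x: np.ndarray, binarize: str = "median", log_base: float = 2.0
) -> float:
    """Normalized LZ76 complexity: c(n) / (n / log n).

    The signal is binarized by its median (or mean) before parsing; an
    i.i.d. random bit sequence approaches 1 for large n.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 samples")
    if binarize == "median":
        thr = np.median(x)
    elif binarize == "mean":
        thr = x.mean()
    else:
        raise ValueError("binarize must be 'median' or 'mean'")
    bits = (x > thr).astype(np.uint8)
    c = lz76_phrase_count(bits)
    return float(c * (np.log(n) / np.log(log_base)) / n)
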