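"""Band-power features: absolute and relative power spectral density per
sub-band, and differential/rational inter-hemispheric asymmetry.

PSD is estimated per epoch with Welch averaging (1-s Hann segments, 50%
overlap) by default; a raw-periodogram mode is kept for exact single-tone
oracles. Band powers integrate the density over half-open bins
``low <= f < high`` so disjoint sub-bands add exactly.
"""
from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy import signal

from .bands import Band, BandScheme, DEFAULT_SCHEME, BAND_ORDER, PRIMARY_BANDS


class DegenerateSignalError(ValueError):
    """Raised for constant/zero-power inputs where a feature is undefined."""


def power_spectral_density(
    x: np.ndarray, fs: float, method: str = "welch"
) -> Tuple[np.ndarray, np.ndarray]:
    """PSD along the last axis. ``method`` is 'welch' or 'periodogram'."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if method == "welch":
        nperseg = min(int(fs), n)
        return signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                            noverlap=nperseg // 2, axis=-1)
    if method == "periodogram":
        return signal.periodogram(x, fs=fs, window="boxcar", axis=-1)
    raise ValueError(f"unknown PSD method {method!r}")


def _band_mask(freqs: np.ndarray, band: Band) -> np.ndarray:
    low, high = band
    return (freqs >= low) & (freqs < high)


def band_power_from_psd(freqs: np.ndarray, psd: np.ndarray, band: Band) -> np.ndarray:
    """Integrate a PSD over a half-open band: sum of bins times bin width."""
    df = freqs[1] - freqs[0]
    mask = _band_mask(freqs, band)
    return psd[..., mask].sum(axis=-1) * df


def band_power(
    x: np.ndarray, fs: float, band: Band, method: str = "welch"
) -> np.ndarray:
    """Absolute power (uV^2) of ``x`` in ``band``; works on any leading shape."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} outside (0, fs/2) for fs={fs}")
    freqs, psd = power_spectral_density(x, fs, method=method)
    return band_power_from_psd(freqs, psd, band)


def band_powers(
    x: np.ndarray, fs: float, scheme: BandScheme = DEFAULT_SCHEME,
    method: str = "welch",
) -> Dict[str, np.ndarray]:
    """Absolute power in all nine sub-bands plus the total band.

    Computes the PSD once and integrates each band from it.
    """
    freqs, psd = power_spectral_density(x, fs, method=method)
    out = {name: band_power_from_psd(freqs, psd, scheme[name]) for name in BAND_ORDER}
    out["total"] = band_power_from_psd(freqs, psd, scheme.total_band)
    return out


def relative_band_power(powers: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Relative power: each band's power over total-band power."""
    total = np.asarray(powers["total"], dtype=float)
    if np.any(total <= 0):
        raise DegenerateSignalError("degenerate signal: total-band power is 0")
    return {name: np.asarray(powers[name]) / total for name in BAND_ORDER}


def asymmetry(
    left_power: np.ndarray, right_power: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Differential (left - right) and rational (left / right) asymmetry."""
    left = np.asarray(left_power, dtype=float)
    right = np.asarray(right_power, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("band powers must be nonnegative")
    if np.any(right == 0):
        raise DegenerateSignalError("rational asymmetry undefined: right power is 0")
    return left - right, left / right


__all__ = [
    "power_spectral_density", "band_power", "band_power_from_psd",
    "band_powers", "relative_band_power", "asymmetry",
    "DegenerateSignalError", "PRIMARY_BANDS",
]
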