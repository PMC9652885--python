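"""Frequency-band scheme used by all spectral and coupling features.

Nine sub-bands are defined; the five *primary* bands (delta, theta, alpha,
beta, gamma) partition the total band [1, 50) Hz with half-open edges, while
alphaL/alphaH and betaL/betaH split alpha and beta respectively.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

Band = Tuple[float, float]

DEFAULT_BANDS: Dict[str, Band] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alphaL": (8.0, 10.0),
    "alphaH": (10.0, 12.0),
    "alpha": (8.0, 12.0),
    "betaL": (12.0, 18.0),
    "betaH": (18.0, 30.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: the five disjoint bands whose union is the total band
PRIMARY_BANDS: Tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: sub-band order used for feature naming
BAND_ORDER: Tuple[str, ...] = (
    "delta", "theta", "alphaL", "alphaH", "alpha", "betaL", "betaH", "beta", "gamma",
)

#: phase (low) bands and amplitude (high) bands for phase-amplitude coupling
PAC_LOW_BANDS: Tuple[str, ...] = ("delta", "theta")
PAC_HIGH_BANDS: Tuple[str, ...] = ("alphaL", "alphaH", "alpha", "betaL", "betaH", "beta", "gamma")


def _default_bands() -> Dict[str, Band]:
    return dict(DEFAULT_BANDS)


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands plus the total band used for normalization."""

    bands: Dict[str, Band] = field(default_factory=_default_bands)
    total_band: Band = (1.0, 50.0)

    def __post_init__(self) -> None:
        for name in BAND_ORDER:
            if name not in self.bands:
                raise ValueError(f"band scheme is missing band {name!r}")
        lo, hi = self.total_band
        if not lo < hi:
            raise ValueError("total band must have low < high")
        # the five primary bands must tile the total band without gaps
        edges = sorted(self.bands[b] for b in PRIMARY_BANDS)
        if edges[0][0] != lo or edges[-1][1] != hi:
            raise ValueError("primary bands do not span the total band")
        for (a, b), (c, d) in zip(edges, edges[1:]):
            if b != c:
                raise ValueError("primary bands must be contiguous and disjoint")
        # split bands must reassemble their parents
        if (self.bands["alphaL"][0], self.bands["alphaH"][1]) != self.bands["alpha"]:
            raise ValueError("alphaL/alphaH must partition alpha")
        if (self.bands["betaL"][0], self.bands["betaH"][1]) != self.bands["beta"]:
            raise ValueError("betaL/betaH must partition beta")

    def __getitem__(self, name: str) -> Band:
        return self.bands[name]


DEFAULT_SCHEME = BandScheme()
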