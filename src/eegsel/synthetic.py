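"""Synthetic two-group resting-EEG cohorts.

Each channel carries a 1/f-like fractional-Gaussian-noise background whose
Hurst parameter differs between groups, an eyes-closed alpha oscillation and
a white-noise floor. Group effects are planted as directions: extra delta
amplitude on one left electrode (inter-hemispheric delta asymmetry), and
theta-phase modulation of a high-beta carrier at a posterior electrode whose
modulation depth differs between groups. Amplitudes are kept within the
artifact-rejection bound so every epoch survives preprocessing.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .montage import Montage, standard_montage
from .preprocessing import EpochSet


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a two-group cohort."""

    n_per_group: int = 21
    fs: float = 250.0
    epoch_seconds: float = 5.0
    epochs_per_subject: int = 20
    rng_seed: int = 0
    # group effects (directions, not calibrated magnitudes)
    hurst_mci: float = 0.78
    hurst_hc: float = 0.73
    delta_asym_gain: float = 3.0       # extra delta amplitude (uV) on asym_channel, MCI only
    asym_channel: str = "FC5"
    pac_depth_mci: float = 0.25
    pac_depth_hc: float = 0.75
    pac_channel: str = "P8"
    # shared structure
    background_amp: float = 6.0
    alpha_amp: float = 4.0
    alpha_freq: float = 10.0
    delta_base_amp: float = 1.0
    delta_freq: float = 2.0
    theta_amp: float = 3.0
    theta_freq: float = 6.0
    carrier_amp: float = 3.0
    carrier_freq: float = 24.0
    noise_floor: float = 1.0
    between_subject_sd: float = 0.15
    hurst_subject_sd: float = 0.02
    amplitude_bound: float = 74.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for h in (self.hurst_mci, self.hurst_hc):
            if not 0 < h < 1:
                raise ValueError("Hurst parameters must lie in (0, 1)")
        for d in (self.pac_depth_mci, self.pac_depth_hc):
            if not 0 <= d <= 1:
                raise ValueError("PAC depths must lie in [0, 1]")

    def null(self) -> "CohortSpec":
        """Copy with every group effect removed (both groups identical)."""
        h = (self.hurst_mci + self.hurst_hc) / 2
        d = (self.pac_depth_mci + self.pac_depth_hc) / 2
        return replace(self, hurst_mci=h, hurst_hc=h, delta_asym_gain=0.0,
                       pac_depth_mci=d, pac_depth_hc=d)

    def scaled_effects(self, factor: float) -> "CohortSpec":
        """Copy with effect separations scaled around their midpoints."""
        hm = (self.hurst_mci + self.hurst_hc) / 2
        dh = (self.hurst_mci - self.hurst_hc) / 2 * factor
        pm = (self.pac_depth_mci + self.pac_depth_hc) / 2
        dp = (self.pac_depth_mci - self.pac_depth_hc) / 2 * factor
        return replace(
            self,
            hurst_mci=float(np.clip(hm + dh, 0.05, 0.95)),
            hurst_hc=float(np.clip(hm - dh, 0.05, 0.95)),
            delta_asym_gain=self.delta_asym_gain * factor,
            pac_depth_mci=float(np.clip(pm + dp, 0.0, 1.0)),
            pac_depth_hc=float(np.clip(pm - dp, 0.0, 1.0)),
        )


def fractional_gaussian_noise(
    n: int, hurst: float, rng: "int | np.random.Generator"
) -> np.ndarray:
    """Fractional Gaussian noise by Davies-Harte circulant embedding.

    Zero mean, unit variance (up to sampling noise), exact target
    autocovariance when the circulant eigenvalues are nonnegative (small
    negative eigenvalues are clipped).
    """
    if not 0 < hurst < 1:
        raise ValueError(f"Hurst parameter must be in (0, 1), got {hurst}")
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    eig = np.fft.fft(row).real
    eig = np.maximum(eig, 0.0)
    m = row.size
    w = gen.standard_normal(m) + 1j * gen.standard_normal(m)
    synth = np.fft.fft(np.sqrt(eig / m) * w)
    return synth.real[:n]


def _subject_seeds(rng_seed: int, n_subjects: int) -> List[np.random.SeedSequence]:
    return np.random.SeedSequence(rng_seed).spawn(n_subjects)


def simulate_subject(
    group: str,
    spec: CohortSpec,
    subject_seed: "int | np.random.SeedSequence",
    subject_id: str = None,
    montage: Montage = None,
) -> EpochSet:
    """One subject's epoch set: epochs x 32 channels x fs*epoch_seconds."""
    if group not in ("MCI", "HC"):
        raise ValueError("group must be 'MCI' or 'HC'")
    montage = montage or standard_montage()
    rng = np.random.default_rng(subject_seed)
    fs = spec.fs
    epoch_len = int(round(fs * spec.epoch_seconds))
    n_total = spec.epochs_per_subject * epoch_len
    t = np.arange(n_total) / fs
    is_mci = group == "MCI"

    h_group = spec.hurst_mci if is_mci else spec.hurst_hc
    h_subj = float(np.clip(h_group + rng.normal(0, spec.hurst_subject_sd),
                           0.05, 0.95))
    depth = spec.pac_depth_mci if is_mci else spec.pac_depth_hc
    # per-subject amplitude variability (lognormal multipliers)
    m_bg, m_alpha, m_delta, m_pac = np.exp(
        rng.normal(0.0, spec.between_subject_sd, size=4))

    n_ch = len(montage.channels)
    data = np.empty((n_ch, n_total))
    for c, ch in enumerate(montage.channels):
        x = spec.background_amp * m_bg * fractional_gaussian_noise(n_total, h_subj, rng)
        x += (spec.alpha_amp * m_alpha
              * np.sin(2 * np.pi * spec.alpha_freq * t + rng.uniform(0, 2 * np.pi)))
        x += spec.noise_floor * rng.standard_normal(n_total)
        pair = montage.pair_of(ch)
        if pair is not None and spec.asym_channel in pair:
            amp = spec.delta_base_amp
            if ch == spec.asym_channel and is_mci:
                amp += spec.delta_asym_gain
            x += (amp * m_delta
                  * np.sin(2 * np.pi * spec.delta_freq * t + rng.uniform(0, 2 * np.pi)))
        if ch == spec.pac_channel:
            phase = 2 * np.pi * spec.theta_freq * t + rng.uniform(0, 2 * np.pi)
            theta = spec.theta_amp * m_pac * np.sin(phase)
            envelope = (1.0 + depth * np.cos(phase)) / 2.0
            carrier = (spec.carrier_amp * m_pac * envelope
                       * np.sin(2 * np.pi * spec.carrier_freq * t
                                + rng.uniform(0, 2 * np.pi)))
            x += theta + carrier
        data[c] = x

    peak = np.abs(data).max()
    if peak > spec.amplitude_bound:
        data *= spec.amplitude_bound / peak
    epochs = data.reshape(n_ch, spec.epochs_per_subject, epoch_len).transpose(1, 0, 2)
    sid = subject_id or f"{group}-{rng.integers(0, 10**9):09d}"
    return EpochSet(subject_id=sid, group=group, data=epochs, fs=fs,
                    channel_labels=montage.channels)


def simulate_cohort(
    spec: CohortSpec, montage: Montage = None
) -> Tuple[List[EpochSet], List[str]]:
    """Balanced cohort of n_per_group MCI + n_per_group HC subjects.

    Subject seeds derive deterministically from ``spec.rng_seed``.
    """
    montage = montage or standard_montage()
    seeds = _subject_seeds(spec.rng_seed, 2 * spec.n_per_group)
    subjects: List[EpochSet] = []
    labels: List[str] = []
    for i in range(spec.n_per_group):
        subjects.append(simulate_subject(
            "MCI", spec, seeds[i], subject_id=f"MCI{i + 1:02d}", montage=montage))
        labels.append("MCI")
    for i in range(spec.n_per_group):
        subjects.append(simulate_subject(
            "HC", spec, seeds[spec.n_per_group + i],
            subject_id=f"HC{i + 1:02d}", montage=montage))
        labels.append("HC")
    return subjects, labels
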