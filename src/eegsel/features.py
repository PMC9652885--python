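"""Subject-level feature table construction.

Per channel there are 39 features — 9 absolute band powers (APSD), 9
relative band powers (RPSD), 14 phase-amplitude couplings (PAC), 3 Hjorth
parameters, Shannon entropy (SE), Lyapunov exponent (LE), Hurst exponent
(HE) and Lempel-Ziv complexity (KC) — plus 18 per symmetric pair (9 DASM +
9 RASM), giving 39*32 + 18*14 = 1500 columns for the full montage. Features
are computed per epoch and averaged across a subject's epochs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .bands import (BAND_ORDER, PAC_HIGH_BANDS, PAC_LOW_BANDS, BandScheme,
                    DEFAULT_SCHEME)
from .montage import Montage, standard_montage
from .nonlinear import (DEFAULT_NONLINEAR, NonlinearParams, high_band_envelope,
                        hjorth, hurst_exponent, lempel_ziv_complexity,
                        lyapunov_exponent, shannon_entropy)
from .preprocessing import EpochSet
from .spectral import band_power_from_psd, power_spectral_density

PER_CHANNEL_FAMILY_COUNT = 39   # 9 + 9 + 14 + 3 + 1 + 1 + 1 + 1
PER_PAIR_FAMILY_COUNT = 18      # 9 DASM + 9 RASM

PAC_PAIRS: Tuple[Tuple[str, str], ...] = tuple(
    (low, high) for low in PAC_LOW_BANDS for high in PAC_HIGH_BANDS)

HJORTH_NAMES = ("HjorthActivity", "HjorthMobility", "HjorthComplexity")


def channel_feature_names(channel: str) -> List[str]:
    names = [f"APSD_{b}_{channel}" for b in BAND_ORDER]
    names += [f"RPSD_{b}_{channel}" for b in BAND_ORDER]
    names += [f"PAC_{lo}-{hi}_{channel}" for lo, hi in PAC_PAIRS]
    names += [f"{h}_{channel}" for h in HJORTH_NAMES]
    names += [f"SE_{channel}", f"LE_{channel}", f"HE_{channel}", f"KC_{channel}"]
    return names


def pair_feature_names(pair: Tuple[str, str]) -> List[str]:
    tag = f"{pair[0]}-{pair[1]}"
    return ([f"DASM_{b}_{tag}" for b in BAND_ORDER]
            + [f"RASM_{b}_{tag}" for b in BAND_ORDER])


def feature_schema(
    montage: Optional[Montage] = None,
    channels: Optional[Sequence[str]] = None,
) -> List[str]:
    """Ordered feature-column names for a channel subset (default: all 32).

    Asymmetry columns appear only for pairs whose two members are both in
    the subset.
    """
    montage = montage or standard_montage()
    if channels is None:
        channels = montage.channels
    unknown = set(channels) - set(montage.channels)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    chan_set = set(channels)
    ordered = [c for c in montage.channels if c in chan_set]
    names: List[str] = []
    for ch in ordered:
        names.extend(channel_feature_names(ch))
    for pair in montage.pairs:
        if pair[0] in chan_set and pair[1] in chan_set:
            names.extend(pair_feature_names(pair))
    return names


def extract_epoch_features(
    epoch: np.ndarray,
    fs: float,
    channel_labels: Sequence[str],
    montage: Optional[Montage] = None,
    scheme: BandScheme = DEFAULT_SCHEME,
    params: NonlinearParams = DEFAULT_NONLINEAR,
    spectral_method: str = "welch",
) -> Dict[str, float]:
    """All features of one epoch (channels x samples), keyed by column name."""
    montage = montage or standard_montage()
    epoch = np.asarray(epoch, dtype=float)
    labels = list(channel_labels)
    if epoch.shape[0] != len(labels):
        raise ValueError("channel axis does not match channel_labels")

    out: Dict[str, float] = {}

    # spectral: one PSD for all channels, integrated per band
    freqs, psd = power_spectral_density(epoch, fs, method=spectral_method)
    powers = {b: band_power_from_psd(freqs, psd, scheme[b]) for b in BAND_ORDER}
    total = band_power_from_psd(freqs, psd, scheme.total_band)
    if np.any(total <= 0):
        bad = labels[int(np.argmax(total <= 0))]
        raise ValueError(f"degenerate (zero-power) signal on channel {bad}")

    # PAC: one envelope + coherence per high band, averaged per low band
    n = epoch.shape[-1]
    nperseg = min(int(fs), n)
    pac: Dict[Tuple[str, str], np.ndarray] = {}
    for hi in PAC_HIGH_BANDS:
        env = high_band_envelope(epoch, fs, scheme[hi],
                                 filter_order=params.pac_filter_order)
        cf, cxy = signal.coherence(epoch, env, fs=fs, window="hann",
                                   nperseg=nperseg, noverlap=nperseg // 2,
                                   axis=-1)
        for lo in PAC_LOW_BANDS:
            lo_band = scheme[lo]
            mask = (cf >= lo_band[0]) & (cf < lo_band[1])
            pac[(lo, hi)] = cxy[..., mask].mean(axis=-1)

    activity, mobility, complexity = hjorth(epoch)

    for i, ch in enumerate(labels):
        for b in BAND_ORDER:
            out[f"APSD_{b}_{ch}"] = float(powers[b][i])
        for b in BAND_ORDER:
            out[f"RPSD_{b}_{ch}"] = float(powers[b][i] / total[i])
        for lo, hi in PAC_PAIRS:
            out[f"PAC_{lo}-{hi}_{ch}"] = float(pac[(lo, hi)][i])
        out[f"HjorthActivity_{ch}"] = float(activity[i])
        out[f"HjorthMobility_{ch}"] = float(mobility[i])
        out[f"HjorthComplexity_{ch}"] = float(complexity[i])
        x = epoch[i]
        out[f"SE_{ch}"] = shannon_entropy(x, bins=params.entropy_bins)
        out[f"LE_{ch}"] = lyapunov_exponent(
            x, fs=fs, embed_dim=params.lyap_embed_dim,
            delay=params.lyap_delay, fit_steps=params.lyap_fit_steps)
        out[f"HE_{ch}"] = hurst_exponent(
            x, min_window=params.hurst_min_window, n_sizes=params.hurst_n_sizes)
        out[f"KC_{ch}"] = lempel_ziv_complexity(
            x, binarize=params.lz_binarize, log_base=params.lz_log_base)

    label_index = {ch: i for i, ch in enumerate(labels)}
    for left, right in montage.pairs:
        if left in label_index and right in label_index:
            tag = f"{left}-{right}"
            li, ri = label_index[left], label_index[right]
            for b in BAND_ORDER:
                lp, rp = float(powers[b][li]), float(powers[b][ri])
                out[f"DASM_{b}_{tag}"] = lp - rp
                out[f"RASM_{b}_{tag}"] = lp / rp if rp > 0 else np.nan
    return out


@dataclass
class FeatureTable:
    """Subjects x named features, with a group label per subject."""

    values: pd.DataFrame          # index: subject_id, columns: feature names
    labels: pd.Series             # index: subject_id, values in {"MCI", "HC"}

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share the subject index")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][:5].tolist()
            raise ValueError(f"missing values in features {bad}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, columns: Sequence[str]) -> "FeatureTable":
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise KeyError(f"unknown feature columns {missing[:5]}")
        return FeatureTable(self.values.loc[:, list(columns)], self.labels)

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "label", self.labels)
        df.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("label")
        return cls(df, labels)


def build_feature_table(
    epoch_sets: Sequence[EpochSet],
    montage: Optional[Montage] = None,
    channels: Optional[Sequence[str]] = None,
    scheme: BandScheme = DEFAULT_SCHEME,
    params: NonlinearParams = DEFAULT_NONLINEAR,
    spectral_method: str = "welch",
) -> FeatureTable:
    """Epoch-averaged feature table over a cohort.

    ``channels`` restricts extraction to a subset (used to evaluate a single
    configuration cheaply); default is the full montage.
    """
    montage = montage or standard_montage()
    if not epoch_sets:
        raise ValueError("no epoch sets given")
    n_epochs = epoch_sets[0].n_epochs
    schema = feature_schema(montage, channels)
    want = set(channels) if channels is not None else set(montage.channels)

    rows, ids, labels = [], [], []
    for es in epoch_sets:
        if es.n_epochs != n_epochs:
            raise ValueError(
                f"subject {es.subject_id!r} has {es.n_epochs} epochs, "
                f"expected {n_epochs}")
        missing = want - set(es.channel_labels)
        if missing:
            raise ValueError(
                f"subject {es.subject_id!r} is missing channels {sorted(missing)}")
        sel = [i for i, ch in enumerate(es.channel_labels) if ch in want]
        sel_labels = [es.channel_labels[i] for i in sel]
        acc = np.zeros(len(schema))
        for ep in range(n_epochs):
            feats = extract_epoch_features(
                es.data[ep, sel, :], es.fs, sel_labels, montage=montage,
                scheme=scheme, params=params, spectral_method=spectral_method)
            acc += np.array([feats[name] for name in schema])
        rows.append(acc / n_epochs)
        ids.append(es.subject_id)
        labels.append(es.group)

    values = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="subject_id"),
                          columns=schema)
    return FeatureTable(values, pd.Series(labels, index=values.index, name="label"))
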