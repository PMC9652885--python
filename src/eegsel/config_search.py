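"""Bilaterally symmetric electrode-configuration enumeration and exhaustive
ranking by cross-validated accuracy."""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .features import FeatureTable, channel_feature_names, pair_feature_names
from .evaluation import CVResult, evaluate_configuration
from .montage import Montage, standard_montage


@dataclass(frozen=True)
class ElectrodeConfiguration:
    """A set of electrodes built from whole symmetric pairs plus midline
    electrodes (each pair is included or excluded atomically)."""

    pairs_used: Tuple[Tuple[str, str], ...] = ()
    midline_used: Tuple[str, ...] = ()

    @property
    def electrodes(self) -> Tuple[str, ...]:
        labels: List[str] = []
        for left, right in self.pairs_used:
            labels.extend((left, right))
        labels.extend(self.midline_used)
        return tuple(labels)

    @property
    def size(self) -> int:
        return 2 * len(self.pairs_used) + len(self.midline_used)

    @property
    def name(self) -> str:
        return "-".join(self.electrodes)

    def sort_key(self, montage: Montage) -> Tuple[int, ...]:
        return tuple(sorted(montage.index(ch) for ch in self.electrodes))


def enumerate_configurations(
    k: int, montage: Optional[Montage] = None
) -> List[ElectrodeConfiguration]:
    """All configurations of exactly ``k`` electrodes formed from whole
    symmetric pairs and midline electrodes.

    The count is sum over 2p + m = k of C(n_pairs, p) * C(n_midline, m);
    for the 14-pair / 4-midline montage and k = 2, 4, 6, 8 this gives
    20, 176, 924 and 3276. Order is deterministic.
    """
    montage = montage or standard_montage()
    if not 1 <= k <= len(montage.channels):
        raise ValueError(f"configuration size {k} out of range")
    configs: List[ElectrodeConfiguration] = []
    for n_pairs in range(len(montage.pairs) + 1):
        n_mid = k - 2 * n_pairs
        if n_mid < 0 or n_mid > len(montage.midline):
            continue
        for pair_combo in itertools.combinations(montage.pairs, n_pairs):
            for mid_combo in itertools.combinations(montage.midline, n_mid):
                configs.append(ElectrodeConfiguration(pair_combo, mid_combo))
    return configs


def configuration_from_labels(
    labels: Sequence[str], montage: Optional[Montage] = None
) -> Tuple[Tuple[str, ...], Tuple[Tuple[str, str], ...]]:
    """Split an arbitrary electrode list into (channels, complete pairs).

    Device montages need not obey the symmetry constraint; asymmetry
    features are attached only to pairs whose two members are present.
    """
    montage = montage or standard_montage()
    unknown = set(labels) - set(montage.channels)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    chan_set = set(labels)
    channels = tuple(ch for ch in montage.channels if ch in chan_set)
    pairs = tuple(p for p in montage.pairs
                  if p[0] in chan_set and p[1] in chan_set)
    return channels, pairs


def restrict_features(
    table: FeatureTable,
    config: "ElectrodeConfiguration | Sequence[str]",
    montage: Optional[Montage] = None,
) -> FeatureTable:
    """Columns of ``table`` belonging to a configuration: all per-channel
    features of its electrodes plus DASM/RASM for pairs wholly inside it."""
    montage = montage or standard_montage()
    if isinstance(config, ElectrodeConfiguration):
        labels: Sequence[str] = config.electrodes
    else:
        labels = config
    channels, pairs = configuration_from_labels(labels, montage)
    columns: List[str] = []
    for ch in channels:
        columns.extend(channel_feature_names(ch))
    for pair in pairs:
        columns.extend(pair_feature_names(pair))
    return table.select(columns)


@dataclass
class SearchResult:
    """Ranking of all configurations of one size by CV accuracy."""

    k: int
    ranking: List[Tuple[ElectrodeConfiguration, CVResult]]

    @property
    def best(self) -> Tuple[ElectrodeConfiguration, CVResult]:
        return self.ranking[0]

    def to_records(self) -> List[dict]:
        return [
            {"rank": i + 1, "configuration": cfg.name, "k": self.k,
             "accuracy": res.accuracy, "sensitivity": res.sensitivity,
             "specificity": res.specificity, "best_N": res.best_n,
             "block_sd": res.block_sd}
            for i, (cfg, res) in enumerate(self.ranking)
        ]


def search_optimal(
    k: int,
    table: FeatureTable,
    montage: Optional[Montage] = None,
    max_features: int = 15,
    kernel: str = "linear",
    C: float = 1.0,
    progress: bool = False,
) -> SearchResult:
    """Evaluate every symmetric configuration of size ``k`` and rank them.

    Ranking is by accuracy (desc), then sensitivity (desc), then electrode
    order in the montage — independent of enumeration order.
    """
    montage = montage or standard_montage()
    configs = enumerate_configurations(k, montage)
    iterator: Iterable[ElectrodeConfiguration] = configs
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(configs, desc=f"k={k}")
        except ImportError:
            pass
    scored = []
    for cfg in iterator:
        try:
            sub = restrict_features(table, cfg, montage)
            res = evaluate_configuration(sub, max_features=max_features,
                                         kernel=kernel, C=C)
        except Exception as exc:
            raise RuntimeError(
                f"evaluation failed for configuration {cfg.name}: {exc}") from exc
        scored.append((cfg, res))
    scored.sort(key=lambda cr: (-cr[1].accuracy, -cr[1].sensitivity,
                                cr[0].sort_key(montage)))
    return SearchResult(k=k, ranking=scored)
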