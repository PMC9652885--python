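"""32-channel scalp montage: channel order, midline set, symmetric pairs and
the electrode layouts of five commercial headsets."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

#: 32 electrode labels of the modified 10-20 layout, in acquisition order
CHANNELS_32: Tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

MIDLINE: Tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")

#: left/right pairs mirrored across the sagittal midline
SYMMETRIC_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"),
    ("FC5", "FC6"), ("FC1", "FC2"), ("T7", "T8"), ("C3", "C4"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P7", "P8"), ("P3", "P4"),
    ("PO3", "PO4"), ("O1", "O2"),
)

DEVICE_MONTAGES: Dict[str, Tuple[str, ...]] = {
    "Focusband": ("Fp1", "Fp2"),
    "Insight": ("Pz", "AF3", "AF4", "T7", "T8"),
    "DSI-7": ("Pz", "F3", "F4", "C3", "C4", "P3", "P4"),
    "Imec": ("Fz", "Cz", "F7", "F8", "F3", "F4", "C3", "C4"),
    "EPOC": ("AF3", "AF4", "F7", "F8", "F3", "F4", "FC5", "FC6",
             "T7", "T8", "P7", "P8", "O1", "O2"),
}


@dataclass(frozen=True)
class Montage:
    """Electrode layout: full channel list, midline electrodes, symmetric
    pairs, and named device montages."""

    channels: Tuple[str, ...] = CHANNELS_32
    midline: Tuple[str, ...] = MIDLINE
    pairs: Tuple[Tuple[str, str], ...] = SYMMETRIC_PAIRS
    device_montages: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEVICE_MONTAGES))

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if len(self.midline) + 2 * len(self.pairs) != len(self.channels):
            raise ValueError("midline + 2*pairs must cover all channels")
        covered = set(self.midline)
        for left, right in self.pairs:
            covered.update((left, right))
        if covered != set(self.channels):
            raise ValueError("pair/midline labels do not match channel list")
        for name, labels in self.device_montages.items():
            unknown = set(labels) - set(self.channels)
            if unknown:
                raise ValueError(f"device {name!r} uses unknown labels {sorted(unknown)}")

    def index(self, label: str) -> int:
        return self.channels.index(label)

    def pair_of(self, label: str) -> Tuple[str, str] | None:
        """Return the symmetric pair containing ``label``, or None for midline."""
        for pair in self.pairs:
            if label in pair:
                return pair
        return None


def standard_montage() -> Montage:
    """The default 32-channel montage."""
    return Montage()
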