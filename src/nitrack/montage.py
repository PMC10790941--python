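"""Electrode montage definitions and the 41-channel analysis subset.

The recording montage is a 64-channel international 10-20 layout (reference
FCz, ground Fpz, so neither appears as a recorded channel).  Feature
extraction uses a 41-channel subset covering the frontal, temporal, parietal
and occipital regions; the strip of electrodes over the central sulcus
(FC*, C*, CP* rows) is excluded.  The subset ships as an editable two-column
CSV (``channel,region``) so studies with a different cap can swap it out.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

REGIONS = ("frontal", "temporal", "parietal", "occipital")

#: reference and ground positions, excluded from the analysis subset along
#: with the central-strip rows (FC*, C*, CP*)
_EXCLUDED_EXACT = {"FCz", "FPz", "Fpz"}

#: Full 64-channel recording montage (10-20 names).
CHANNELS_64: tuple[str, ...] = (
    # frontal
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    # fronto-central / central / centro-parietal strip (excluded from features)
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    # temporal
    "FT9", "FT7", "FT8", "FT10", "T7", "T8", "TP7", "TP8", "TP9", "TP10",
    # parietal
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    # occipital / parieto-occipital
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
)

#: Default region assignment for every recorded channel (used by the
#: synthetic generator to place oscillatory sources; the central strip gets
#: its own region and never enters the feature subset).
REGION_OF_64: dict[str, str] = {}
for _ch in CHANNELS_64:
    if _ch.startswith(("Fp", "AF", "F")) and not _ch.startswith("FC") and not _ch.startswith("FT"):
        REGION_OF_64[_ch] = "frontal"
    elif _ch.startswith(("FT", "T", "TP")):
        REGION_OF_64[_ch] = "temporal"
    elif _ch.startswith("P") and not _ch.startswith("PO"):
        REGION_OF_64[_ch] = "parietal"
    elif _ch.startswith(("PO", "O", "I")):
        REGION_OF_64[_ch] = "occipital"
    else:
        REGION_OF_64[_ch] = "central"
del _ch

#: Occipital channels used for individual-alpha-frequency estimation.
DEFAULT_IAF_CHANNELS = ("O1", "Oz", "O2")


def _is_central(name: str) -> bool:
    # central strip = FC, C or CP rows; FCz (reference) and Fpz (ground)
    # are excluded outright.
    if name in _EXCLUDED_EXACT:
        return True
    if name.startswith("FC") or name.startswith("CP"):
        return True
    return name.startswith("C")


class MontageError(ValueError):
    """Raised when a channel subset violates the analysis-montage contract."""


@dataclass(frozen=True)
class MontageSubset:
    """Ordered 41-channel feature montage with a channel -> region map."""

    channel_labels: tuple[str, ...]
    region_of: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.channel_labels) != 41:
            raise MontageError(
                f"analysis montage must have exactly 41 channels, got {len(self.channel_labels)}"
            )
        if len(set(self.channel_labels)) != 41:
            raise MontageError("duplicate channel in analysis montage")
        for ch in self.channel_labels:
            if _is_central(ch):
                raise MontageError(f"channel {ch} lies on the excluded central strip")
            region = self.region_of.get(ch)
            if region not in REGIONS:
                raise MontageError(f"channel {ch} mapped to unknown region {region!r}")

    @property
    def regions(self) -> tuple[str, ...]:
        return REGIONS

    def channels_in(self, region: str) -> tuple[str, ...]:
        return tuple(ch for ch in self.channel_labels if self.region_of[ch] == region)


def load_montage(path: str | Path | None = None) -> MontageSubset:
    """Load a channel/region CSV; ``None`` loads the packaged default."""
    if path is None:
        ref = resources.files("nitrack.data").joinpath("montage41.csv")
        text = ref.read_text(encoding="utf-8")
        rows = list(csv.reader(text.splitlines()))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    rows = [r for r in rows if r and not r[0].startswith("#")]
    if rows and rows[0][0].lower() == "channel":
        rows = rows[1:]
    labels = tuple(r[0].strip() for r in rows)
    region_of = {r[0].strip(): r[1].strip() for r in rows}
    return MontageSubset(channel_labels=labels, region_of=region_of)


def default_montage() -> MontageSubset:
    return load_montage(None)
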