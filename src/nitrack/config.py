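"""Flat pipeline configuration with YAML round-trip and presets.

Defaults mirror the study design: 15 participants x 60 trials in blocks of
6, 500 Hz acquisition downsampled to 256 Hz, 1 s epochs, 10 mRMR features,
100 classification runs, 1000 permutations, bottom/top 10% trials labeled.
Two additional presets trade cohort size for runtime: ``desk`` (6 x 20,
minutes) and ``tiny`` (3 x 12, seconds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .synthetic import CohortSpec, TrajectoryParams

__all__ = ["PipelineConfig", "preset"]


@dataclass(frozen=True)
class PipelineConfig:
    # cohort design
    n_participants: int = 15
    responder_fraction: float = 9 / 15
    n_trials: int = 60
    block_size: int = 6
    sampling_rate: float = 500.0
    max_trial_duration_s: float = 180.0
    min_trial_duration_s: float = 5.0
    baseline_duration_s: float = 60.0
    iaf_low: float = 8.5
    iaf_high: float = 12.5
    alpha_effect_size: float = 2.0
    noise_exponent: float = 1.0
    alpha_freq_offset: float = 1.0
    nonresponder_decreasing_fraction: float = 0.5
    ideal_time_low: float = 30.0
    ideal_time_high: float = 60.0
    plateau_block: int = 7
    channel_set: str = "full64"  # or "montage"
    # analysis
    epoch_s: float = 1.0
    extreme_fraction: float = 0.10
    corr_extreme_fraction: float = 0.20
    k_features: int = 10
    n_runs: int = 100
    n_perm: int = 1000
    runs_per_perm: int = 1
    svm_c: float = 1.0
    mrmr_bins: int = 3
    effectiveness_alpha: float = 0.001
    iaf_channels: str = "O1,Oz,O2"
    montage_path: str = ""
    seed: int = 0

    def cohort_spec(self) -> CohortSpec:
        from .montage import CHANNELS_64, REGION_OF_64

        if self.channel_set == "full64":
            channels = CHANNELS_64
        elif self.channel_set == "montage":
            channels = tuple(ch for ch in CHANNELS_64 if REGION_OF_64[ch] != "central")
        else:
            raise ValueError(f"unknown channel_set {self.channel_set!r}")
        return CohortSpec(
            n_participants=self.n_participants,
            responder_fraction=self.responder_fraction,
            n_trials=self.n_trials,
            block_size=self.block_size,
            sampling_rate=self.sampling_rate,
            max_trial_duration=self.max_trial_duration_s,
            min_trial_duration=self.min_trial_duration_s,
            baseline_duration=self.baseline_duration_s,
            iaf_range=(self.iaf_low, self.iaf_high),
            alpha_effect_size=self.alpha_effect_size,
            noise_exponent=self.noise_exponent,
            alpha_freq_offset=self.alpha_freq_offset,
            nonresponder_decreasing_fraction=self.nonresponder_decreasing_fraction,
            ideal_time_range=(self.ideal_time_low, self.ideal_time_high),
            trajectory=TrajectoryParams(plateau_block=self.plateau_block),
            channel_labels=channels,
            seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


_PRESETS = {
    "full": dict(),
    "desk": dict(
        n_participants=6,
        responder_fraction=4 / 6,
        n_trials=20,
        block_size=5,
        max_trial_duration_s=30.0,
        baseline_duration_s=30.0,
        ideal_time_low=8.0,
        ideal_time_high=12.0,
        plateau_block=3,
        channel_set="montage",
        n_runs=10,
        n_perm=50,
    ),
    "tiny": dict(
        n_participants=3,
        responder_fraction=2 / 3,
        n_trials=12,
        block_size=6,
        max_trial_duration_s=15.0,
        baseline_duration_s=30.0,
        ideal_time_low=5.0,
        ideal_time_high=8.0,
        plateau_block=2,
        channel_set="montage",
        n_runs=3,
        n_perm=10,
    ),
}


def preset(name: str, **overrides) -> PipelineConfig:
    """Built-in configurations: ``full`` (hours-scale complete design),
    ``desk`` (minutes), ``tiny`` (seconds, smoke tests)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return replace(PipelineConfig(**_PRESETS[name]), **overrides)
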