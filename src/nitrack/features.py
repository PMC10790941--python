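"""Epoch feature tables and proficiency class labels.

Normalized band power is cut into non-overlapping 1 s epochs per navigation
trial; each epoch's features are the mean z-scored power per channel and
band (41 channels x 4 bands = 164 features, named ``<channel>_<band>``).
Class labels come from ranking a participant's trials by self-reported
certainty (ties broken by completion order): the bottom 10% of trials are
"low proficiency" (class 0), the top 10% "high proficiency" (class 1), the
rest unlabeled.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .montage import MontageSubset
from .preprocessing import BAND_NAMES, NormalizedPower

__all__ = [
    "UNLABELED",
    "ANNOTATION_COLUMNS",
    "feature_columns",
    "epoch_features",
    "rank_trials",
    "assign_classes",
    "time_performance",
    "behavior_table",
    "label_feature_table",
    "build_feature_table",
]

log = logging.getLogger(__name__)

UNLABELED = -1

ANNOTATION_COLUMNS = (
    "participant_id",
    "trial_index",
    "block_index",
    "epoch_index",
    "class_label",
)


def feature_columns(montage: MontageSubset) -> list[str]:
    """Feature names in canonical order: channels (montage order) x bands."""
    return [f"{ch}_{band}" for ch in montage.channel_labels for band in BAND_NAMES]


def epoch_features(norm: NormalizedPower, montage: MontageSubset) -> pd.DataFrame:
    """1 s epoch x feature table for one participant's navigation trials.

    Per trial there are ``floor(duration_s)`` epochs; a trailing partial
    second is discarded.  Each value is the mean z-scored power over the
    epoch's samples for that channel and band.
    """
    fs = int(round(norm.sampling_rate))
    labels = list(norm.channel_labels)
    missing = [ch for ch in montage.channel_labels if ch not in labels]
    if missing:
        raise ValueError(f"montage channels absent from power series: {missing}")
    ch_idx = np.array([labels.index(ch) for ch in montage.channel_labels])

    segs = norm.segments
    nav = segs[segs["segment_kind"] == "navigation"]

    rows_ann: list[tuple] = []
    blocks: list[np.ndarray] = []
    band_arrays = {b: norm.power[b] for b in BAND_NAMES}
    for seg in nav.itertuples():
        start, end = int(seg.start_sample), int(seg.end_sample)
        n_epochs = (end - start) // fs
        if n_epochs == 0:
            log.warning(
                "trial %s of %s shorter than 1 s after resampling; no epochs",
                seg.trial_index, norm.participant_id,
            )
            continue
        used = n_epochs * fs
        # (bands, channels, epochs, fs) -> mean over samples
        per_band = []
        for b in BAND_NAMES:
            x = band_arrays[b][ch_idx, start:start + used]
            per_band.append(x.reshape(len(ch_idx), n_epochs, fs).mean(axis=2))
        # feature order: channel-major, band-minor
        feats = np.stack(per_band, axis=2).transpose(1, 0, 2).reshape(n_epochs, -1)
        blocks.append(feats)
        for e in range(n_epochs):
            rows_ann.append(
                (norm.participant_id, int(seg.trial_index), int(seg.block_index), e)
            )

    cols = feature_columns(montage)
    if not blocks:
        empty = pd.DataFrame(columns=list(ANNOTATION_COLUMNS) + cols)
        return empty
    ann = pd.DataFrame(
        rows_ann, columns=["participant_id", "trial_index", "block_index", "epoch_index"]
    )
    ann["class_label"] = UNLABELED
    feat = pd.DataFrame(np.vstack(blocks).astype(np.float64), columns=cols)
    return pd.concat([ann, feat], axis=1)


def time_performance(trial_time: float, ideal_time: float) -> float:
    """Percent difference from the ideal completion time."""
    if ideal_time <= 0:
        raise ValueError("ideal_time must be positive")
    return 100.0 * (trial_time - ideal_time) / ideal_time


def behavior_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Augment a per-trial behavior frame with time performance and
    completion order."""
    out = behavior.copy()
    if (out["ideal_time_s"] <= 0).any():
        raise ValueError("ideal_time_s must be positive")
    out["time_performance_pct"] = (
        100.0 * (out["trial_time_s"] - out["ideal_time_s"]) / out["ideal_time_s"]
    )
    out["completion_order"] = np.arange(1, len(out) + 1)
    return out


def rank_trials(behavior: pd.DataFrame) -> np.ndarray:
    """Trial indices ordered by ascending certainty, ties by completion order."""
    if behavior["certainty_rating"].isna().any():
        bad = behavior.loc[behavior["certainty_rating"].isna(), "trial_index"].tolist()
        raise ValueError(f"missing certainty rating for trial(s) {bad}")
    order = (
        behavior.sort_values("trial_index", kind="stable")
        .sort_values("certainty_rating", kind="stable")
    )
    return order["trial_index"].to_numpy()


def assign_classes(ranked: np.ndarray, n_trials: int, extreme_fraction: float = 0.10) -> dict[int, int]:
    """Map trial index -> class label (0 low / 1 high / UNLABELED).

    The lowest-certainty ``floor(extreme_fraction * n_trials)`` trials
    (minimum 2) form class 0, the highest the same number as class 1.
    """
    if len(ranked) != n_trials:
        raise ValueError("ranking length does not match n_trials")
    n_label = max(2, math.floor(extreme_fraction * n_trials))
    if 2 * n_label > n_trials:
        raise ValueError(
            f"cannot label {n_label} trials per class out of {n_trials}"
        )
    labels = {int(t): UNLABELED for t in ranked}
    for t in ranked[:n_label]:
        labels[int(t)] = 0
    for t in ranked[-n_label:]:
        labels[int(t)] = 1
    return labels


def label_feature_table(
    table: pd.DataFrame, behavior: pd.DataFrame, extreme_fraction: float = 0.10
) -> pd.DataFrame:
    """Fill ``class_label`` for one participant's epochs from its behavior."""
    ranked = rank_trials(behavior_table(behavior))
    labels = assign_classes(ranked, len(ranked), extreme_fraction)
    out = table.copy()
    out["class_label"] = out["trial_index"].map(labels).fillna(UNLABELED).astype(int)
    return out


def build_feature_table(
    norm: NormalizedPower, montage: MontageSubset, extreme_fraction: float = 0.10
) -> pd.DataFrame:
    """Epoch features plus class labels for one participant."""
    table = epoch_features(norm, montage)
    if table.empty:
        return table
    return label_feature_table(table, norm.behavior, extreme_fraction)
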