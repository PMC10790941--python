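"""Shared fixtures: all EEG fixtures are generated at test time from the
synthetic cohort module (nothing is stored on disk)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nitrack.config import preset
from nitrack.montage import default_montage
from nitrack.pipeline import build_cohort_features
from nitrack.preprocessing import preprocess_recording
from nitrack.synthetic import generate_cohort, tiny_spec


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 participants x 12 trials, 2 responders, planted alpha effect."""
    return generate_cohort(tiny_spec(seed=7))


@pytest.fixture(scope="session")
def tiny_norm(tiny_cohort, montage):
    """Preprocessed power for the first responder of the tiny cohort."""
    rec = next(r for r in tiny_cohort if r.is_responder)
    return preprocess_recording(rec, keep_channels=montage.channel_labels)


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale all-responder cohort configuration."""
    return preset("desk", seed=42, responder_fraction=1.0)


@pytest.fixture(scope="session")
def desk_table(desk_config, montage):
    """Labeled epoch-feature table for the desk all-responder cohort."""
    table, responders, behaviors = build_cohort_features(desk_config, montage)
    return table


@pytest.fixture(scope="session")
def zero_config():
    """Desk cohort with no planted alpha effect (null condition)."""
    return preset("desk", seed=11, alpha_effect_size=1.0)


@pytest.fixture(scope="session")
def zero_table(zero_config, montage):
    table, _, _ = build_cohort_features(zero_config, montage)
    return table


def make_feature_frame(
    rng: np.random.Generator,
    n_participants: int = 4,
    epochs_per_class: int = 30,
    n_features: int = 12,
    effect: float = 2.0,
    n_blocks: int = 4,
) -> pd.DataFrame:
    """Small synthetic epoch table (no EEG) with one informative feature
    (feature f0 shifts by ``effect`` for class 1)."""
    rows = []
    for p in range(n_participants):
        pid = f"S{p + 1:02d}"
        for cls in (0, 1):
            block = 1 if cls == 0 else n_blocks
            for e in range(epochs_per_class):
                feats = rng.standard_normal(n_features)
                feats[0] += effect * cls
                rows.append(
                    dict(
                        participant_id=pid,
                        trial_index=cls * 100 + e // 8 + 1,
                        block_index=block,
                        epoch_index=e,
                        class_label=cls,
                        **{f"f{i}": feats[i] for i in range(n_features)},
                    )
                )
    return pd.DataFrame(rows)
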