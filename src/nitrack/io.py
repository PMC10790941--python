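"""Cohort, power-series and results file formats.

A cohort on disk is one EDF per participant plus two CSVs: ``sessions.csv``
(segment table with behavior merged onto navigation rows) and
``participants.csv`` (id, synthetic ground truth).  Normalized power is an
``.npz`` array container per participant with a JSON sidecar carrying the
band scheme, channel labels, rate and segment table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import read_edf, write_edf
from .preprocessing import BAND_NAMES, BandScheme, NormalizedPower
from .synthetic import SessionRecording

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_power",
    "read_power",
    "write_feature_table",
    "read_feature_table",
]

SESSIONS_COLUMNS = [
    "participant_id",
    "segment_kind",
    "trial_index",
    "block_index",
    "start_sample",
    "end_sample",
    "certainty_rating",
    "trial_time_s",
    "ideal_time_s",
]


def _sessions_frame(rec: SessionRecording) -> pd.DataFrame:
    seg = rec.segments.copy()
    seg.insert(0, "participant_id", rec.participant_id)
    beh = rec.behavior[["trial_index", "certainty_rating", "trial_time_s", "ideal_time_s"]]
    out = seg.merge(beh, on="trial_index", how="left")
    return out[SESSIONS_COLUMNS]


def write_cohort(directory: str | Path, cohort: list[SessionRecording]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sessions = []
    participants = []
    for rec in cohort:
        write_edf(
            directory / f"{rec.participant_id}.edf",
            rec.signal,
            list(rec.channel_labels),
            rec.sampling_rate,
            patient_id=rec.participant_id,
        )
        sessions.append(_sessions_frame(rec))
        participants.append(
            dict(
                participant_id=rec.participant_id,
                is_responder=rec.is_responder,
                true_iaf=rec.true_iaf if rec.true_iaf is not None else "",
            )
        )
    pd.concat(sessions, ignore_index=True).to_csv(directory / "sessions.csv", index=False)
    pd.DataFrame(participants).to_csv(directory / "participants.csv", index=False)


def read_cohort(directory: str | Path) -> list[SessionRecording]:
    directory = Path(directory)
    sessions = pd.read_csv(
        directory / "sessions.csv",
        dtype={"trial_index": "Int64", "block_index": "Int64"},
    )
    participants = pd.read_csv(directory / "participants.csv")
    cohort = []
    for row in participants.itertuples():
        pid = row.participant_id
        data, labels, fs = read_edf(directory / f"{pid}.edf")
        mine = sessions[sessions["participant_id"] == pid]
        segments = mine[
            ["segment_kind", "trial_index", "block_index", "start_sample", "end_sample"]
        ].reset_index(drop=True)
        nav = mine[mine["segment_kind"] == "navigation"]
        behavior = pd.DataFrame(
            dict(
                trial_index=nav["trial_index"].astype(int).to_numpy(),
                block_index=nav["block_index"].astype(int).to_numpy(),
                certainty_rating=nav["certainty_rating"].astype(int).to_numpy(),
                trial_time_s=nav["trial_time_s"].to_numpy(),
                ideal_time_s=nav["ideal_time_s"].to_numpy(),
            )
        )
        true_iaf = getattr(row, "true_iaf", None)
        cohort.append(
            SessionRecording(
                participant_id=pid,
                is_responder=bool(row.is_responder),
                sampling_rate=fs,
                channel_labels=tuple(labels),
                signal=data.astype(np.float32),
                segments=segments,
                behavior=behavior,
                true_iaf=float(true_iaf) if true_iaf not in (None, "") else None,
            )
        )
    return cohort


def write_power(directory: str | Path, norm: NormalizedPower) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / norm.participant_id
    np.savez_compressed(
        base.with_suffix(".npz"), **{b: norm.power[b] for b in BAND_NAMES}
    )
    sidecar = dict(
        participant_id=norm.participant_id,
        channel_labels=list(norm.channel_labels),
        sampling_rate=norm.sampling_rate,
        iaf=norm.band_scheme.iaf,
        bands={k: list(v) for k, v in norm.band_scheme.bands.items()},
        is_responder=norm.is_responder,
        segments=norm.segments.astype(object).where(norm.segments.notna(), None).to_dict("list"),
        behavior=norm.behavior.to_dict("list"),
    )
    base.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def read_power(directory: str | Path, participant_id: str) -> NormalizedPower:
    directory = Path(directory)
    base = directory / participant_id
    arrays = np.load(base.with_suffix(".npz"))
    meta = json.loads(base.with_suffix(".json").read_text(encoding="utf-8"))
    segments = pd.DataFrame(meta["segments"])
    segments["trial_index"] = segments["trial_index"].astype("Int64")
    segments["block_index"] = segments["block_index"].astype("Int64")
    return NormalizedPower(
        participant_id=meta["participant_id"],
        channel_labels=tuple(meta["channel_labels"]),
        sampling_rate=float(meta["sampling_rate"]),
        band_scheme=BandScheme(
            iaf=float(meta["iaf"]),
            bands={k: tuple(v) for k, v in meta["bands"].items()},
        ),
        power={b: arrays[b] for b in BAND_NAMES},
        segments=segments,
        behavior=pd.DataFrame(meta["behavior"]),
        is_responder=meta.get("is_responder"),
    )


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
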