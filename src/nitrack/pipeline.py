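"""End-to-end orchestration: simulate -> preprocess -> features ->
classify -> stats.

Two entry points: :func:`run_study` keeps everything in memory (what the
test suite and reproduction script use), and :func:`run_all` runs the same
stages against an artifact directory with per-stage completion markers so
interrupted runs resume.  Every output directory carries a ``manifest.json``
naming the config hash and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .classification import RunResult, lopo_run, permutation_test
from .config import PipelineConfig
from .features import build_feature_table
from .indicator import (
    NITrace,
    TrendResult,
    classify_effectiveness,
    compute_ni,
    feature_histogram,
    ni_correlations,
    trend_regression,
)
from .montage import MontageSubset, load_montage
from .preprocessing import preprocess_recording
from .synthetic import generate_cohort

__all__ = ["StudyResult", "run_study", "run_all"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "classify", "stats")


@dataclass
class StudyResult:
    config: PipelineConfig
    montage: MontageSubset
    feature_table: pd.DataFrame
    runs: dict[str, list[RunResult]]
    traces: dict[str, NITrace]
    block_table: pd.DataFrame
    trend: TrendResult | None
    correlations: pd.DataFrame
    histogram: pd.DataFrame
    histogram_marginals: pd.DataFrame
    permutations: dict[str, dict] = field(default_factory=dict)
    responders: dict[str, bool] = field(default_factory=dict)
    behaviors: dict[str, pd.DataFrame] = field(default_factory=dict)


def _montage_for(config: PipelineConfig) -> MontageSubset:
    return load_montage(config.montage_path or None)


def build_cohort_features(
    config: PipelineConfig, montage: MontageSubset | None = None
) -> tuple[pd.DataFrame, dict[str, bool], dict[str, pd.DataFrame]]:
    """Simulate + preprocess + feature-extract, one participant at a time
    (raw signals are dropped as soon as their features exist)."""
    montage = montage or _montage_for(config)
    iaf_channels = tuple(config.iaf_channels.split(","))
    spec = config.cohort_spec()
    tables, responders, behaviors = [], {}, {}
    for rec in generate_cohort(spec):
        norm = preprocess_recording(
            rec,
            iaf_channels=iaf_channels,
            keep_channels=montage.channel_labels,
        )
        tables.append(build_feature_table(norm, montage, config.extreme_fraction))
        responders[rec.participant_id] = rec.is_responder
        behaviors[rec.participant_id] = norm.behavior
    return pd.concat(tables, ignore_index=True), responders, behaviors


def analyze_cohort(
    table: pd.DataFrame,
    config: PipelineConfig,
    montage: MontageSubset,
    *,
    participants: list[str] | None = None,
    with_permutation: bool = False,
) -> tuple[dict, dict, pd.DataFrame, dict]:
    """LOPO classification + NI traces (+ optional permutation test)."""
    all_pids = sorted(table["participant_id"].unique())
    pids = participants or all_pids
    runs: dict[str, list[RunResult]] = {}
    traces: dict[str, NITrace] = {}
    perms: dict[str, dict] = {}
    for pid in pids:
        t0 = time.perf_counter()
        rr = lopo_run(
            table, pid,
            n_runs=config.n_runs, k=config.k_features, seed=config.seed,
            C=config.svm_c, n_bins=config.mrmr_bins,
        )
        runs[pid] = rr
        test = table[table["participant_id"] == pid]
        traces[pid] = compute_ni(
            rr,
            test["trial_index"].to_numpy(),
            test["block_index"].to_numpy(),
            participant_id=pid,
        )
        if with_permutation and config.n_perm > 0:
            true_acc = float(np.mean([r.block_extremes_accuracy for r in rr]))
            pr = permutation_test(
                table, pid, true_acc,
                n_perm=config.n_perm, seed=config.seed,
                k=config.k_features, C=config.svm_c, n_bins=config.mrmr_bins,
                runs_per_perm=config.runs_per_perm,
            )
            perms[pid] = dict(
                true_accuracy=pr.true_accuracy,
                p_value=pr.p_value,
                null_mean=float(pr.null_accuracies.mean()),
                null_sd=float(pr.null_accuracies.std(ddof=1)) if config.n_perm > 1 else 0.0,
                n_perm=config.n_perm,
                group=classify_effectiveness(
                    pr.p_value, config.n_perm, config.effectiveness_alpha
                ),
            )
            traces[pid].group = perms[pid]["group"]
        log.info("participant %s analyzed in %.1f s", pid, time.perf_counter() - t0)
    block_rows = []
    for pid, tr in traces.items():
        for row in tr.per_block.itertuples():
            block_rows.append(dict(participant_id=pid, block_index=row.block_index, ni=row.ni))
    return runs, traces, pd.DataFrame(block_rows), perms


def run_study(config: PipelineConfig, *, with_permutation: bool = False) -> StudyResult:
    """Full in-memory pipeline on a synthetic cohort."""
    montage = _montage_for(config)
    table, responders, behaviors = build_cohort_features(config, montage)
    runs, traces, block_table, perms = analyze_cohort(
        table, config, montage, with_permutation=with_permutation
    )
    trend = None
    if block_table["block_index"].nunique() >= 3 and len(traces) >= 2:
        trend = trend_regression(block_table)
    corr_rows = []
    for pid, tr in traces.items():
        cr = ni_correlations(tr, behaviors[pid], config.corr_extreme_fraction)
        corr_rows.append(vars(cr))
    all_runs = [r for rr in runs.values() for r in rr]
    hist, marg = feature_histogram(all_runs, montage)
    return StudyResult(
        config=config,
        montage=montage,
        feature_table=table,
        runs=runs,
        traces=traces,
        block_table=block_table,
        trend=trend,
        correlations=pd.DataFrame(corr_rows),
        histogram=hist,
        histogram_marginals=marg,
        permutations=perms,
        responders=responders,
        behaviors=behaviors,
    )


# ---------------------------------------------------------------------------
# file-based orchestration


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / stage / ".done"
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark_done(out: Path, stage: str, cfg_hash: str) -> None:
    (out / stage / ".done").write_text(cfg_hash)


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> Path:
    """Run (or resume) the file-based pipeline into ``out_dir``."""
    config.cohort_spec().validate()  # reject invalid designs before any compute
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    config.to_yaml(out / "config.yaml")
    manifest = dict(config_hash=cfg_hash, seed=config.seed, stages={})
    montage = _montage_for(config)
    iaf_channels = tuple(config.iaf_channels.split(","))

    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if not force and _stage_done(out, stage, cfg_hash):
            log.info("stage %s up to date, skipping", stage)
            manifest["stages"][stage] = "cached"
            continue
        t0 = time.perf_counter()
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        try:
            if stage == "simulate":
                nio.write_cohort(sdir, generate_cohort(config.cohort_spec()))
            elif stage == "preprocess":
                for rec in nio.read_cohort(out / "simulate"):
                    norm = preprocess_recording(
                        rec, iaf_channels=iaf_channels,
                        keep_channels=montage.channel_labels,
                    )
                    nio.write_power(sdir, norm)
            elif stage == "features":
                participants = pd.read_csv(out / "simulate" / "participants.csv")
                tables = []
                for pid in participants["participant_id"]:
                    norm = nio.read_power(out / "preprocess", pid)
                    tables.append(build_feature_table(norm, montage, config.extreme_fraction))
                nio.write_feature_table(
                    sdir / "features.csv", pd.concat(tables, ignore_index=True)
                )
            elif stage == "classify":
                table = nio.read_feature_table(out / "features" / "features.csv")
                runs, traces, block_table, perms = analyze_cohort(
                    table, config, montage, with_permutation=config.n_perm > 0
                )
                _write_classify(sdir, runs, perms)
                pred_rows = []
                for pid, rr in runs.items():
                    test = table[table["participant_id"] == pid]
                    mean_pred = np.vstack([r.predictions for r in rr]).mean(axis=0)
                    pred_rows.append(pd.DataFrame(dict(
                        participant_id=pid,
                        trial_index=test["trial_index"].to_numpy(),
                        epoch_index=test["epoch_index"].to_numpy(),
                        mean_predicted_class=mean_pred,
                    )))
                pd.concat(pred_rows, ignore_index=True).to_csv(
                    sdir / "predictions.csv", index=False
                )
                block_table.to_csv(sdir / "ni_per_block.csv", index=False)
                pd.concat(
                    [tr.per_trial.assign(participant_id=pid) for pid, tr in traces.items()],
                    ignore_index=True,
                ).to_csv(sdir / "ni_per_trial.csv", index=False)
            elif stage == "stats":
                _run_stats(out, sdir, config, montage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _mark_done(out, stage, cfg_hash)
        manifest["stages"][stage] = f"{time.perf_counter() - t0:.1f}s"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return out


def _write_classify(sdir: Path, runs: dict[str, list[RunResult]], perms: dict) -> None:
    rows = []
    for pid, rr in runs.items():
        for r in rr:
            rows.append(
                dict(
                    participant_id=pid,
                    run=r.run_index,
                    block_extremes_accuracy=r.block_extremes_accuracy,
                    selected_features=";".join(r.selected_features),
                )
            )
    pd.DataFrame(rows).to_csv(sdir / "runs.csv", index=False)
    if perms:
        (sdir / "permutation.json").write_text(json.dumps(perms, indent=2), encoding="utf-8")


def _run_stats(out: Path, sdir: Path, config: PipelineConfig, montage: MontageSubset) -> None:
    table = nio.read_feature_table(out / "features" / "features.csv")
    block_table = pd.read_csv(out / "classify" / "ni_per_block.csv")
    runs_df = pd.read_csv(out / "classify" / "runs.csv")

    if block_table["block_index"].nunique() >= 3 and block_table["participant_id"].nunique() >= 2:
        trend = trend_regression(block_table)
        (sdir / "trend.json").write_text(
            json.dumps(
                dict(
                    slope_per_block=trend.slope_per_block,
                    t_statistic=trend.t_statistic,
                    degrees_of_freedom=trend.degrees_of_freedom,
                    p_value=trend.p_value,
                    fallback_ols=trend.fallback_ols,
                ),
                indent=2,
            ),
            encoding="utf-8",
        )

    counts: dict[str, int] = {}
    for sel in runs_df["selected_features"]:
        for f in str(sel).split(";"):
            counts[f] = counts.get(f, 0) + 1
    hist_rows = []
    for feat, c in sorted(counts.items()):
        ch, band = feat.split("_", 1)
        hist_rows.append(
            dict(feature=feat, channel=ch, band=band,
                 region=montage.region_of.get(ch, "unknown"), count=c)
        )
    pd.DataFrame(hist_rows).to_csv(sdir / "feature_histogram.csv", index=False)

    # per-participant NI-vs-behavior correlations from the stored trial NIs
    ni_trial = pd.read_csv(out / "classify" / "ni_per_trial.csv")
    sessions = pd.read_csv(out / "simulate" / "sessions.csv")
    nav = sessions[sessions["segment_kind"] == "navigation"]
    corr_rows = []
    for pid, tr_df in ni_trial.groupby("participant_id"):
        beh = nav[nav["participant_id"] == pid][
            ["trial_index", "certainty_rating", "trial_time_s", "ideal_time_s"]
        ].astype({"trial_index": int})
        trace = NITrace(pid, tr_df.reset_index(drop=True), pd.DataFrame())
        corr_rows.append(vars(ni_correlations(trace, beh, config.corr_extreme_fraction)))
    pd.DataFrame(corr_rows).to_csv(sdir / "correlations.csv", index=False)
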