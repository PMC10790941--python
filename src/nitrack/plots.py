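"""Optional matplotlib views of the neural-indicator results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import pandas as pd

from .indicator import NITrace

__all__ = ["plot_ni_per_trial", "plot_block_ni", "plot_feature_histogram"]


def plot_ni_per_trial(trace: NITrace, ax=None):
    """Per-trial NI with its across-runs 95% confidence band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    df = trace.per_trial
    ax.plot(df["trial_index"], df["ni"], color="tab:blue", lw=1.2)
    ax.fill_between(
        df["trial_index"], df["ni_ci_low"], df["ni_ci_high"],
        color="tab:blue", alpha=0.25, linewidth=0,
    )
    ax.set(
        xlabel="trial", ylabel="NI", ylim=(-0.02, 1.02),
        title=f"{trace.participant_id} ({trace.group})",
    )
    return ax


def plot_block_ni(block_table: pd.DataFrame, groups: dict[str, str] | None = None, ax=None):
    """Mean NI per block, one line per group (plus the overall mean)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    df = block_table.copy()
    df["group"] = df["participant_id"].map(groups or {}).fillna("all")
    for name, sub in df.groupby("group"):
        mean = sub.groupby("block_index")["ni"].mean()
        ax.plot(mean.index, mean.values, marker="o", label=name)
    overall = df.groupby("block_index")["ni"].mean()
    ax.plot(overall.index, overall.values, color="k", ls="--", label="combined")
    ax.set(xlabel="block", ylabel="mean NI", ylim=(-0.02, 1.02))
    ax.legend(fontsize=8)
    return ax


def plot_feature_histogram(per_feature: pd.DataFrame, band: str = "alpha_high"):
    """Selection counts for one band, one panel per region."""
    sub = per_feature[per_feature["band"] == band]
    regions = sorted(sub["region"].unique()) or ["frontal"]
    fig, axes = plt.subplots(1, len(regions), figsize=(3 * len(regions), 3), squeeze=False)
    for ax, region in zip(axes[0], regions):
        rows = sub[sub["region"] == region].sort_values("count", ascending=False)
        ax.bar(rows["channel"], rows["count"], color="tab:purple")
        ax.set(title=region, ylabel="selections")
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.suptitle(f"{band} feature selections")
    fig.tight_layout()
    return fig
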