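"""Neural indicator (NI) and session-level statistics.

The NI of trial *t* is the mean predicted class over the trial's 1 s
epochs, with each epoch's prediction first averaged over classification
runs; because the test set is fixed across runs this equals the mean over
runs of the per-run trial NI.  NI ranges from 0 ("low proficiency") to 1
("high proficiency").

Block NIs are unweighted means of trial NIs.  The session trend is a
repeated-measures linear mixed model (fixed block slope, random intercept
per participant); per-participant Pearson correlations relate the NI to
certainty ratings and to time performance, over all trials and over the
extreme (first and last 20%) trials.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classification import RunResult
from .montage import MontageSubset

__all__ = [
    "NITrace",
    "TrendResult",
    "CorrelationResult",
    "compute_ni",
    "block_ni",
    "trend_regression",
    "ni_correlations",
    "feature_histogram",
    "classify_effectiveness",
]

log = logging.getLogger(__name__)


@dataclass
class NITrace:
    """Per-trial and per-block NI values for one participant."""

    participant_id: str
    per_trial: pd.DataFrame  # trial_index, block_index, n_epochs, ni, ni_ci_low/high
    per_block: pd.DataFrame  # block_index, ni
    group: str = "unassigned"


@dataclass
class TrendResult:
    slope_per_block: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    fallback_ols: bool = False


def compute_ni(
    runs: list[RunResult],
    trial_index: np.ndarray,
    block_index: np.ndarray,
    participant_id: str = "",
    ci: float = 0.95,
) -> NITrace:
    """Per-trial NI from per-epoch predictions of one or more runs.

    ``trial_index``/``block_index`` annotate the (fixed) test epochs in the
    same order as each run's prediction vector.  The confidence band is the
    normal-approximation interval of the per-run trial NIs.
    """
    preds = np.vstack([r.predictions for r in runs])  # runs x epochs
    trial_index = np.asarray(trial_index)
    block_index = np.asarray(block_index)
    if preds.shape[1] != len(trial_index):
        raise ValueError("predictions do not cover every test epoch")

    rows = []
    for t in np.unique(trial_index):
        mask = trial_index == t
        n_t = int(mask.sum())
        if n_t == 0:
            continue
        per_run_ni = preds[:, mask].mean(axis=1)
        ni = float(per_run_ni.mean())
        if len(runs) > 1:
            se = float(per_run_ni.std(ddof=1)) / np.sqrt(len(runs))
            zq = sstats.norm.ppf(0.5 + ci / 2)
            lo, hi = max(0.0, ni - zq * se), min(1.0, ni + zq * se)
        else:
            lo = hi = ni
        rows.append(
            dict(
                trial_index=int(t),
                block_index=int(block_index[mask][0]),
                n_epochs=n_t,
                ni=ni,
                ni_ci_low=lo,
                ni_ci_high=hi,
            )
        )
    per_trial = pd.DataFrame(rows).sort_values("trial_index", ignore_index=True)
    return NITrace(
        participant_id=participant_id,
        per_trial=per_trial,
        per_block=block_ni(per_trial),
    )


def block_ni(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of trial NIs within each block."""
    out = (
        per_trial.groupby("block_index", as_index=False)["ni"].mean()
        .sort_values("block_index", ignore_index=True)
    )
    return out


def trend_regression(block_table: pd.DataFrame) -> TrendResult:
    """Mixed-model trend of NI on block number.

    ``block_table`` needs columns participant_id, block_index, ni.  Fits
    NI ~ 1 + block with a random intercept per participant; the p-value
    uses the normal approximation to the slope's t statistic, with the
    conventional df = n_obs - n_participants - 1 reported alongside.
    Falls back to OLS with cluster-robust errors if the fit is singular.
    """
    import statsmodels.formula.api as smf

    df = block_table.rename(columns={"block_index": "block"})
    n_obs = len(df)
    n_groups = df["participant_id"].nunique()
    if n_groups < 2 or df["block"].nunique() < 3:
        raise ValueError("need >= 2 participants and >= 3 blocks")
    dof = n_obs - n_groups - 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("ni ~ block", df, groups=df["participant_id"])
            fit = model.fit(reml=True, method="lbfgs")
        slope = float(fit.params["block"])
        tval = float(fit.tvalues["block"])
        if not np.isfinite(tval):
            raise np.linalg.LinAlgError("non-finite slope statistic")
        p = 2 * sstats.norm.sf(abs(tval))
        return TrendResult(slope, tval, dof, float(p))
    except (np.linalg.LinAlgError, ValueError):
        ols = smf.ols("ni ~ block", df).fit(
            cov_type="cluster", cov_kwds={"groups": df["participant_id"]}
        )
        slope = float(ols.params["block"])
        tval = float(ols.tvalues["block"])
        p = 2 * sstats.norm.sf(abs(tval))
        return TrendResult(slope, tval, dof, float(p), fallback_ols=True)


@dataclass
class CorrelationResult:
    participant_id: str
    r_certainty_all: float
    p_certainty_all: float
    r_certainty_extremes: float
    p_certainty_extremes: float
    r_time_all: float
    p_time_all: float
    r_time_extremes: float
    p_time_extremes: float


def _pearson(x, y) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def ni_correlations(
    trace: NITrace, behavior: pd.DataFrame, extreme_fraction: float = 0.20
) -> CorrelationResult:
    """Pearson correlations of trial NI with certainty and time performance,
    over all trials and over the first/last ``extreme_fraction`` of trials
    (in completion order)."""
    merged = trace.per_trial.merge(behavior, on="trial_index", suffixes=("", "_b"))
    merged = merged.sort_values("trial_index")
    n = len(merged)
    n_ext = int(np.floor(extreme_fraction * n))
    ext = pd.concat([merged.iloc[:n_ext], merged.iloc[n - n_ext:]])
    tp = 100.0 * (merged["trial_time_s"] - merged["ideal_time_s"]) / merged["ideal_time_s"]
    tp_ext = 100.0 * (ext["trial_time_s"] - ext["ideal_time_s"]) / ext["ideal_time_s"]

    r_ca, p_ca = _pearson(merged["ni"], merged["certainty_rating"])
    r_ce, p_ce = _pearson(ext["ni"], ext["certainty_rating"])
    r_ta, p_ta = _pearson(merged["ni"], tp)
    r_te, p_te = _pearson(ext["ni"], tp_ext)
    return CorrelationResult(
        trace.participant_id, r_ca, p_ca, r_ce, p_ce, r_ta, p_ta, r_te, p_te
    )


def feature_histogram(
    runs: list[RunResult], montage: MontageSubset
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Selection counts per feature over all runs, plus region x band
    marginals.  Total count equals k x n_runs."""
    counts: Counter = Counter()
    for r in runs:
        counts.update(r.selected_features)
    rows = []
    for feat, c in sorted(counts.items()):
        ch, band = feat.split("_", 1)
        rows.append(
            dict(
                feature=feat,
                channel=ch,
                band=band,
                region=montage.region_of.get(ch, "unknown"),
                count=c,
            )
        )
    per_feature = pd.DataFrame(rows, columns=["feature", "channel", "band", "region", "count"])
    if per_feature.empty:
        marginals = pd.DataFrame(columns=["region", "band", "count"])
    else:
        marginals = (
            per_feature.groupby(["region", "band"], as_index=False)["count"].sum()
        )
    return per_feature, marginals


def classify_effectiveness(p_value: float, n_perm: int, alpha: float = 0.001) -> str:
    """'effective' when the permutation p-value clears the significance
    threshold; the threshold floor is 1/n_perm at small permutation counts."""
    threshold = max(alpha, 1.0 / n_perm)
    return "effective" if p_value < threshold else "ineffective"
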