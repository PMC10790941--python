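"""Subject-independent proficiency-state classification.

For each held-out ("test") participant, every run: (1) re-balances each
training participant's labeled epochs by subsampling the larger class,
(2) runs mRMR on the pooled balanced epochs to pick a 10-feature set,
(3) fits a standardized linear SVM, and (4) predicts the class of *every*
navigation epoch of the test participant.  The test data are identical
across runs; only the training subsample changes.  No test-participant
epoch ever enters feature selection or training.

Significance of a participant's block-extremes accuracy comes from a
permutation null: training labels are shuffled within each training
participant (label counts preserved) and the identical
balance -> mRMR -> SVM procedure is re-run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import ANNOTATION_COLUMNS, UNLABELED
from .mrmr import mrmr_select

__all__ = [
    "RunResult",
    "PermutationResult",
    "balance_within_participant",
    "train_linear_svm",
    "lopo_run",
    "block_extremes_accuracy",
    "permutation_test",
]


@dataclass
class RunResult:
    """One classification run for one held-out participant."""

    run_index: int
    selected_features: list[str]
    predictions: np.ndarray  # class per test epoch, aligned with the test table
    block_extremes_accuracy: float
    model: object | None = None  # fitted scaler+SVM pipeline (selected features only)


@dataclass
class PermutationResult:
    true_accuracy: float
    null_accuracies: np.ndarray
    p_value: float


def balance_within_participant(rows: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Subsample the larger class (without replacement) to the smaller
    class's epoch count; the smaller class is untouched."""
    by_class = {c: df for c, df in rows.groupby("class_label")}
    if 0 not in by_class or 1 not in by_class or len(by_class) != 2:
        present = sorted(by_class)
        raise ValueError(f"need both classes to balance, got {present}")
    n = min(len(by_class[0]), len(by_class[1]))
    if n == 0:
        raise ValueError("a class has zero epochs")
    parts = []
    for c in (0, 1):
        df = by_class[c]
        if len(df) > n:
            keep = rng.choice(len(df), size=n, replace=False)
            df = df.iloc[np.sort(keep)]
        parts.append(df)
    return pd.concat(parts, axis=0)


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> Pipeline:
    """Linear SVM on training-standardized features."""
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit an SVM on a single class")
    model = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=C))]
    )
    model.fit(X, y)
    return model


def block_extremes_accuracy(
    predictions: np.ndarray,
    block_index: np.ndarray,
    first_block: int = 1,
    last_block: int | None = None,
) -> float:
    """Accuracy over the first and last blocks' epochs, scoring first-block
    epochs correct when predicted 0 and last-block epochs correct when
    predicted 1."""
    predictions = np.asarray(predictions)
    block_index = np.asarray(block_index)
    if last_block is None:
        last_block = int(block_index.max())
    first_mask = block_index == first_block
    last_mask = block_index == last_block
    total = first_mask.sum() + last_mask.sum()
    if total == 0:
        raise ValueError("no epochs in the extreme blocks")
    correct = (predictions[first_mask] == 0).sum() + (predictions[last_mask] == 1).sum()
    return float(correct) / float(total)


# ---------------------------------------------------------------------------
# internal: cohort table pre-arranged as numpy arrays for fast repeated runs


class _CohortArrays:
    def __init__(self, table: pd.DataFrame, test_participant: str, feature_cols: list[str]):
        self.feature_cols = feature_cols
        test = table[table["participant_id"] == test_participant]
        if test.empty:
            raise ValueError(f"unknown test participant {test_participant!r}")
        self.X_test = test[feature_cols].to_numpy(float)
        self.test_blocks = test["block_index"].to_numpy(int)
        self.test_trials = test["trial_index"].to_numpy(int)
        self.test_epoch_idx = test["epoch_index"].to_numpy(int)

        self.train_parts: list[tuple[np.ndarray, np.ndarray]] = []  # (X, y) labeled
        for pid, df in table[table["participant_id"] != test_participant].groupby(
            "participant_id", sort=True
        ):
            lab = df[df["class_label"] != UNLABELED]
            y = lab["class_label"].to_numpy(int)
            if (y == 0).sum() == 0 or (y == 1).sum() == 0:
                raise ValueError(f"training participant {pid} lacks a class")
            self.train_parts.append((lab[feature_cols].to_numpy(float), y))


def _balanced_pool(
    parts: list[tuple[np.ndarray, np.ndarray]], rng: np.random.Generator,
    label_shuffle: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for X, y in parts:
        if label_shuffle:
            y = rng.permutation(y)
        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        n = min(len(idx0), len(idx1))
        keep0 = np.sort(rng.choice(idx0, size=n, replace=False)) if len(idx0) > n else idx0
        keep1 = np.sort(rng.choice(idx1, size=n, replace=False)) if len(idx1) > n else idx1
        keep = np.concatenate([keep0, keep1])
        xs.append(X[keep])
        ys.append(y[keep])
    return np.vstack(xs), np.concatenate(ys)


def _single_run(
    arrays: _CohortArrays,
    rng: np.random.Generator,
    k: int,
    C: float,
    n_bins: int,
    label_shuffle: bool = False,
) -> tuple[list[str], np.ndarray, float, object]:
    X_train, y_train = _balanced_pool(arrays.train_parts, rng, label_shuffle)
    frame = pd.DataFrame(X_train, columns=arrays.feature_cols)
    selected = mrmr_select(frame, y_train, k=k, n_bins=n_bins)
    sel_idx = [arrays.feature_cols.index(f) for f in selected]
    model = train_linear_svm(X_train[:, sel_idx], y_train, C=C)
    preds = model.predict(arrays.X_test[:, sel_idx]).astype(int)
    acc = block_extremes_accuracy(preds, arrays.test_blocks)
    return selected, preds, acc, model


def lopo_run(
    table: pd.DataFrame,
    test_participant: str,
    n_runs: int = 100,
    k: int = 10,
    seed: int = 0,
    *,
    C: float = 1.0,
    n_bins: int = 3,
) -> list[RunResult]:
    """Leave-one-participant-out evaluation: ``n_runs`` independent
    balance/select/train/predict runs against a fixed test set."""
    feature_cols = [c for c in table.columns if c not in ANNOTATION_COLUMNS]
    arrays = _CohortArrays(table, test_participant, feature_cols)
    results = []
    for run in range(1, n_runs + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_participant_key(test_participant), run))
        )
        selected, preds, acc, model = _single_run(arrays, rng, k, C, n_bins)
        results.append(RunResult(run, selected, preds, acc, model))
    return results


def _participant_key(pid: str) -> int:
    # stable small integer per participant id for seed spawning
    return int.from_bytes(pid.encode("utf-8")[-4:], "big") % (2**31)


def permutation_test(
    table: pd.DataFrame,
    test_participant: str,
    true_accuracy: float,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    k: int = 10,
    C: float = 1.0,
    n_bins: int = 3,
    runs_per_perm: int = 1,
) -> PermutationResult:
    """Permutation null for one participant's block-extremes accuracy.

    Each permutation shuffles class labels within every training
    participant, then repeats the identical classification procedure
    (``runs_per_perm`` runs, averaged).  p = proportion of null >= true.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    feature_cols = [c for c in table.columns if c not in ANNOTATION_COLUMNS]
    arrays = _CohortArrays(table, test_participant, feature_cols)
    null = np.empty(n_perm)
    pkey = _participant_key(test_participant)
    for i in range(n_perm):
        accs = []
        for r in range(runs_per_perm):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(pkey, 10_000 + i, r))
            )
            _, _, acc, _ = _single_run(arrays, rng, k, C, n_bins, label_shuffle=True)
            accs.append(acc)
        null[i] = float(np.mean(accs))
    p = float((null >= true_accuracy).sum()) / n_perm
    return PermutationResult(true_accuracy=true_accuracy, null_accuracies=null, p_value=p)
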