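import numpy as np
import pandas as pd
import pytest

from nitrack.classification import RunResult
from nitrack.indicator import (
    block_ni,
    classify_effectiveness,
    compute_ni,
    feature_histogram,
    ni_correlations,
    trend_regression,
)


def _runs(pred_lists) -> list[RunResult]:
    return [
        RunResult(i + 1, ["f0"], np.asarray(p), 0.0) for i, p in enumerate(pred_lists)
    ]


class TestComputeNI:
    def test_all_high(self):
        trace = compute_ni(_runs([[1, 1, 1, 1]]), np.ones(4, int), np.ones(4, int))
        assert trace.per_trial["ni"].iloc[0] == 1.0

    def test_half_high(self):
        trace = compute_ni(_runs([[0, 1, 1, 0]]), np.ones(4, int), np.ones(4, int))
        assert trace.per_trial["ni"].iloc[0] == 0.5

    def test_two_runs_average(self):
        trace = compute_ni(
            _runs([[0, 1, 1, 0], [1, 1, 1, 0]]), np.ones(4, int), np.ones(4, int)
        )
        assert trace.per_trial["ni"].iloc[0] == pytest.approx(0.625)

    def test_averaging_order_commutes(self):
        """Epoch-then-run averaging equals run-then-epoch averaging, and a
        single run's NI times the epoch count is an integer."""
        rng = np.random.default_rng(0)
        n_trials, epochs_per_trial, n_runs = 6, 5, 7
        trials = np.repeat(np.arange(1, n_trials + 1), epochs_per_trial)
        blocks = np.ones_like(trials)
        preds = [rng.integers(0, 2, size=len(trials)) for _ in range(n_runs)]
        trace = compute_ni(_runs(preds), trials, blocks)
        stacked = np.vstack(preds)
        for row in trace.per_trial.itertuples():
            mask = trials == row.trial_index
            per_run = stacked[:, mask].mean(axis=1)
            assert row.ni == pytest.approx(per_run.mean())
            assert 0.0 <= row.ni <= 1.0
        one_run = compute_ni(_runs(preds[:1]), trials, blocks)
        for row in one_run.per_trial.itertuples():
            assert (row.ni * row.n_epochs) == pytest.approx(round(row.ni * row.n_epochs))

    def test_block_means_consistent(self):
        rng = np.random.default_rng(1)
        trials = np.repeat(np.arange(1, 13), 4)
        blocks = np.repeat(np.repeat([1, 2], 6), 4)
        trace = compute_ni(_runs([rng.integers(0, 2, len(trials))]), trials, blocks)
        manual = trace.per_trial.groupby("block_index")["ni"].mean()
        for row in trace.per_block.itertuples():
            assert row.ni == pytest.approx(manual[row.block_index])


class TestBlockNI:
    def test_simple_mean(self):
        per_trial = pd.DataFrame(dict(block_index=[1] * 6, ni=[0, 0, 0, 1, 1, 1]))
        assert block_ni(per_trial)["ni"].iloc[0] == 0.5

    def test_constant(self):
        per_trial = pd.DataFrame(dict(block_index=[1, 1, 2, 2], ni=[0.3] * 4))
        assert (block_ni(per_trial)["ni"] == 0.3).all()


def _block_table(ni_fn, n_participants=6, n_blocks=10, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for b in range(1, n_blocks + 1):
            rows.append(dict(
                participant_id=f"S{p:02d}", block_index=b,
                ni=ni_fn(p, b) + (rng.normal(0, noise_sd) if noise_sd else 0.0),
            ))
    return pd.DataFrame(rows)


class TestTrendRegression:
    def test_exact_linear(self):
        res = trend_regression(_block_table(lambda p, b: 0.1 * b))
        assert res.slope_per_block == pytest.approx(0.1, abs=1e-6)
        assert res.p_value < 1e-6

    def test_constant_per_participant_null(self):
        res = trend_regression(_block_table(lambda p, b: 0.2 + 0.05 * p, noise_sd=0.02))
        assert abs(res.slope_per_block) < 0.02
        assert res.p_value > 0.05

    def test_degrees_of_freedom_convention(self):
        res = trend_regression(_block_table(lambda p, b: 0.1 * b, n_participants=15))
        assert res.degrees_of_freedom == 15 * 10 - 15 - 1

    def test_slope_recovery_with_noise(self):
        """Per-block increment 0.065 with trial noise: recovered within
        [0.05, 0.08] in at least 90% of 50 seeded replicates."""
        hits = 0
        for seed in range(50):
            tbl = _block_table(
                lambda p, b: 0.065 * b, noise_sd=0.05, seed=seed
            )
            res = trend_regression(tbl)
            hits += 0.05 <= res.slope_per_block <= 0.08
        assert hits >= 45

    def test_type_i_error_calibrated(self):
        """Null cohorts (no block effect) reject at alpha=0.05 at a rate
        inside [0.01, 0.12] over 200 replicates."""
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            tbl = _block_table(
                lambda p, b: 0.4, n_participants=5, n_blocks=6,
                noise_sd=0.08, seed=1000 + seed,
            )
            rejections += trend_regression(tbl).p_value < 0.05
        assert 0.01 * n_rep <= rejections <= 0.12 * n_rep

    def test_too_small_design_rejected(self):
        with pytest.raises(ValueError):
            trend_regression(_block_table(lambda p, b: 0.1 * b, n_participants=1))


class TestCorrelations:
    def _trace(self, ni_values):
        from nitrack.indicator import NITrace

        per_trial = pd.DataFrame(dict(
            trial_index=np.arange(1, len(ni_values) + 1),
            block_index=1, n_epochs=5, ni=ni_values,
        ))
        return NITrace("S01", per_trial, block_ni(per_trial))

    def _behavior(self, certainty, times=None):
        n = len(certainty)
        return pd.DataFrame(dict(
            trial_index=np.arange(1, n + 1),
            certainty_rating=certainty,
            trial_time_s=times if times is not None else np.linspace(100, 50, n),
            ideal_time_s=50.0,
        ))

    def test_affine_ni_gives_unit_correlation(self):
        certainty = np.clip(np.round(np.linspace(1, 10, 60)), 1, 10)
        trace = self._trace(0.05 + 0.09 * certainty)
        res = ni_correlations(trace, self._behavior(certainty))
        assert res.r_certainty_all == pytest.approx(1.0)

    def test_independent_noise_rarely_correlates(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = self._trace(rng.uniform(0, 1, 60))
            certainty = rng.integers(1, 11, 60)
            res = ni_correlations(trace, self._behavior(certainty))
            hits += abs(res.r_certainty_all) < 0.4
        assert hits >= 95

    def test_extremes_beat_all_trials_for_sigmoid_learner(self):
        """When the NI tracks a saturating learning curve with mid-session
        noise, the extreme-trials correlation exceeds the all-trials one on
        average (the study's observed pattern for effective participants)."""
        diffs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            t = np.arange(60)
            latent = 1 / (1 + np.exp(-(t - 30) / 4))
            certainty = np.clip(np.round(1 + 9 * latent + rng.normal(0, 1.2, 60)), 1, 10)
            ni = np.clip(latent + rng.normal(0, 0.25, 60), 0, 1)
            res = ni_correlations(self._trace(ni), self._behavior(certainty))
            diffs.append(res.r_certainty_extremes - res.r_certainty_all)
        assert np.mean(diffs) > 0

    def test_extremes_use_first_and_last_fifth(self):
        certainty = np.ones(60, int) * 5
        certainty[:12] = 1
        certainty[-12:] = 10
        ni = np.zeros(60)
        ni[-12:] = 1.0
        res = ni_correlations(self._trace(ni), self._behavior(certainty))
        assert res.r_certainty_extremes == pytest.approx(1.0)


class TestFeatureHistogram:
    def test_total_conserved(self, montage):
        rng = np.random.default_rng(0)
        from nitrack.features import feature_columns

        cols = feature_columns(montage)
        runs = [
            RunResult(i + 1, list(rng.choice(cols, 10, replace=False)), np.zeros(1), 0.0)
            for i in range(100)
        ]
        hist, marginals = feature_histogram(runs, montage)
        assert hist["count"].sum() == 1000
        assert marginals["count"].sum() == 1000
        assert set(marginals["region"]) <= {"frontal", "temporal", "parietal", "occipital"}

    def test_constant_selection(self, montage):
        from nitrack.features import feature_columns

        cols = feature_columns(montage)[:10]
        runs = [RunResult(i + 1, cols, np.zeros(1), 0.0) for i in range(100)]
        hist, _ = feature_histogram(runs, montage)
        assert len(hist) == 10
        assert (hist["count"] == 100).all()


class TestEffectiveness:
    @pytest.mark.parametrize(
        "p,n_perm,expected",
        [(0.0, 200, "effective"), (0.5, 200, "ineffective"),
         (0.0005, 1000, "effective"), (0.004, 1000, "ineffective")],
    )
    def test_threshold(self, p, n_perm, expected):
        assert classify_effectiveness(p, n_perm) == expected
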