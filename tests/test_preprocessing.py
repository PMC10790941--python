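import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from nitrack.preprocessing import (
    BAND_NAMES,
    DegenerateBaselineError,
    NoPeakError,
    UnsupportedRateError,
    bandpass_1_50,
    baseline_z_normalize,
    define_bands,
    estimate_iaf,
    filter_hilbert_power,
    preprocess_recording,
    resample_256,
)
from nitrack.synthetic import SessionRecording


def _recording(signal: np.ndarray, fs: float = 500.0) -> SessionRecording:
    n = signal.shape[1]
    segments = pd.DataFrame(
        dict(segment_kind=["navigation"], trial_index=[1], block_index=[1],
             start_sample=[0], end_sample=[n])
    )
    behavior = pd.DataFrame(
        dict(trial_index=[1], block_index=[1], certainty_rating=[5],
             trial_time_s=[n / fs], ideal_time_s=[n / fs])
    )
    return SessionRecording(
        participant_id="T01", is_responder=False, sampling_rate=fs,
        channel_labels=tuple(f"ch{i}" for i in range(signal.shape[0])),
        signal=signal, segments=segments, behavior=behavior,
    )


def _sine(freq: float, duration: float, fs: float) -> np.ndarray:
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


class TestResample:
    def test_sample_count(self):
        rec = _recording(np.zeros((2, 5000)))
        out = resample_256(rec)
        assert out.sampling_rate == 256.0
        assert abs(out.signal.shape[1] - 2560) <= 1

    def test_ten_hz_peak_preserved(self):
        rec = _recording(_sine(10.0, 20.0, 500.0))
        out = resample_256(rec)
        freqs, psd = sps.periodogram(out.signal[0], fs=256.0)
        assert abs(freqs[np.argmax(psd)] - 10.0) < 0.1

    def test_beyond_nyquist_attenuated(self):
        rec = _recording(_sine(200.0, 20.0, 500.0))
        out = resample_256(rec)
        in_rms = np.sqrt(np.mean(rec.signal**2))
        out_rms = np.sqrt(np.mean(out.signal**2))
        assert 20 * np.log10(out_rms / in_rms) < -20.0

    def test_segment_remap_floor_ceil(self):
        sig = np.zeros((1, 5000))
        rec = _recording(sig)
        rec.segments.loc[0, ["start_sample", "end_sample"]] = [1000, 4999]
        out = resample_256(rec)
        assert out.segments.loc[0, "start_sample"] == int(np.floor(1000 * 256 / 500))
        assert out.segments.loc[0, "end_sample"] == int(np.ceil(4999 * 256 / 500))

    def test_already_256_noop_and_other_rates_rejected(self):
        rec256 = _recording(np.zeros((1, 1000)), fs=256.0)
        assert resample_256(rec256) is rec256
        with pytest.raises(UnsupportedRateError):
            resample_256(_recording(np.zeros((1, 1000)), fs=1000.0))


class TestBandpass:
    def test_dc_removed(self):
        rec = _recording(np.full((1, 256 * 20), 7.5), fs=256.0)
        out = bandpass_1_50(rec)
        assert abs(out.signal.mean()) < 0.05

    def test_passband_amplitude_preserved(self):
        rec = _recording(_sine(10.0, 30.0, 256.0), fs=256.0)
        out = bandpass_1_50(rec)
        mid = slice(256 * 5, -256 * 5)
        ratio = np.sqrt(np.mean(out.signal[0, mid] ** 2) / np.mean(rec.signal[0, mid] ** 2))
        assert abs(ratio - 1.0) < 0.05

    def test_sixty_hz_attenuated(self):
        rec = _recording(_sine(60.0, 30.0, 256.0), fs=256.0)
        out = bandpass_1_50(rec)
        ratio = np.sqrt(np.mean(out.signal**2) / np.mean(rec.signal**2))
        assert ratio < 0.10


class TestIAF:
    def _baseline(self, freq: float, fs: float = 256.0, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        t = np.arange(int(40 * fs)) / fs
        osc = 5.0 * np.sin(2 * np.pi * freq * t)
        return osc[None, :] + 0.5 * rng.standard_normal((3, len(t)))

    def test_planted_peak_recovered(self):
        iaf = estimate_iaf(self._baseline(10.0), self._baseline(10.0, seed=1))
        assert abs(iaf - 10.0) <= 0.25

    def test_average_of_two_peaks(self):
        iaf = estimate_iaf(self._baseline(9.5), self._baseline(10.5, seed=1))
        assert iaf == pytest.approx(10.0, abs=1e-9)

    def test_white_noise_raises_no_peak(self):
        rng = np.random.default_rng(0)
        noise = lambda: rng.standard_normal((3, 256 * 40))
        with pytest.raises(NoPeakError):
            estimate_iaf(noise(), noise())

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError, match="30 s"):
            estimate_iaf(self._baseline(10.0)[:, : 256 * 10], self._baseline(10.0))


class TestBands:
    def test_iaf_10(self):
        scheme = define_bands(10.0)
        assert scheme.bands == {
            "theta": (4.0, 6.0),
            "alpha_low1": (6.0, 8.0),
            "alpha_low2": (8.0, 10.0),
            "alpha_high": (10.0, 12.0),
        }

    def test_iaf_8_theta(self):
        assert define_bands(8.0).bands["theta"] == (2.0, 4.0)

    def test_out_of_range_rejected(self):
        for bad in (7.9, 15.1):
            with pytest.raises(ValueError):
                define_bands(bad)

    @given(st.floats(min_value=8.0, max_value=15.0, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_properties(self, iaf):
        scheme = define_bands(iaf)
        edges = [scheme.bands[b] for b in BAND_NAMES]
        for lo, hi in edges:
            assert hi - lo == pytest.approx(2.0)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(edges, edges[1:]):
            assert a_hi == b_lo
        assert edges[0][0] == pytest.approx(iaf - 6)
        assert edges[-1][1] == pytest.approx(iaf + 2)
        assert edges[0][0] > 1.0 and edges[-1][1] < 50.0


class TestFilterHilbert:
    def test_superposition(self):
        fs = 256.0
        t = np.arange(int(60 * fs)) / fs
        in_band = np.sin(2 * np.pi * 10.0 * t)
        far = 0.8 * np.sin(2 * np.pi * 30.0 * t)
        mid = slice(int(5 * fs), int(-5 * fs))
        p_single = filter_hilbert_power(in_band[None, :], (9.0, 11.0))[0, mid]
        p_mix = filter_hilbert_power((in_band + far)[None, :], (9.0, 11.0))[0, mid]
        assert np.abs(p_mix.mean() - p_single.mean()) / p_single.mean() < 0.10

    def test_power_nonnegative_and_band_validated(self):
        x = np.random.default_rng(0).standard_normal((2, 256 * 10))
        p = filter_hilbert_power(x, (8.0, 10.0))
        assert (p >= 0).all()
        with pytest.raises(ValueError):
            filter_hilbert_power(x, (0.5, 2.5))


class TestBaselineNormalize:
    def test_baseline_itself_standardized(self):
        rng = np.random.default_rng(1)
        power = rng.gamma(2.0, 1.0, size=(4, 5000))
        z = baseline_z_normalize(power, (0, 2000))
        assert np.abs(z[:, :2000].mean(axis=1)).max() < 1e-12
        assert np.abs(z[:, :2000].std(axis=1) - 1).max() < 1e-12

    def test_post_baseline_shift_moves_z_up(self):
        rng = np.random.default_rng(2)
        power = rng.gamma(2.0, 1.0, size=(2, 4000))
        boosted = power.copy()
        boosted[:, 2000:] *= 2.0
        z0 = baseline_z_normalize(power, (0, 2000))
        z1 = baseline_z_normalize(boosted, (0, 2000))
        assert np.allclose(z1[:, :2000], z0[:, :2000])
        assert (z1[:, 2000:].mean(axis=1) > z0[:, 2000:].mean(axis=1)).all()

    def test_degenerate_baseline_rejected(self):
        power = np.ones((1, 1000))
        with pytest.raises(DegenerateBaselineError):
            baseline_z_normalize(power, (0, 500))


class TestPreprocessEndToEnd:
    def test_iaf_close_to_planted(self, tiny_cohort, tiny_norm):
        rec = next(r for r in tiny_cohort if r.is_responder)
        assert abs(tiny_norm.band_scheme.iaf - rec.true_iaf) <= 0.3

    def test_baseline_invariant_all_bands(self, tiny_norm):
        seg = tiny_norm.segments
        eo = seg[seg["segment_kind"] == "eyes_open"].iloc[0]
        sl = slice(int(eo.start_sample), int(eo.end_sample))
        for band in BAND_NAMES:
            z = tiny_norm.power[band][:, sl]
            assert np.abs(z.mean(axis=1)).max() < 1e-9
            assert np.abs(z.std(axis=1) - 1).max() < 1e-9

    def test_responder_alpha_high_rises(self, tiny_norm):
        seg = tiny_norm.segments
        nav = seg[seg["segment_kind"] == "navigation"]
        occ = [tiny_norm.channel_labels.index(c) for c in ("O1", "Oz", "O2")]

        def mean_z(block):
            rows = nav[nav["block_index"] == block]
            vals = [
                tiny_norm.power["alpha_high"][occ, int(r.start_sample):int(r.end_sample)].mean()
                for r in rows.itertuples()
            ]
            return float(np.mean(vals))

        assert mean_z(int(nav["block_index"].max())) > mean_z(1)

    def test_fast_and_sequential_paths_agree(self, tiny_cohort, montage):
        """The one-FFT spectral path must reproduce the sequential
        zero-phase FIR + Hilbert route (the two differ only in the
        finite-length edge treatment of the analytic signal, whose 1/t
        tails leave a small residual everywhere)."""
        rec = tiny_cohort[0]
        fast = preprocess_recording(rec, keep_channels=montage.channel_labels)
        slow = preprocess_recording(
            rec, keep_channels=montage.channel_labels, artifact_hook=lambda r: r
        )
        assert fast.band_scheme.iaf == slow.band_scheme.iaf
        margin = 6000  # past the longest filter transient
        for band in BAND_NAMES:
            a = fast.power[band][:, margin:-margin]
            b = slow.power[band][:, margin:-margin]
            assert np.abs(a - b).max() < 0.02  # z-units; catches any O(1) defect

    def test_deterministic_rerun(self, tiny_cohort, montage, tiny_norm):
        rec = next(r for r in tiny_cohort if r.is_responder)
        again = preprocess_recording(rec, keep_channels=montage.channel_labels)
        for band in BAND_NAMES:
            assert np.array_equal(again.power[band], tiny_norm.power[band])
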