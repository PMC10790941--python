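"""Synthetic single-session EEG training cohorts.

Emulates a spatial-navigation training study: each participant completes
``n_trials`` navigation trials in blocks of ``block_size``, with a 1-min
eyes-open rest before every block and an eyes-closed rest at the very start
and end of the session.  Per trial the participant reports a certainty
rating (1-10) that rises to a plateau, and a completion time that falls
toward an "ideal" time.

The EEG is a sum of 1/f ("pink") background noise, a theta oscillation at
IAF-5 Hz, and an alpha oscillation whose amplitude carries the planted
effect: for *responders* the upper-alpha amplitude grows with the latent
proficiency trajectory; for *non-responders* it stays flat (or decreases,
mimicking the minority pattern seen in real trainees).  The task-modulated
alpha component is centred in the upper-alpha band (IAF + 1 Hz by default)
so the effect lands in the alpha-high feature band; eyes-closed rest places
a strong occipital peak exactly at the participant's IAF, which is what the
IAF estimator consumes.

All randomness flows from ``CohortSpec.seed`` through a
``numpy.random.SeedSequence`` spawn tree, so cohorts are pure functions of
the spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .montage import CHANNELS_64, REGION_OF_64

__all__ = [
    "CohortSpec",
    "TrajectoryParams",
    "SessionRecording",
    "ConfigurationError",
    "generate_cohort",
    "participant_modes",
    "certainty_trajectory",
    "trial_times",
    "synthesize_trial_eeg",
]


class ConfigurationError(ValueError):
    """A cohort spec field violates the generator's contract."""


# Baseline regional gains for the alpha source; each participant multiplies
# these by an independent uniform jitter per region.
_REGION_ALPHA_BASE = {
    "frontal": 0.8,
    "temporal": 0.25,
    "parietal": 1.2,
    "occipital": 1.5,
    "central": 0.6,
}


@dataclass(frozen=True)
class TrajectoryParams:
    """Shape of the behavioral learning curves.

    ``plateau_block`` is the block by which both curves have saturated
    (logistic in trial index).  ``noise_sd`` is the rating noise (rating
    units); ``time_noise_sd`` the completion-time noise (percent points of
    excess over ideal).
    """

    certainty_floor: float = 1.0
    certainty_ceiling: float = 10.0
    plateau_block: int = 7
    time_excess_start: float = 100.0
    time_excess_end: float = 10.0
    noise_sd: float = 1.0
    time_noise_sd: float = 8.0

    def validate(self, n_blocks: int) -> None:
        if self.certainty_ceiling < self.certainty_floor:
            raise ConfigurationError("certainty_ceiling < certainty_floor")
        if not (1 <= self.plateau_block <= n_blocks):
            raise ConfigurationError(
                f"plateau_block={self.plateau_block} outside 1..{n_blocks}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one synthetic cohort."""

    n_participants: int = 15
    responder_fraction: float = 9 / 15
    n_trials: int = 60
    block_size: int = 6
    sampling_rate: float = 500.0
    max_trial_duration: float = 180.0
    min_trial_duration: float = 5.0
    baseline_duration: float = 60.0
    iaf_range: tuple[float, float] = (8.5, 12.5)
    alpha_effect_size: float = 2.0
    noise_exponent: float = 1.0
    noise_exponent_jitter: float = 0.15
    seed: int = 0
    # signal scales, µV
    noise_scale: float = 10.0
    theta_amplitude: float = 3.0
    alpha_amplitude: float = 6.0
    eyes_closed_boost: float = 3.0
    #: offset of the task-modulated alpha component above IAF (Hz); +1 puts
    #: it in the middle of the upper-alpha band [IAF, IAF+2].
    alpha_freq_offset: float = 1.0
    #: fraction of non-responders whose alpha trend *decreases* (the rest flat)
    nonresponder_decreasing_fraction: float = 0.5
    ideal_time_range: tuple[float, float] = (30.0, 60.0)
    region_weight_jitter: tuple[float, float] = (0.7, 1.3)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    channel_labels: tuple[str, ...] = CHANNELS_64

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_size

    @property
    def n_responders(self) -> int:
        return int(math.floor(self.responder_fraction * self.n_participants + 0.5))

    def validate(self) -> None:
        if self.n_trials % self.block_size != 0:
            raise ConfigurationError(
                f"n_trials={self.n_trials} is not a multiple of block_size={self.block_size}"
            )
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ConfigurationError(f"responder_fraction={self.responder_fraction} outside [0, 1]")
        if self.max_trial_duration > 180.0:
            raise ConfigurationError(
                f"max_trial_duration={self.max_trial_duration} exceeds the 180 s trial cap"
            )
        if self.min_trial_duration < 1.0:
            raise ConfigurationError("min_trial_duration must be >= 1 s (one epoch)")
        if self.baseline_duration < 30.0:
            raise ConfigurationError("baseline_duration must be >= 30 s")
        if not (self.iaf_range[0] >= 8.0 and self.iaf_range[1] <= 15.0):
            raise ConfigurationError(f"iaf_range={self.iaf_range} outside the 8-15 Hz search band")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        self.trajectory.validate(self.n_blocks)


@dataclass
class SessionRecording:
    """One participant's continuous session EEG plus metadata.

    ``signal`` is channels x samples in µV.  ``segments`` has columns
    ``segment_kind`` (navigation / eyes_open / eyes_closed), ``trial_index``
    (1-based, navigation only; nullable), ``block_index`` (1-based; nullable
    for eyes_closed), ``start_sample``, ``end_sample`` (half-open).
    ``behavior`` has one row per trial: ``trial_index``, ``block_index``,
    ``certainty_rating``, ``trial_time_s``, ``ideal_time_s``.
    """

    participant_id: str
    is_responder: bool
    sampling_rate: float
    channel_labels: tuple[str, ...]
    signal: np.ndarray
    segments: pd.DataFrame
    behavior: pd.DataFrame
    true_iaf: float | None = None

    def validate(self) -> None:
        seg = self.segments
        if not (seg["end_sample"] > seg["start_sample"]).all():
            raise ValueError("empty or inverted segment")
        if seg["start_sample"].min() < 0 or seg["end_sample"].max() > self.signal.shape[1]:
            raise ValueError("segment outside signal")
        ends = seg["end_sample"].to_numpy()
        starts = seg["start_sample"].to_numpy()
        if not (starts[1:] >= ends[:-1]).all():
            raise ValueError("segments overlap or are unordered")
        if not np.isfinite(self.signal).all():
            raise ValueError("non-finite sample in signal")
        ratings = self.behavior["certainty_rating"]
        if not ratings.between(1, 10).all():
            raise ValueError("certainty rating outside 1..10")
        if (self.behavior["trial_time_s"] <= 0).any():
            raise ValueError("non-positive trial time")

    def segments_of(self, kind: str) -> pd.DataFrame:
        return self.segments[self.segments["segment_kind"] == kind]

    def segment_signal(self, row) -> np.ndarray:
        return self.signal[:, int(row.start_sample):int(row.end_sample)]


def _progress(trial_index: np.ndarray, plateau_trial: int) -> np.ndarray:
    """Latent learning curve in [0, 1]: logistic in (1-based) trial index,
    ~0 at trial 1 and saturated (>0.997) from ``plateau_trial`` on."""
    mid = plateau_trial / 2.0
    scale = plateau_trial / 12.0
    return expit((trial_index - mid) / scale)


def certainty_trajectory(
    params: TrajectoryParams, n_trials: int, rng: np.random.Generator, block_size: int = 6
) -> np.ndarray:
    """Integer certainty ratings (1-10), rising to a plateau."""
    t = np.arange(1, n_trials + 1)
    p = _progress(t, params.plateau_block * block_size)
    raw = params.certainty_floor + (params.certainty_ceiling - params.certainty_floor) * p
    raw = raw + rng.normal(0.0, params.noise_sd, size=n_trials) if params.noise_sd > 0 else raw
    return np.clip(np.rint(raw), 1, 10).astype(int)


def trial_times(
    params: TrajectoryParams,
    ideal_times: np.ndarray,
    rng: np.random.Generator,
    block_size: int = 6,
    max_trial_duration: float = 180.0,
    min_trial_duration: float = 5.0,
) -> np.ndarray:
    """Completion times: ideal x (1 + excess/100), excess declining from
    ``time_excess_start`` to ``time_excess_end`` percent along the same
    saturating curve as certainty."""
    ideal_times = np.asarray(ideal_times, dtype=float)
    if (ideal_times <= 0).any():
        raise ValueError("ideal_times must be positive")
    n = len(ideal_times)
    t = np.arange(1, n + 1)
    p = _progress(t, params.plateau_block * block_size)
    excess = params.time_excess_end + (params.time_excess_start - params.time_excess_end) * (1 - p)
    if params.time_noise_sd > 0:
        excess = excess + rng.normal(0.0, params.time_noise_sd, size=n)
    times = ideal_times * (1.0 + excess / 100.0)
    return np.clip(times, min_trial_duration, max_trial_duration)


def _pink_noise(n_channels: int, n_samples: int, exponent: float, rng: np.random.Generator,
                sampling_rate: float) -> np.ndarray:
    """1/f^exponent noise with an *absolute* spectral scale.

    The spectrum is scaled analytically so that the 1-to-Nyquist band has
    unit variance regardless of segment length; per-segment empirical
    normalization would make band-limited noise power depend on segment
    duration (short trials have fewer low-frequency bins), creating a
    spurious duration-coupled class signal.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    # unit variance over the 1 Hz .. Nyquist reference band
    f1, f2 = 1.0, sampling_rate / 2.0
    if abs(exponent - 1.0) < 1e-9:
        ref = math.log(f2 / f1)
    else:
        ref = (f2 ** (1 - exponent) - f1 ** (1 - exponent)) / (1 - exponent)
    scale = math.sqrt(sampling_rate / (2.0 * ref))
    return np.fft.irfft(spec * (scale * shape), n=n_samples, axis=1)


def _slow_envelope(
    n_channels: int,
    n_samples: int,
    sampling_rate: float,
    rng: np.random.Generator,
    shared_depth: float = 0.1,
    channel_depth: float = 0.5,
) -> np.ndarray:
    """Positive, slowly varying amplitude envelopes (~1 Hz modulation).

    Each channel mixes a cohort-wide ("source") modulation with its own
    independent component, so channels carrying the same oscillation are
    correlated but not mutually redundant copies.
    """
    # knots every ~2 s keep the AM sidebands within +/-0.5 Hz of the
    # carrier, i.e. inside a single 2 Hz analysis band
    n_knots = max(int(n_samples / (2.0 * sampling_rate)) + 2, 4)
    t = np.linspace(0.0, n_knots - 1.0, n_samples)
    base = np.arange(n_knots)
    shared = np.interp(t, base, rng.standard_normal(n_knots))
    mods = np.empty((n_channels, n_samples))
    for c in range(n_channels):
        own = np.interp(t, base, rng.standard_normal(n_knots))
        mods[c] = shared_depth * shared + channel_depth * own
    return np.clip(1.0 + mods, 0.2, None)


def synthesize_trial_eeg(
    duration: float,
    iaf: float,
    alpha_high_gain: float,
    region_weights: np.ndarray,
    rng: np.random.Generator,
    *,
    sampling_rate: float = 500.0,
    noise_exponent: float = 1.0,
    noise_scale: float = 10.0,
    theta_amplitude: float = 3.0,
    alpha_amplitude: float = 6.0,
    alpha_freq_offset: float = 1.0,
) -> np.ndarray:
    """One segment of multi-channel EEG (µV), channels x samples.

    Channel c = pink noise + theta sine at IAF-5 Hz + amplitude-modulated
    alpha sine at IAF + ``alpha_freq_offset`` scaled by
    ``alpha_high_gain * region_weights[c]``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_ch = len(region_weights)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    sig = noise_scale * _pink_noise(n_ch, n, noise_exponent, rng, sampling_rate)

    theta_phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
    sig += theta_amplitude * np.sin(2 * np.pi * (iaf - 5.0) * t[None, :] + theta_phase)

    alpha_freq = iaf + alpha_freq_offset
    alpha_phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
    envelope = _slow_envelope(n_ch, n, sampling_rate, rng)
    carrier = np.sin(2 * np.pi * alpha_freq * t[None, :] + alpha_phase)
    amp = alpha_amplitude * alpha_high_gain * np.asarray(region_weights, dtype=float)[:, None]
    sig += amp * envelope * carrier
    return sig


def _participant_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def participant_modes(spec: CohortSpec) -> list[str]:
    """Per-participant ground-truth mode: ``responder`` for exactly
    ``round(responder_fraction * n_participants)`` participants, the rest
    split into ``flat`` and ``decreasing`` non-responders.  Pure function of
    the spec (shares the cohort seed stream)."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    n = spec.n_participants

    order = assign_rng.permutation(n)
    is_resp = np.zeros(n, dtype=bool)
    is_resp[order[: spec.n_responders]] = True
    non_resp_idx = np.flatnonzero(~is_resp)
    n_decreasing = int(math.floor(spec.nonresponder_decreasing_fraction * len(non_resp_idx) + 0.5))
    decreasing = np.zeros(n, dtype=bool)
    if len(non_resp_idx):
        decreasing[assign_rng.permutation(non_resp_idx)[:n_decreasing]] = True
    return [
        "responder" if is_resp[i] else ("decreasing" if decreasing[i] else "flat")
        for i in range(n)
    ]


def generate_cohort(spec: CohortSpec) -> list[SessionRecording]:
    """Generate a full cohort; deterministic given ``spec`` (incl. seed)."""
    modes = participant_modes(spec)
    root = np.random.SeedSequence(spec.seed)
    n = spec.n_participants
    streams = root.spawn(n + 1)[1:]
    ids = _participant_ids(n)
    cohort = []
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        cohort.append(_generate_session(spec, ids[i], modes[i], rng))
    return cohort


def _generate_session(
    spec: CohortSpec, participant_id: str, mode: str, rng: np.random.Generator
) -> SessionRecording:
    fs = spec.sampling_rate
    tr = spec.trajectory
    iaf = rng.uniform(*spec.iaf_range)
    beta = rng.uniform(
        max(0.3, spec.noise_exponent - spec.noise_exponent_jitter),
        spec.noise_exponent + spec.noise_exponent_jitter,
    )
    lo, hi = spec.region_weight_jitter
    region_gain = {r: b * rng.uniform(lo, hi) for r, b in _REGION_ALPHA_BASE.items()}
    weights = np.array(
        [region_gain[REGION_OF_64.get(ch, "central")] for ch in spec.channel_labels]
    )
    # per-channel spread on top of the regional profile
    weights = weights * rng.uniform(0.8, 1.2, size=len(weights))

    n_trials, bs = spec.n_trials, spec.block_size
    certainty = certainty_trajectory(tr, n_trials, rng, bs)
    ideal = rng.uniform(*spec.ideal_time_range, size=n_trials)
    times = trial_times(tr, ideal, rng, bs, spec.max_trial_duration, spec.min_trial_duration)
    proficiency = _progress(np.arange(1, n_trials + 1), tr.plateau_block * bs)
    if mode == "responder":
        gains = 1.0 + (spec.alpha_effect_size - 1.0) * proficiency
    elif mode == "decreasing":
        gains = spec.alpha_effect_size - (spec.alpha_effect_size - 1.0) * proficiency
    else:
        gains = np.ones(n_trials)

    synth_kw = dict(
        sampling_rate=fs,
        noise_exponent=beta,
        noise_scale=spec.noise_scale,
        theta_amplitude=spec.theta_amplitude,
        alpha_amplitude=spec.alpha_amplitude,
    )

    chunks: list[np.ndarray] = []
    seg_rows: list[dict] = []
    cursor = 0

    def add_segment(kind: str, trial_index, block_index, arr: np.ndarray) -> None:
        nonlocal cursor
        chunks.append(arr.astype(np.float32))
        seg_rows.append(
            dict(
                segment_kind=kind,
                trial_index=trial_index,
                block_index=block_index,
                start_sample=cursor,
                end_sample=cursor + arr.shape[1],
            )
        )
        cursor += arr.shape[1]

    def eyes_closed() -> np.ndarray:
        # strong occipital-weighted alpha exactly at IAF: the IAF estimator's input
        return synthesize_trial_eeg(
            spec.baseline_duration, iaf, spec.eyes_closed_boost, weights, rng,
            alpha_freq_offset=0.0, **synth_kw,
        )

    add_segment("eyes_closed", pd.NA, pd.NA, eyes_closed())
    trial = 0
    for block in range(1, spec.n_blocks + 1):
        add_segment(
            "eyes_open", pd.NA, block,
            synthesize_trial_eeg(
                spec.baseline_duration, iaf, 1.0, weights, rng,
                alpha_freq_offset=spec.alpha_freq_offset, **synth_kw,
            ),
        )
        for _ in range(bs):
            add_segment(
                "navigation", trial + 1, block,
                synthesize_trial_eeg(
                    float(times[trial]), iaf, float(gains[trial]), weights, rng,
                    alpha_freq_offset=spec.alpha_freq_offset, **synth_kw,
                ),
            )
            trial += 1
    add_segment("eyes_closed", pd.NA, pd.NA, eyes_closed())

    segments = pd.DataFrame(seg_rows)
    segments["trial_index"] = segments["trial_index"].astype("Int64")
    segments["block_index"] = segments["block_index"].astype("Int64")
    behavior = pd.DataFrame(
        dict(
            trial_index=np.arange(1, n_trials + 1),
            block_index=np.repeat(np.arange(1, spec.n_blocks + 1), bs),
            certainty_rating=certainty,
            trial_time_s=times,
            ideal_time_s=ideal,
        )
    )
    rec = SessionRecording(
        participant_id=participant_id,
        is_responder=(mode == "responder"),
        sampling_rate=fs,
        channel_labels=tuple(spec.channel_labels),
        signal=np.hstack(chunks),
        segments=segments,
        behavior=behavior,
        true_iaf=iaf,
    )
    rec.validate()
    return rec


def desk_spec(**overrides) -> CohortSpec:
    """Minutes-scale preset: 6 participants, 20 trials in 4 blocks of 5,
    short trials and 30 s baselines, feature-montage channels only."""
    base = CohortSpec(
        n_participants=6,
        responder_fraction=4 / 6,
        n_trials=20,
        block_size=5,
        max_trial_duration=30.0,
        baseline_duration=30.0,
        ideal_time_range=(8.0, 12.0),
        trajectory=TrajectoryParams(plateau_block=3),
        channel_labels=tuple(
            ch for ch in CHANNELS_64 if REGION_OF_64[ch] != "central"
        ),
    )
    return replace(base, **overrides)


def tiny_spec(**overrides) -> CohortSpec:
    """Seconds-scale preset for smoke tests: 3 participants, 12 trials."""
    base = CohortSpec(
        n_participants=3,
        responder_fraction=2 / 3,
        n_trials=12,
        block_size=6,
        max_trial_duration=15.0,
        baseline_duration=30.0,
        ideal_time_range=(5.0, 8.0),
        trajectory=TrajectoryParams(plateau_block=2),
        channel_labels=tuple(
            ch for ch in CHANNELS_64 if REGION_OF_64[ch] != "central"
        ),
    )
    return replace(base, **overrides)
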