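"""Synthetic multichannel motor-imagery EEG with blink artifacts.

Emulates the statistical structure the decoding pipeline assumes, so every
stage is testable without recorded data:

* background 1/f ("pink-ish") noise on every EEG channel,
* class-specific 8-30 Hz oscillatory components (amplitude-modulated 10 Hz
  mu and 22 Hz beta sinusoids with random phases) on each class's "active"
  channels, restricted to the 2-7 s motor-imagery window of each 9 s trial,
* a shared blink train — raised-cosine pulses at Poisson onsets — recorded
  almost cleanly on the VEOG channel and projected onto the EEG channels
  through a front-to-back attenuation profile (strongest frontally).

The raised-cosine blink is band-limited below 8 Hz, so the 8-30 Hz band-pass
alone removes most but not all of it (leakage via onset transients) — the
contamination regime the wCCA stage is designed for. The per-class
band-power gain is calibrated against the measured background band power so
active channels exceed inactive ones by the configured factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .montage import (
    CLASS_ORDER,
    ContinuousRecording,
    Dataset,
    Montage,
    assign_splits,
    default_montage,
    epoch_trials,
)


@dataclass(frozen=True)
class ClassPattern:
    """Active channels and 8-30 Hz band-power gain for one MI state."""

    channels: tuple[str, ...]
    gain: float = 3.0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("band-power gain must be >= 0")


def default_class_patterns() -> dict[str, ClassPattern]:
    """Distinct two-channel activation sets per state (clearly separated)."""
    return {
        "R": ClassPattern(("C3", "CP3")),
        "RF": ClassPattern(("C4", "CP4")),
        "LH": ClassPattern(("FC4", "P4")),
        "RS": ClassPattern(("FC3", "P3")),
    }


def default_frontal_decay() -> dict[str, float]:
    """Blink projection attenuation per channel, largest frontally."""
    return {
        "FZ": 0.70, "FC3": 0.60, "FC4": 0.60, "CZ": 0.45,
        "C3": 0.35, "C4": 0.35, "CP3": 0.25, "CP4": 0.25,
        "P3": 0.15, "P4": 0.15, "T7": 0.05, "T8": 0.05,
        "P7": 0.05, "P8": 0.05,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic recordings.

    Defaults mirror the acquisition protocol the pipeline targets: five
    subjects, 60 trials per state (50 train / 10 test), 9 s trials sampled
    at 256 Hz with the imagery period in [2, 7) s.
    """

    n_subjects: int = 5
    trials_per_state: int = 60
    train_per_state: int = 50
    fs: float = 256.0
    trial_len: float = 9.0
    mi_window: tuple[float, float] = (2.0, 7.0)
    class_pattern_map: Mapping[str, ClassPattern] = field(default_factory=default_class_patterns)
    background_noise_sd: float = 10.0
    blink_rate: float = 0.25
    blink_amplitude: float = 200.0
    blink_width: float = 0.4
    frontal_decay: Mapping[str, float] = field(default_factory=default_frontal_decay)
    veog_noise_sd: float = 2.0
    line_noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.blink_rate, self.blink_amplitude, self.blink_width,
               self.background_noise_sd, self.veog_noise_sd) < 0:
            raise ValueError("rates, amplitudes and noise levels must be >= 0")
        if set(self.class_pattern_map) != set(CLASS_ORDER):
            raise ValueError(f"class_pattern_map keys must be {set(CLASS_ORDER)}")
        if not all(0.0 <= v <= 1.0 for v in self.frontal_decay.values()):
            raise ValueError("frontal_decay values must lie in [0, 1]")
        if self.train_per_state > self.trials_per_state:
            raise ValueError("train_per_state cannot exceed trials_per_state")


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------


def generate_blink_train(
    duration: float,
    rate: float,
    amplitude: float,
    width: float,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sum of raised-cosine blink pulses at Poisson-distributed onsets.

    Returns a 1 x T signal (T = round(duration * fs)); overlapping pulses
    sum linearly. Deterministic given the seed.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_total = int(round(duration * fs))
    out = np.zeros(t_total)
    if rate <= 0 or amplitude == 0 or width <= 0:
        # still consume the event draw so seeding stays stage-stable
        rng.poisson(max(rate, 0.0) * duration)
        return out
    n_events = rng.poisson(rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_events))
    w = int(round(width * fs))
    pulse = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(w) / w))
    for onset in onsets:
        s0 = int(round(onset * fs))
        s1 = min(s0 + w, t_total)
        out[s0:s1] += pulse[: s1 - s0]
    return out


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float, sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, flat below 1 Hz, normalized to sd per row."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    shaped *= sd / shaped.std(axis=-1, keepdims=True)
    return shaped


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float] = (8.0, 30.0)) -> float:
    """Welch band power (variance contribution) of a 1-D segment."""
    nper = min(512, x.size)
    f, psd = sps.welch(x, fs=fs, nperseg=nper)
    mask = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(psd[mask], f[mask]))


def _mi_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulation envelope over the imagery window: 0.25 s
    raised-cosine on/off ramps times a slow (0.4 Hz) sinusoidal modulation."""
    t = np.arange(n) / fs
    env = np.ones(n)
    ramp = int(round(0.25 * fs))
    if 2 * ramp < n:
        up = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = up
        env[-ramp:] = up[::-1]
    mod = 1.0 + 0.3 * np.sin(2.0 * np.pi * 0.4 * t + rng.uniform(0, 2 * np.pi))
    return env * mod


# ---------------------------------------------------------------------------
# Recording assembly
# ---------------------------------------------------------------------------


def _subject_rng(config: SyntheticConfig, subject_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(subject_idx,)))


def _balanced_labels(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    labels = [c for c in CLASS_ORDER for _ in range(config.trials_per_state)]
    return [labels[i] for i in rng.permutation(len(labels))]


def generate_recording(
    config: SyntheticConfig,
    subject_idx: int,
    montage: Montage | None = None,
) -> ContinuousRecording:
    """One subject's continuous session: concatenated 9 s trials + events."""
    montage = montage or default_montage(config.fs)
    rng = _subject_rng(config, subject_idx)
    fs = config.fs
    trial_samples = int(round(config.trial_len * fs))
    labels = _balanced_labels(config, rng)
    n_trials = len(labels)
    total = n_trials * trial_samples

    data = np.zeros((montage.n_eeg + 1, total))
    data[: montage.n_eeg] = _pink_noise(
        rng, montage.n_eeg, total, fs, config.background_noise_sd
    )

    # blink train shared by VEOG and (attenuated) all EEG channels
    blink = generate_blink_train(
        n_trials * config.trial_len, config.blink_rate, config.blink_amplitude,
        config.blink_width, fs, rng,
    )[:total]
    decay = np.array([config.frontal_decay.get(ch, 0.0) for ch in montage.eeg_channels])
    data[: montage.n_eeg] += decay[:, None] * blink[None, :]
    data[montage.n_eeg] = blink + config.veog_noise_sd * rng.standard_normal(total)

    if config.line_noise_amplitude > 0:
        t = np.arange(total) / fs
        data[: montage.n_eeg] += config.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t)

    # calibrate oscillation amplitude against measured background band power
    p_bg = np.mean([
        _band_power(data[montage.index(ch)][: min(total, 30 * int(fs))], fs)
        for ch in ("P7", "P8")  # low blink projection -> clean background estimate
    ])

    w0 = int(round(config.mi_window[0] * fs))
    w1 = int(round(config.mi_window[1] * fs))
    t_win = np.arange(w1 - w0) / fs
    for k, lab in enumerate(labels):
        pattern = config.class_pattern_map[lab]
        if pattern.gain <= 1.0 or not pattern.channels:
            continue
        s0 = k * trial_samples
        for ch in pattern.channels:
            env = _mi_envelope(w1 - w0, fs, rng)
            osc = env * (
                np.sin(2 * np.pi * 10.0 * t_win + rng.uniform(0, 2 * np.pi))
                + 0.7 * np.sin(2 * np.pi * 22.0 * t_win + rng.uniform(0, 2 * np.pi))
            )
            # mean power of osc = A^2 * mean(env^2) * (1 + 0.7^2) / 2
            amp = np.sqrt(2.0 * (pattern.gain - 1.0) * p_bg / (np.mean(env**2) * 1.49))
            data[montage.index(ch), s0 + w0 : s0 + w1] += amp * osc

    events = [(k * trial_samples, lab) for k, lab in enumerate(labels)]
    return ContinuousRecording(data=data, montage=montage, events=events)


def generate_recordings(config: SyntheticConfig) -> list[ContinuousRecording]:
    """All subjects' continuous recordings (deterministic given config.seed)."""
    return [generate_recording(config, i) for i in range(config.n_subjects)]


def dataset_from_recording(
    recording: ContinuousRecording,
    subject_id: str,
    train_per_state: int,
    window: tuple[float, float] | None = None,
) -> Dataset:
    """Epoch a recording into a split-tagged Dataset (full trials by default)."""
    if window is None:
        n_total = recording.n_samples
        n_trials = len(recording.events)
        window = (0.0, n_total / n_trials / recording.montage.fs)
    trials = epoch_trials(recording, window)
    splits = assign_splits([t.label for t in trials], train_per_state)
    return Dataset(subject_id=subject_id, trials=trials, splits=splits)


def generate_dataset(config: SyntheticConfig) -> list[Dataset]:
    """One split-tagged Dataset of raw (unfiltered) 9 s trials per subject."""
    out = []
    for i in range(config.n_subjects):
        rec = generate_recording(config, i)
        out.append(
            dataset_from_recording(
                rec, subject_id=f"S{i + 1}", train_per_state=config.train_per_state,
                window=(0.0, config.trial_len),
            )
        )
    return out


__all__ = [
    "ClassPattern",
    "SyntheticConfig",
    "default_class_patterns",
    "default_frontal_decay",
    "generate_blink_train",
    "generate_recording",
    "generate_recordings",
    "dataset_from_recording",
    "generate_dataset",
]
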