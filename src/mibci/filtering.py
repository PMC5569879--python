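"""Temporal filtering front end: 50 Hz notch and 8-30 Hz Butterworth band-pass.

Motor-imagery information lives in the mu (8-13 Hz) and beta (14-30 Hz)
rhythms, so the band-pass isolates 8-30 Hz before spatial filtering. The
notch suppresses power-line interference. Both filters are applied
forward-backward (zero-phase) by default so event-related (de)synchronization
timing inside the trial window is not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass / notch parameters.

    band : (low, high) pass band in Hz; default (8, 30).
    order : Butterworth order (per pass; doubled effectively in zero-phase mode).
    notch_freq : power-line frequency, Hz.
    notch_q : notch quality factor (bandwidth = notch_freq / Q).
    zero_phase : forward-backward filtering when True.
    """

    band: tuple[float, float] = (8.0, 30.0)
    order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not (0 < low < high < fs / 2):
            raise ValueError(f"invalid band {self.band} for fs={fs}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def notch_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Remove the power-line component from each row of a C x T matrix."""
    if fs <= 2 * spec.notch_freq:
        raise ValueError(f"fs={fs} too low for a {spec.notch_freq} Hz notch")
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if spec.zero_phase:
        return signal.filtfilt(b, a, x, axis=-1)
    return signal.lfilter(b, a, x, axis=-1)


def bandpass_butterworth(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth band-pass each row of a C x T matrix (default 8-30 Hz)."""
    spec.validate(fs)
    sos = signal.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def preprocess_continuous(
    data: np.ndarray,
    fs: float,
    spec: FilterSpec = FilterSpec(),
    notch: bool = True,
) -> np.ndarray:
    """Notch (optional) then band-pass a continuous C x T recording.

    Applied to the continuous record before epoching so filter edge
    transients fall outside the trial windows.
    """
    out = np.asarray(data, dtype=float)
    if notch:
        out = notch_filter(out, fs, spec)
    return bandpass_butterworth(out, fs, spec)


__all__ = ["FilterSpec", "notch_filter", "bandpass_butterworth", "preprocess_continuous"]
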