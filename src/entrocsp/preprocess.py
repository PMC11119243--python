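"""Cue-relative epoching and broadband Butterworth filtering.

The imagery segment of each trial is cut relative to the cue marker with
a half-open window ``[start, end)`` in seconds, so a 4-s window at
100 Hz yields exactly 400 samples.  The broadband stage is a 5th-order
8-35 Hz Butterworth bandpass applied forward-backward (zero phase); the
same second-order-sections engine backs the sub-band filter bank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import EpochingError, FilterDesignError, ValidationError
from .io_formats import ContinuousEEG, EpochedEEG

__all__ = ["EpochWindow", "BandpassSpec", "epoch", "bandpass", "bandpass_array"]


@dataclass(frozen=True)
class EpochWindow:
    """Epoch boundaries in seconds relative to the cue marker.

    The competition-style defaults differ by paradigm: 3.5-s cues are
    typically cut at [0.5, 3.0) s post-cue (imagery proper, discarding
    pre/post-imagination half seconds), 4-s cues at [0, 4) s.  Both are
    plain configuration here, nothing is hard-coded.
    """

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"epoch window end ({self.end_s}s) must exceed start ({self.start_s}s)"
            )


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth bandpass description (edges in Hz)."""

    low_hz: float = 8.0
    high_hz: float = 35.0
    order: int = 5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (self.low_hz > 0 and self.high_hz > self.low_hz):
            raise ValidationError(
                f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")

    def design(self, fs: float):
        """Second-order sections for this band at sampling rate *fs*."""
        if not self.high_hz < fs / 2:
            raise FilterDesignError(
                f"high edge {self.high_hz} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        return signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
        )


def epoch(continuous: ContinuousEEG, window: EpochWindow) -> EpochedEEG:
    """Cut one trial per *labelled* event (label 1 or 2).

    Trial ``m`` sample ``n`` is continuous sample
    ``pos_m + round(start_s * fs) + n`` with ``N = round((end-start)*fs)``
    samples per trial.  Unlabelled events (class 0) are skipped.
    """
    fs = continuous.fs
    start = int(round(window.start_s * fs))
    n_samples = int(round((window.end_s - window.start_s) * fs))
    if n_samples < 2:
        raise ValidationError(f"window spans only {n_samples} samples; need >= 2")

    labelled = [(i, int(p), int(c)) for i, (p, c) in enumerate(continuous.events) if c != 0]
    if not labelled:
        raise ValidationError("no labelled events to epoch")

    trials, labels = [], []
    for i, pos, cls in labelled:
        lo = pos + start
        hi = lo + n_samples
        if lo < 0 or hi > continuous.n_samples:
            raise EpochingError(
                f"event {i} at sample {pos}: window [{lo}, {hi}) exceeds "
                f"recording of {continuous.n_samples} samples"
            )
        trials.append(continuous.data[:, lo:hi])
        labels.append(cls)

    return EpochedEEG(
        data=np.stack(trials, axis=0),
        fs=fs,
        channel_names=list(continuous.channel_names),
        labels=np.asarray(labels, dtype=np.int64),
    )


def bandpass_array(x: np.ndarray, spec: BandpassSpec, fs: float, axis: int = -1) -> np.ndarray:
    """Filter an arbitrary array along *axis* with *spec* at rate *fs*.

    Zero-phase mode runs the filter forward and backward (odd-extension
    padding), cancelling group delay and squaring the magnitude response.
    """
    sos = spec.design(fs)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=axis)
    return signal.sosfilt(sos, x, axis=axis)


def bandpass(epoched: EpochedEEG, spec: BandpassSpec) -> EpochedEEG:
    """Apply *spec* per trial per channel; shape and labels unchanged."""
    return EpochedEEG(
        data=bandpass_array(epoched.data, spec, epoched.fs, axis=-1),
        fs=epoched.fs,
        channel_names=list(epoched.channel_names),
        labels=epoched.labels.copy(),
    )
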