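"""Sub-band decomposition of selected-channel trials.

The default bank is the four-band layout used for sensorimotor rhythms:
mu (8-13 Hz), low beta (13-22 Hz), high beta (22-35 Hz) and the full
8-35 Hz band.  Bands deliberately share edges and the full band
duplicates the narrow bands' content — the redundancy is part of the
design, letting the spatial-pattern stage weigh broadband and
narrowband variance contrasts independently.  Each band layer is the
same zero-phase Butterworth engine used by the broadband stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import FilterDesignError, ValidationError
from .io_formats import EpochedEEG
from .preprocess import BandpassSpec, bandpass_array

__all__ = ["DEFAULT_BANDS", "FilterBankSpec", "SubbandEEG", "apply_filterbank"]

DEFAULT_BANDS: Tuple[Tuple[float, float], ...] = ((8.0, 13.0), (13.0, 22.0), (22.0, 35.0), (8.0, 35.0))


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered band edges plus the shared Butterworth order (default 5)."""

    bands: Tuple[Tuple[float, float], ...] = DEFAULT_BANDS
    order: int = 5

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValidationError("filter bank needs at least one band")
        for lo, hi in self.bands:
            if not (0 < lo < hi):
                raise ValidationError(f"invalid band ({lo}, {hi}) Hz")
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_specs(self) -> list[BandpassSpec]:
        return [
            BandpassSpec(low_hz=lo, high_hz=hi, order=self.order, zero_phase=True)
            for lo, hi in self.bands
        ]


@dataclass
class SubbandEEG:
    """Band-decomposed trials: ``data`` has shape (S, M, L, N)."""

    data: np.ndarray
    spec: FilterBankSpec
    fs: float
    channel_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValidationError(
                f"sub-band data must be 4-D (bands x trials x channels x samples), got ndim={self.data.ndim}"
            )
        if self.data.shape[0] != self.spec.n_bands:
            raise ValidationError(
                f"{self.data.shape[0]} band layers but spec declares {self.spec.n_bands}"
            )

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def band(self, s: int) -> np.ndarray:
        """Trials of band *s* as an (M, L, N) array."""
        return self.data[s]

    def select_channels(self, idx: Sequence[int]) -> "SubbandEEG":
        """Restrict every band layer to the channels *idx* (ranked order)."""
        idx = np.asarray(idx, dtype=np.int64)
        return SubbandEEG(
            data=self.data[:, :, idx, :],
            spec=self.spec,
            fs=self.fs,
            channel_names=[self.channel_names[i] for i in idx],
            labels=self.labels.copy(),
        )


def apply_filterbank(epoched: EpochedEEG, spec: Optional[FilterBankSpec] = None) -> SubbandEEG:
    """Decompose each trial/channel into the bands of *spec* (default 4-band)."""
    spec = spec or FilterBankSpec()
    layers = []
    for band_spec in spec.band_specs():
        try:
            layers.append(bandpass_array(epoched.data, band_spec, epoched.fs, axis=-1))
        except FilterDesignError as err:
            raise FilterDesignError(
                f"band ({band_spec.low_hz}, {band_spec.high_hz}) Hz: {err}"
            ) from err
    return SubbandEEG(
        data=np.stack(layers, axis=0),
        spec=spec,
        fs=epoched.fs,
        channel_names=list(epoched.channel_names),
        labels=epoched.labels.copy(),
    )
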