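"""Synthetic two-class motor-imagery EEG with known ground truth.

The generator emulates event-related desynchronisation (ERD): a subset
of *informative* channels carries band-limited Gaussian sources (mu
band 8-13 Hz by default) whose amplitude differs between classes —
class 2's sources are scaled by ``erd_ratio`` in (0, 1], so the class
contrast is a variance difference, not a mean shift, which is exactly
the phenomenon spatial-pattern filters and entropy scoring detect.
All channels additionally receive independent broadband Gaussian noise.

Sources reach the informative channels through a mixing matrix.  The
default ``"random_orthonormal"`` draws one independent source per
informative channel and mixes them with a random orthonormal matrix,
so every informative channel receives exactly the full source variance
(orthonormal rows have unit norm) while the spatial structure stays
non-trivial.  Passing an explicit ``(n_informative, n_sources)`` array
instead gives a known discriminative direction for filter-recovery
checks.

Default geometry mirrors a typical two-class competition recording:
100 Hz sampling, 4-s trials (400 samples), 100 trials per class.
Everything is driven by a single seed; identical configs produce
identical tensors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .exceptions import ValidationError
from .io_formats import EpochedEEG, save_native
from .preprocess import BandpassSpec, bandpass_array

__all__ = ["SimConfig", "GroundTruth", "simulate_mi_eeg", "make_fixture_suite"]

_PAD_S = 1.0  # seconds of throw-away padding around each band-limited source


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the standard study conditions."""

    n_channels: int = 16
    informative_channels: Tuple[int, ...] = (2, 5, 8, 11)
    fs: float = 100.0
    trial_len_s: float = 4.0
    trials_per_class: int = 100
    source_band: Tuple[float, float] = (8.0, 13.0)
    erd_ratio: float = 0.5          # class-2 / class-1 source amplitude
    source_amplitude: float = 2.0   # class-1 source std relative to noise_sd
    noise_sd: float = 1.0
    mixing: Union[str, tuple] = "random_orthonormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        inf = tuple(self.informative_channels)
        if not inf:
            raise ValidationError("informative_channels must be nonempty")
        if min(inf) < 0 or max(inf) >= self.n_channels or len(set(inf)) != len(inf):
            raise ValidationError(
                f"informative_channels must be distinct indices in [0, {self.n_channels})"
            )
        if not 0 < self.erd_ratio <= 1:
            raise ValidationError(f"erd_ratio must be in (0, 1], got {self.erd_ratio}")
        if self.trials_per_class < 1:
            raise ValidationError("trials_per_class must be >= 1")
        if not (self.noise_sd >= 0 and self.source_amplitude > 0):
            raise ValidationError("noise_sd must be >= 0 and source_amplitude > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len_s * self.fs))


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle-style tests."""

    informative_channels: Tuple[int, ...]
    class_amplitudes: dict          # {1: A, 2: A * erd_ratio}
    mixing: np.ndarray              # (n_informative, n_sources)
    seed: int

    def to_dict(self) -> dict:
        return {
            "informative_channels": list(self.informative_channels),
            "class_amplitudes": {str(k): v for k, v in self.class_amplitudes.items()},
            "mixing": self.mixing.tolist(),
            "seed": self.seed,
        }


def _resolve_mixing(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_inf = len(cfg.informative_channels)
    if isinstance(cfg.mixing, str):
        if cfg.mixing != "random_orthonormal":
            raise ValidationError(f"unknown mixing mode {cfg.mixing!r}")
        q, _ = np.linalg.qr(rng.normal(size=(n_inf, n_inf)))
        return q
    q = np.asarray(cfg.mixing, dtype=np.float64)
    if q.ndim == 1:
        q = q[:, None]
    if q.shape[0] != n_inf:
        raise ValidationError(
            f"mixing matrix must have {n_inf} rows (one per informative channel), got {q.shape}"
        )
    return q


def simulate_mi_eeg(cfg: Optional[SimConfig] = None) -> tuple[EpochedEEG, GroundTruth]:
    """Generate a balanced two-class trial tensor plus its ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    pad = int(round(_PAD_S * cfg.fs))
    mix = _resolve_mixing(cfg, rng)
    n_sources = mix.shape[1]
    inf = np.asarray(cfg.informative_channels)
    band = BandpassSpec(low_hz=cfg.source_band[0], high_hz=cfg.source_band[1], order=5)

    m = 2 * cfg.trials_per_class
    labels = np.tile([1, 2], cfg.trials_per_class)
    amps = {1: cfg.source_amplitude, 2: cfg.source_amplitude * cfg.erd_ratio}

    data = np.empty((m, cfg.n_channels, n))
    for t in range(m):
        src = bandpass_array(
            rng.normal(size=(n_sources, n + 2 * pad)), band, cfg.fs, axis=-1
        )[:, pad:-pad]
        src = src / src.std(axis=-1, keepdims=True)
        x = cfg.noise_sd * rng.normal(size=(cfg.n_channels, n))
        x[inf] += mix @ (amps[labels[t]] * src)
        data[t] = x

    epoched = EpochedEEG(
        data=data,
        fs=cfg.fs,
        channel_names=[f"ch{i:02d}" for i in range(cfg.n_channels)],
        labels=labels,
    )
    truth = GroundTruth(
        informative_channels=tuple(cfg.informative_channels),
        class_amplitudes=amps,
        mixing=mix,
        seed=cfg.seed,
    )
    return epoched, truth


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

FIXTURE_SEED = 20240

FIXTURE_CONFIGS = {
    # cleanly separable: strong ERD contrast on 4 of 16 channels
    "separable": SimConfig(trials_per_class=60, erd_ratio=0.4, seed=FIXTURE_SEED),
    # null: identical class statistics, chance-level by construction
    "null": SimConfig(trials_per_class=60, erd_ratio=1.0, seed=FIXTURE_SEED + 1),
    # rank-deficient spatial covariance: channel 7 duplicates channel 0
    "rank_deficient": SimConfig(
        n_channels=8, informative_channels=(1, 3), trials_per_class=20,
        erd_ratio=0.4, seed=FIXTURE_SEED + 2,
    ),
    "single_trial_per_class": SimConfig(
        n_channels=8, informative_channels=(1, 3), trials_per_class=1,
        erd_ratio=0.4, seed=FIXTURE_SEED + 3,
    ),
    # one channel with zero variance end to end
    "constant_channel": SimConfig(
        n_channels=8, informative_channels=(1, 3), trials_per_class=20,
        erd_ratio=0.4, seed=FIXTURE_SEED + 4,
    ),
}


def make_fixture_suite(out_dir: Union[str, Path]) -> dict:
    """Write the standard test fixtures as native containers.

    Fully seeded: running twice produces byte-identical output.  Returns
    a name -> path mapping.  Each fixture directory also carries a
    ``groundtruth.json``.
    """
    out_dir = Path(out_dir)
    paths = {}
    for name, cfg in FIXTURE_CONFIGS.items():
        epoched, truth = simulate_mi_eeg(cfg)
        if name == "rank_deficient":
            epoched.data[:, 7, :] = epoched.data[:, 0, :]
        elif name == "constant_channel":
            epoched.data[:, 7, :] = 0.0
        dest = out_dir / name
        save_native(epoched, dest, storage="csv")
        with open(dest / "groundtruth.json", "w") as f:
            json.dump(truth.to_dict(), f, indent=1, sort_keys=True)
            f.write("\n")
        paths[name] = dest
    return paths
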