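"""Shannon-entropy channel scoring, ranking and selection.

Each channel of each trial is scored by the Shannon entropy of its
amplitude histogram: amplitudes are binned into ``bins`` equal-width
bins spanning ``[min(x), max(x)]`` of that trial/channel, and

    h = -sum_b p_b ln p_b

over the occupied bins, in nats.  A channel's weight is its mean
entropy over trials; channels are ranked descending and the top-k kept.
Because the bin edges scale with the data range, the score is invariant
to affine amplitude rescaling, and the ranking is invariant to the
logarithm base.

High entropy indicates a less predictable, more information-rich
amplitude pattern.  Physically, channels carrying band-limited
oscillatory sources (mu/beta rhythms) have fewer effective degrees of
freedom per trial than broadband noise channels, which compresses the
extreme values of their amplitude range relative to the bulk and spreads
occupancy across histogram bins — raising the score exactly on the
channels worth keeping.

An alternative reading of the per-channel score sums ``-p ln p`` over
*samples* rather than bins (weighting each bin by its count); it is
available as ``literal_sample_sum=True`` for comparison but is not
Shannon entropy and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import EpochedEEG

__all__ = [
    "EntropyScores",
    "ChannelRanking",
    "trial_entropy",
    "channel_entropy",
    "rank_channels",
    "select_channels",
    "sweep_channel_count",
]

DEFAULT_BINS = 256


@dataclass
class EntropyScores:
    """Per-channel mean entropies (nats) plus the bin count used."""

    h: np.ndarray
    bins: int
    per_trial: Optional[np.ndarray] = None  # (M, L) when requested

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.h)) or np.any(self.h < 0):
            raise ValidationError("entropy scores must be finite and non-negative")


@dataclass
class ChannelRanking:
    """Channel order (indices into the original montage), descending by score."""

    order: np.ndarray
    scores: EntropyScores

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64).ravel()
        n = self.order.shape[0]
        if not np.array_equal(np.sort(self.order), np.arange(n)):
            raise ValidationError("order must be a permutation of 0..L-1")
        if np.any(np.diff(self.scores.h[self.order]) > 0):
            raise ValidationError("scores along the ranking must be non-increasing")

    def to_frame(self, channel_names: Sequence[str]) -> pd.DataFrame:
        """Ranking as a tidy table (channel_name, score, rank)."""
        return pd.DataFrame(
            {
                "channel_name": [channel_names[i] for i in self.order],
                "channel_index": self.order,
                "score": self.scores.h[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def trial_entropy(x: np.ndarray, bins: int = DEFAULT_BINS, literal_sample_sum: bool = False) -> float:
    """Histogram Shannon entropy (nats) of one sample vector.

    A constant vector occupies a single bin and scores 0.  The score is
    bounded by ``ln(bins)``, attained at exactly uniform occupancy.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValidationError(f"need at least 2 samples, got {x.size}")
    if bins < 1:
        raise ValidationError(f"bins must be >= 1, got {bins}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples must be finite")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts / x.size
    occupied = p[p > 0]
    if literal_sample_sum:
        # per-sample reading: each sample contributes -p(its bin) ln p(its bin)
        return float(-np.sum(counts[counts > 0] * occupied * np.log(occupied)))
    return float(-np.sum(occupied * np.log(occupied)))


def channel_entropy(
    epoched: EpochedEEG,
    bins: int = DEFAULT_BINS,
    keep_per_trial: bool = False,
    literal_sample_sum: bool = False,
) -> EntropyScores:
    """Mean per-channel trial entropy over all trials."""
    m, l, _ = epoched.data.shape
    per_trial = np.empty((m, l))
    for i in range(m):
        for j in range(l):
            try:
                per_trial[i, j] = trial_entropy(
                    epoched.data[i, j], bins=bins, literal_sample_sum=literal_sample_sum
                )
            except ValidationError as err:
                raise ValidationError(f"trial {i}, channel {j}: {err}") from err
    return EntropyScores(
        h=per_trial.mean(axis=0),
        bins=bins,
        per_trial=per_trial if keep_per_trial else None,
    )


def rank_channels(scores: EntropyScores) -> ChannelRanking:
    """Descending-score ranking; ties broken by ascending channel index."""
    order = np.argsort(-scores.h, kind="stable")
    return ChannelRanking(order=order, scores=scores)


def select_channels(epoched: EpochedEEG, ranking: ChannelRanking, k: int) -> EpochedEEG:
    """Restrict to the top-*k* ranked channels, in ranked order."""
    l = epoched.n_channels
    if ranking.order.shape[0] != l:
        raise ValidationError(
            f"ranking covers {ranking.order.shape[0]} channels but data has {l}"
        )
    if not 1 <= k <= l:
        raise ValidationError(f"k must be in [1, {l}], got {k}")
    idx = ranking.order[:k]
    return EpochedEEG(
        data=epoched.data[:, idx, :],
        fs=epoched.fs,
        channel_names=[epoched.channel_names[i] for i in idx],
        labels=epoched.labels.copy(),
    )


def sweep_channel_count(
    epoched: EpochedEEG,
    ks: Sequence[int],
    cfg=None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Mean cross-validated accuracy as a function of channel count.

    Runs the full leak-free pipeline (entropy ranking, selection, filter
    bank, CSP, classifier — all refit inside each training fold) once per
    distinct ``k`` and tabulates mean CV accuracy.  Returns the table and
    the accuracy-maximising ``k`` (smallest on ties).
    """
    from .classify_eval import cross_validate  # local import: avoids cycle
    from .config import PipelineConfig

    cfg = cfg if cfg is not None else PipelineConfig()
    l = epoched.n_channels
    ks = sorted(set(int(k) for k in ks))
    if not ks or ks[0] < 1 or ks[-1] > l:
        raise ValidationError(f"ks must be distinct values in [1, {l}], got {ks}")

    rows = []
    for k in ks:
        cfg_k = cfg.replace(n_select=k)
        try:
            report = cross_validate(epoched, cfg_k, n_folds=n_folds, seed=seed)
        except Exception as err:
            raise type(err)(f"sweep at k={k}: {err}") from err
        rows.append({"k": k, "mean_accuracy": report.mean["accuracy"]})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["mean_accuracy"].idxmax(), "k"])
    return table, best_k
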