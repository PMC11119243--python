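"""Pipeline configuration: one object, every tunable, YAML in and out.

Defaults mirror the standard two-class motor-imagery setup: broadband
8-35 Hz order-5 zero-phase Butterworth, 256-bin entropy histograms,
the four-band filter bank, V=2 filter pairs per band (16 features),
an RBF-kernel SVM and stratified 5-fold cross-validation with channel
selection and CSP refit inside each training fold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .exceptions import ValidationError
from .filterbank import DEFAULT_BANDS

__all__ = ["ClassifierSpec", "PipelineConfig"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train on the fused feature vector.

    kind
        ``svm_rbf`` (default), ``lda`` or ``ann``.
    c
        SVM regularisation constant.
    gamma
        RBF width; ``"median"`` sets gamma = 1 / (2 d^2) with d the
        median pairwise training-feature distance, or pass a float.
    hidden_size / max_epochs
        ANN: single sigmoid hidden layer, two linear outputs, full-batch
        quasi-Newton training capped at ``max_epochs`` iterations.
    """

    kind: str = "svm_rbf"
    c: float = 1.0
    gamma: Union[str, float] = "median"
    hidden_size: int = 10
    max_epochs: int = 500
    lda_ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "lda", "ann"):
            raise ValidationError(f"classifier kind must be svm_rbf|lda|ann, got {self.kind!r}")
        if not self.c > 0:
            raise ValidationError(f"SVM C must be positive, got {self.c}")
        if self.hidden_size < 1:
            raise ValidationError(f"hidden_size must be >= 1, got {self.hidden_size}")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully-resolved settings for the selection/classification pipeline."""

    # epoching (used only when the input is continuous)
    epoch_start_s: float = 0.5
    epoch_end_s: float = 3.0
    # broadband preprocessing
    broadband_low_hz: float = 8.0
    broadband_high_hz: float = 35.0
    broadband_order: int = 5
    # entropy scoring / channel selection
    entropy_bins: int = 256
    entropy_literal_sample_sum: bool = False
    n_select: Optional[int] = None  # None = keep all channels
    leaky_selection: bool = False   # True: rank channels on all trials (whole-dataset mode)
    # filter bank
    bands: Tuple[Tuple[float, float], ...] = DEFAULT_BANDS
    filterbank_order: int = 5
    # CSP
    csp_pairs: int = 2          # V: filters kept per spectrum end
    csp_reg: float = 1e-6
    normalized_variance: bool = False
    # evaluation
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.entropy_bins < 1:
            raise ValidationError(f"entropy_bins must be >= 1, got {self.entropy_bins}")
        if self.n_select is not None and self.n_select < 1:
            raise ValidationError(f"n_select must be >= 1 or None, got {self.n_select}")
        if self.csp_pairs < 1:
            raise ValidationError(f"csp_pairs must be >= 1, got {self.csp_pairs}")
        if self.n_folds < 2:
            raise ValidationError(f"n_folds must be >= 2, got {self.n_folds}")

    # -- construction ------------------------------------------------------

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(tuple(float(e) for e in b) for b in d["bands"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = ClassifierSpec(**d["classifier"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as f:
            loaded = yaml.safe_load(f) or {}
        return cls.from_dict(loaded)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
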