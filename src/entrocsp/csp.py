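"""Common spatial patterns: covariances, filters, log-variance features.

CSP finds spatial filters w maximising the two-class variance ratio

    w = argmax (w' B1 w) / (w' B2 w),

where B_c is the class-mean trace-normalised trial covariance.  The
extremal directions are obtained from the generalised eigenproblem
posed against the composite covariance,

    B1 w = lambda (B1 + B2) w,

whose eigenvalues lie in [0, 1]: directions with lambda near 1 carry
maximal class-1 variance share, near 0 maximal class-2 share.  The
spatial filter matrix keeps the V eigenvectors from each end (2V
filters).  Per trial, each filter's projection is summarised by the
natural log of its variance; the per-band feature blocks are
concatenated band-major into the final feature vector of width S * 2V
(16 for the default four bands and V = 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from .exceptions import DegenerateTrialError, ValidationError
from .filterbank import SubbandEEG

__all__ = [
    "ClassCovariances",
    "CSPModel",
    "MultibandCSPModel",
    "FeatureMatrix",
    "class_covariances",
    "fit_csp",
    "band_features",
    "fit_multiband",
    "extract_features",
]

VAR_FLOOR = 1e-12  # guards log of a numerically-zero projection variance


@dataclass
class ClassCovariances:
    """Trace-normalised class-mean spatial covariances (class 1, class 2)."""

    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        for name, b in (("b1", self.b1), ("b2", self.b2)):
            b = np.asarray(b, dtype=np.float64)
            if b.ndim != 2 or b.shape[0] != b.shape[1]:
                raise ValidationError(f"{name} must be square, got shape {b.shape}")
            if np.max(np.abs(b - b.T)) > 1e-10:
                raise ValidationError(f"{name} is not symmetric to tolerance 1e-10")
            if np.min(linalg.eigvalsh(b)) < -1e-10:
                raise ValidationError(f"{name} has eigenvalues below -1e-10")
        if self.b1.shape != self.b2.shape:
            raise ValidationError("class covariances must have equal shapes")

    @property
    def n_channels(self) -> int:
        return self.b1.shape[0]


@dataclass
class CSPModel:
    """Spatial filters W (L x 2V) with their generalised eigenvalues.

    Columns 0..V-1 hold the largest-eigenvalue filters (descending),
    columns V..2V-1 the smallest (ascending); each column is scaled so
    w'(B1+B2)w = 1 and sign-fixed so its first nonzero entry is positive.
    """

    w: np.ndarray
    eigenvalues: np.ndarray
    v: int

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.w)):
            raise ValidationError("spatial filters must be finite")
        if self.w.shape[1] != 2 * self.v or self.eigenvalues.shape[0] != 2 * self.v:
            raise ValidationError("filter count must equal 2V")
        if 2 * self.v > self.w.shape[0]:
            raise ValidationError(f"2V={2 * self.v} exceeds channel count {self.w.shape[0]}")


@dataclass
class MultibandCSPModel:
    """One CSPModel per sub-band, plus the band layout and channel names."""

    models: list
    bands: tuple
    channel_names: list

    def __post_init__(self) -> None:
        if len(self.models) != len(self.bands):
            raise ValidationError(
                f"{len(self.models)} band models but {len(self.bands)} bands"
            )

    def to_dict(self) -> dict:
        """JSON-serialisable dump (filters, eigenvalues, bands, channels)."""
        return {
            "bands": [list(b) for b in self.bands],
            "channel_names": list(self.channel_names),
            "models": [
                {
                    "v": m.v,
                    "filters": m.w.tolist(),
                    "eigenvalues": m.eigenvalues.tolist(),
                }
                for m in self.models
            ],
        }


@dataclass
class FeatureMatrix:
    """Trials x (S * 2V) log-variance features with column names."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValidationError("feature matrix / name length mismatch")


def class_covariances(band_trials: np.ndarray, labels: np.ndarray) -> ClassCovariances:
    """Class-mean normalised covariances of an (M, L, N) trial block.

    Per trial ``C_m = X X' / trace(X X')``; ``B_c`` averages ``C_m`` over
    the trials of class c, so ``trace(B_c) = 1`` by construction.
    """
    x = np.asarray(band_trials, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if x.ndim != 3:
        raise ValidationError(f"band trials must be (M, L, N), got ndim={x.ndim}")
    if x.shape[2] < 2:
        raise ValidationError("need N > 1 samples per trial")

    out = {}
    for cls in (1, 2):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValidationError(f"class {cls} has no trials")
        acc = np.zeros((x.shape[1], x.shape[1]))
        for m in idx:
            c = x[m] @ x[m].T
            tr = np.trace(c)
            if tr <= 0:
                raise DegenerateTrialError(f"trial {m} has zero total power")
            acc += c / tr
        out[cls] = acc / idx.size
    # symmetrise away accumulation round-off
    b1 = (out[1] + out[1].T) / 2
    b2 = (out[2] + out[2].T) / 2
    return ClassCovariances(b1=b1, b2=b2)


def fit_csp(cov: ClassCovariances, v: int = 2, reg: float = 1e-6) -> CSPModel:
    """Solve B1 w = lambda (B1+B2) w and keep the V extremal pairs.

    Each class covariance is shrunk toward a scaled identity,
    ``B <- (1-reg) B + reg (trace(B)/L) I``, before composing, which keeps
    the composite positive definite when the selected channel count
    approaches the trial length.
    """
    l = cov.n_channels
    if not 1 <= 2 * v <= l:
        raise ValidationError(f"need 1 <= 2V <= L={l}, got V={v}")

    def shrink(b):
        return (1 - reg) * b + reg * (np.trace(b) / l) * np.eye(l)

    b1 = shrink(cov.b1)
    composite = b1 + shrink(cov.b2)
    try:
        eigvals, eigvecs = linalg.eigh(b1, composite)
    except linalg.LinAlgError as err:
        raise ValidationError(
            f"composite covariance not positive definite (reg={reg}); "
            "increase the regularisation"
        ) from err

    # eigh returns ascending eigenvalues with B-orthonormal vectors
    # (w' (B1+B2) w = 1 already holds column-wise)
    top = list(range(l - 1, l - 1 - v, -1))   # V largest, descending
    bottom = list(range(v))                   # V smallest, ascending
    keep = top + bottom
    w = eigvecs[:, keep].copy()
    lam = eigvals[keep].copy()

    for j in range(w.shape[1]):
        nz = np.flatnonzero(np.abs(w[:, j]) > 1e-12)
        if nz.size and w[nz[0], j] < 0:
            w[:, j] = -w[:, j]
    return CSPModel(w=w, eigenvalues=lam, v=v)


def band_features(
    band_trials: np.ndarray, model: CSPModel, normalized_variance: bool = False
) -> np.ndarray:
    """Log-variance of each filter's projection: an (M, 2V) block.

    ``normalized_variance=True`` divides each filter's variance by the
    trial's total filtered variance before the log (the conventional
    normalised variant); the default takes the log of the raw variance.
    Zero-variance projections are floored at 1e-12 before the log.
    """
    x = np.asarray(band_trials, dtype=np.float64)
    if x.ndim != 3 or x.shape[1] != model.w.shape[0]:
        raise ValidationError(
            f"band trials (M, {model.w.shape[0]}, N) expected, got {x.shape}"
        )
    proj = np.einsum("lv,mln->mvn", model.w, x)
    var = proj.var(axis=-1, ddof=1)
    if normalized_variance:
        var = var / np.maximum(var.sum(axis=1, keepdims=True), VAR_FLOOR)
    return np.log(np.maximum(var, VAR_FLOOR))


def fit_multiband(subbands: SubbandEEG, v: int = 2, reg: float = 1e-6) -> MultibandCSPModel:
    """Fit one CSP filter set per sub-band on that band's trials."""
    models = []
    for s in range(subbands.n_bands):
        try:
            cov = class_covariances(subbands.band(s), subbands.labels)
            models.append(fit_csp(cov, v=v, reg=reg))
        except (ValidationError, DegenerateTrialError) as err:
            raise type(err)(f"band {subbands.spec.bands[s]} Hz: {err}") from err
    return MultibandCSPModel(
        models=models,
        bands=tuple(subbands.spec.bands),
        channel_names=list(subbands.channel_names),
    )


def extract_features(
    subbands: SubbandEEG,
    model: MultibandCSPModel,
    normalized_variance: bool = False,
) -> FeatureMatrix:
    """Concatenate per-band feature blocks band-major into F (M x S*2V)."""
    if tuple(subbands.spec.bands) != tuple(model.bands):
        raise ValidationError(
            f"model bands {model.bands} do not match data bands {subbands.spec.bands}"
        )
    blocks, names = [], []
    for s, m in enumerate(model.models):
        blocks.append(band_features(subbands.band(s), m, normalized_variance))
        lo, hi = subbands.spec.bands[s]
        names.extend(f"band{lo:g}-{hi:g}Hz_f{vv}" for vv in range(2 * m.v))
    return FeatureMatrix(
        values=np.concatenate(blocks, axis=1),
        labels=subbands.labels.copy(),
        feature_names=names,
    )
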