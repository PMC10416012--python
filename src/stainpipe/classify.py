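"""Tile-level classifier contract, slide-level aggregation, threshold
selection, and the full metric suite (confusion metrics, ROC/AUC,
bootstrap confidence intervals)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import joblib
import numpy as np
from skimage.transform import downscale_local_mean
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve
from sklearn.neural_network import MLPClassifier

from .errors import (
    DegenerateLabels,
    InvalidInputError,
    NoTiles,
    UndefinedROC,
)

__all__ = [
    "TilePrediction",
    "SlideScore",
    "MetricsReport",
    "ROCCurve",
    "TrainConfig",
    "TileClassifier",
    "train_tile_classifier",
    "slide_score",
    "select_threshold",
    "compute_metrics",
    "f1_from_sensitivity_precision",
    "roc_and_auc",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class TilePrediction:
    slide_id: str
    row: int
    col: int
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise InvalidInputError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class SlideScore:
    slide_id: str
    fraction_positive: float
    n_tiles: int


@dataclass(frozen=True)
class MetricsReport:
    level: str  # "tile" | "slide"
    gamma: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: Tuple[str, ...] = ()  # metrics whose denominator was zero

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "gamma": self.gamma,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "undefined": list(self.undefined),
        }


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (published defaults) plus backend choice.

    The reference pipeline used a 34-layer residual network; at desk scale
    the default backend is a small multilayer perceptron over block-mean
    colour features, trained with Adam on binary cross-entropy.  Any
    backend honouring :class:`TileClassifier`'s contract can be plugged in.
    """

    learning_rate: float = 1e-4
    adam_betas: Tuple[float, float] = (0.9, 0.999)
    epochs: int = 100
    batch_size: int = 100
    model: str = "mlp"
    hidden_layer_sizes: Tuple[int, ...] = (64, 16)
    feature_grid: int = 16  # tiles are block-averaged to grid x grid x 3
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise InvalidInputError("hyperparameters must be positive")


def _tile_features(images: Sequence[np.ndarray], grid: int) -> np.ndarray:
    """Block-mean colour features: each tile reduced to grid x grid x 3,
    scaled to [0, 1] and flattened."""
    feats = []
    for img in images:
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise InvalidInputError("tiles must be HxWx3")
        fy = max(arr.shape[0] // grid, 1)
        fx = max(arr.shape[1] // grid, 1)
        small = downscale_local_mean(arr[: fy * grid, : fx * grid], (fy, fx, 1))
        feats.append(small.ravel() / 255.0)
    return np.asarray(feats)


class TileClassifier:
    """Handle returned by :func:`train_tile_classifier`.

    Exposes ``score(images) -> [0, 1]`` probabilities for the positive
    class plus joblib-backed save/load.
    """

    def __init__(self, model, config: TrainConfig):
        self._model = model
        self.config = config

    def score(self, images: Sequence[np.ndarray]) -> np.ndarray:
        X = _tile_features(images, self.config.feature_grid)
        return self._model.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        joblib.dump({"model": self._model, "config": self.config}, path)

    @classmethod
    def load(cls, path) -> "TileClassifier":
        blob = joblib.load(path)
        return cls(blob["model"], blob["config"])


def _build_backend(config: TrainConfig, n_samples: int):
    if config.model == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=config.hidden_layer_sizes,
            solver="adam",
            learning_rate_init=config.learning_rate,
            beta_1=config.adam_betas[0],
            beta_2=config.adam_betas[1],
            batch_size=min(config.batch_size, n_samples),
            max_iter=config.epochs,
            random_state=config.seed,
            tol=0.0,
            n_iter_no_change=config.epochs,
        )
    raise InvalidInputError(f"unknown classifier backend {config.model!r}")


def train_tile_classifier(
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    config: TrainConfig = TrainConfig(),
) -> TileClassifier:
    """Fit the configured backend on labelled tile images.

    Raises :class:`DegenerateLabels` unless both classes are present.
    Seeded-deterministic for the default backend.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise DegenerateLabels("training set must contain both classes")
    if len(images) != len(y):
        raise InvalidInputError("images and labels length mismatch")
    X = _tile_features(images, config.feature_grid)
    model = _build_backend(config, X.shape[0])
    import warnings as _w

    with _w.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        _w.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return TileClassifier(model, config)


def slide_score(
    preds: Sequence[TilePrediction], tile_cutoff: float = 0.5
) -> SlideScore:
    """Fraction of tiles whose score strictly exceeds ``tile_cutoff``."""
    if len(preds) == 0:
        raise NoTiles("no tile predictions for slide")
    slide_ids = {p.slide_id for p in preds}
    if len(slide_ids) != 1:
        raise InvalidInputError("predictions span multiple slides")
    scores = np.array([p.score for p in preds])
    return SlideScore(
        slide_id=next(iter(slide_ids)),
        fraction_positive=float((scores > tile_cutoff).mean()),
        n_tiles=len(preds),
    )


def _accuracy_at(fractions: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    pred = fractions > gamma
    return float((pred == labels.astype(bool)).mean())


def select_threshold(
    fractions: Sequence[float], labels: Sequence[int]
) -> float:
    """Smallest decision threshold maximizing accuracy.

    A slide is called positive iff its positive-tile fraction strictly
    exceeds the threshold.  Candidates are 0, 1, and the midpoints of
    consecutive distinct sorted fractions.
    """
    f = np.asarray(fractions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if f.size == 0:
        raise InvalidInputError("need at least one slide")
    uniq = np.unique(f)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    accs = np.array([_accuracy_at(f, y, g) for g in candidates])
    best = accs.max()
    return float(candidates[np.nonzero(accs == best)[0][0]])


def _safe_div(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(
    fractions: Sequence[float],
    labels: Sequence[int],
    gamma: float,
    level: str = "slide",
) -> MetricsReport:
    """Confusion counts and derived metrics at decision threshold ``gamma``
    (positive call = score strictly above gamma).  Metrics with a zero
    denominator are reported as 0 and flagged in ``undefined``."""
    f = np.asarray(fractions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (0.0 <= gamma <= 1.0):
        raise InvalidInputError("gamma must be in [0, 1]")
    pred = f > gamma
    truth = y.astype(bool)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    undefined: list = []
    accuracy = _safe_div(tp + tn, tp + fp + tn + fn, "accuracy", undefined)
    sensitivity = _safe_div(tp, tp + fn, "sensitivity", undefined)
    specificity = _safe_div(tn, tn + fp, "specificity", undefined)
    precision = _safe_div(tp, tp + fp, "precision", undefined)
    f1 = f1_from_sensitivity_precision(sensitivity, precision)
    if sensitivity + precision == 0:
        undefined.append("f1")
    return MetricsReport(
        level=level,
        gamma=float(gamma),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        undefined=tuple(undefined),
    )


def f1_from_sensitivity_precision(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity (recall) and precision; 0 when both
    are 0."""
    denom = sensitivity + precision
    if denom == 0:
        return 0.0
    return 2.0 * sensitivity * precision / denom


def roc_and_auc(
    fractions: Sequence[float], labels: Sequence[int]
) -> ROCCurve:
    """ROC over all distinct slide fractions with trapezoidal AUC."""
    f = np.asarray(fractions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise UndefinedROC("ROC requires both classes")
    fpr, tpr, thr = _sk_roc_curve(y, f, drop_intermediate=False)
    return ROCCurve(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr))
    )


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    fractions: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Percentile confidence interval of ``metric(fractions, labels)``
    under seeded slide-level resampling with replacement.

    The interval-estimation method behind published slide-level error bars
    is a stand-in; this is an ordinary nonparametric bootstrap.
    """
    f = np.asarray(fractions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if f.size < 2:
        raise InvalidInputError("bootstrap needs at least 2 slides")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, f.size, size=(n_boot, f.size))
    stats = np.array([metric(f[i], y[i]) for i in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
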