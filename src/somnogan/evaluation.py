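"""Generated-image quality (Fréchet distance) and staging metrics.

The Fréchet distance between Gaussians fitted to feature embeddings,

    FD(x, g) = ||u_x - u_g||^2 + Tr(S_x + S_g - 2 (S_x S_g)^{1/2}),

scores how closely generated images match real ones; lower is better.  The
feature space is pluggable: absolute values are only comparable within one
extractor, so every report records which was used.  A frozen random-weight
convolutional surrogate is the offline default (no pretrained weights are
bundled); raw pixels are available for toy problems.

Classification quality uses the standard confusion matrix with per-class
one-vs-rest precision, recall and F1 plus overall (micro) accuracy; classes
with zero support report NaN rather than a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import nn
from .containers import ImageSet

__all__ = [
    "PixelFeatures", "RandomConvFeatures", "extract_features", "FeatureStats",
    "frechet_distance", "frechet_from_images", "ConfusionCounts",
    "confusion_matrix", "EvalReport", "classification_metrics", "f1_score",
]


# ---------------------------------------------------------------------------
# feature extractors

class PixelFeatures:
    """Identity extractor: flattened raw pixels."""

    name = "pixels"

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return pixels.reshape(len(pixels), -1)


class RandomConvFeatures:
    """Frozen convolutional feature map with fixed random weights.

    Three strided conv + LeakyReLU stages followed by global average
    pooling.  Weights are drawn once from a fixed seed and never trained, so
    the embedding is deterministic and shared between the Fréchet score and
    the perceptual loss.  Works on any input size >= 8.
    """

    def __init__(self, channels: tuple[int, ...] = (16, 32, 64),
                 seed: int = 0, pool: bool = True, dtype: str = "float32"):
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        c_in = 3
        with nn.default_dtype(dtype):
            for c in channels:
                layers.append(nn.Conv2D(c_in, c, 3, rng, stride=2))
                layers.append(nn.LeakyReLU(0.2))
                c_in = c
        self.net = nn.Sequential(*layers)
        self.pool = pool
        self.out_channels = c_in
        self.name = f"random-conv-{'x'.join(map(str, channels))}"

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        feats = self.net.forward(np.asarray(pixels), train=False)
        if self.pool:
            return feats.mean(axis=(1, 2))
        return feats

    def feature_map(self, pixels: np.ndarray) -> np.ndarray:
        """Unpooled (n, h, w, d) feature map (for the perceptual loss)."""
        return self.net.forward(np.asarray(pixels), train=False)


def extract_features(images: "ImageSet | np.ndarray",
                     extractor) -> np.ndarray:
    """Embed a batch of images; returns an (n, d) matrix."""
    pixels = images.pixels if isinstance(images, ImageSet) else np.asarray(images)
    if len(pixels) == 0:
        raise ValueError("cannot extract features from an empty batch")
    feats = extractor(pixels)
    return feats.reshape(len(feats), -1)


# ---------------------------------------------------------------------------
# Fréchet distance

@dataclass
class FeatureStats:
    """Sample mean and covariance of a feature-space sample."""

    u: np.ndarray
    S: np.ndarray
    n: int

    @classmethod
    def from_features(cls, feats: np.ndarray) -> "FeatureStats":
        feats = np.asarray(feats, dtype=float)
        if feats.ndim != 2 or feats.shape[0] < 2:
            raise ValueError("need an (n >= 2, d) feature matrix")
        u = feats.mean(axis=0)
        S = np.cov(feats, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        return cls(u=u, S=0.5 * (S + S.T), n=feats.shape[0])


def _psd_sqrt(S: np.ndarray, tol: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < -tol * max(1.0, abs(vals.max())):
        raise np.linalg.LinAlgError(
            f"covariance not PSD within tolerance (min eig {vals.min():.3g})")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(stats_x: FeatureStats, stats_g: FeatureStats,
                     tol: float = 1e-10) -> float:
    """Fréchet distance between two feature Gaussians.

    The trace term uses the symmetric-product decomposition
    ``Tr((S_x S_g)^{1/2}) = Tr((S_x^{1/2} S_g S_x^{1/2})^{1/2})`` so only
    Hermitian eigendecompositions are needed; eigenvalues in [-tol, 0) are
    clipped to 0 and the result is clamped at 0.
    """
    if stats_x.u.shape != stats_g.u.shape or stats_x.S.shape != stats_g.S.shape:
        raise ValueError("feature statistics have mismatched dimensions")
    du = stats_x.u - stats_g.u
    sx_half = _psd_sqrt(stats_x.S, tol=1e-6)
    m = sx_half @ stats_g.S @ sx_half
    m = 0.5 * (m + m.T)
    vals = np.linalg.eigh(m)[0]
    if vals.min() < -1e-6 * max(1.0, abs(vals.max())):
        raise np.linalg.LinAlgError("product matrix not PSD within tolerance")
    tr_sqrt = np.sqrt(np.clip(vals, 0.0, None)).sum()
    fd = float(du @ du + np.trace(stats_x.S) + np.trace(stats_g.S)
               - 2.0 * tr_sqrt)
    return max(fd, 0.0)


def frechet_from_images(real: "ImageSet | np.ndarray",
                        fake: "ImageSet | np.ndarray",
                        extractor) -> float:
    """Convenience wrapper: embed both batches and score them."""
    fx = FeatureStats.from_features(extract_features(real, extractor))
    fg = FeatureStats.from_features(extract_features(fake, extractor))
    return frechet_distance(fx, fg)


# ---------------------------------------------------------------------------
# classification metrics

@dataclass
class ConfusionCounts:
    """Integer confusion counts, rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: list[str]

    def normalized(self) -> np.ndarray:
        """Row-normalised matrix; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index ``i``."""
        total = int(self.counts.sum())
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        return tp, fp, fn, total - tp - fp - fn


def confusion_matrix(y_true, y_pred, classes: list[str]) -> ConfusionCounts:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    for y in (y_true, y_pred):
        unknown = set(y) - set(classes)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in classes")
    if not y_true:
        return ConfusionCounts(np.zeros((len(classes), len(classes)),
                                        dtype=int), list(classes))
    counts = _sk_confusion(y_true, y_pred, labels=list(classes))
    return ConfusionCounts(counts.astype(int), list(classes))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN if both are zero/NaN."""
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Per-class precision/recall/F1, overall accuracy and the confusion
    matrix behind them.  Undefined metrics are NaN."""

    confusion: ConfusionCounts
    normalized: np.ndarray
    per_class: dict[str, dict[str, float]]
    accuracy: float
    extras: dict = field(default_factory=dict)

    def recall(self, cls: str) -> float:
        return self.per_class[cls]["recall"]

    def to_frame(self):
        """Per-class metrics as a pandas DataFrame (for CSV export)."""
        import pandas as pd
        return pd.DataFrame(self.per_class).T[
            ["precision", "recall", "f1", "support"]]


def classification_metrics(counts: ConfusionCounts) -> EvalReport:
    total = int(counts.counts.sum())
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(counts.classes):
        tp, fp, fn, _tn = counts.one_vs_rest(i)
        pre = tp / (tp + fp) if tp + fp > 0 else float("nan")
        rec = tp / (tp + fn) if tp + fn > 0 else float("nan")
        per_class[cls] = {"precision": pre, "recall": rec,
                          "f1": f1_score(pre, rec),
                          "support": float(tp + fn)}
    acc = float(np.trace(counts.counts)) / total if total else float("nan")
    return EvalReport(confusion=counts, normalized=counts.normalized(),
                      per_class=per_class, accuracy=acc)
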