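"""Confusion-matrix metrics (overall accuracy, mean IoU, Cohen's kappa),
misclassification maps, 2-D hidden-feature embeddings with a silhouette
separability score, and the cross-domain (year-shift) transfer harness.

Confusion-matrix convention: rows are predicted classes, columns are
reference classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import tiling
from .attnseg import AttentionSegNet
from .features import FeatureStack, NormStats, build_feature_stack, normalize_stack
from .synthgen import MultispectralScene, boundary_mask


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) int64, rows = predicted, cols = reference

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")

    @property
    def k(self):
        return self.counts.shape[0]

    @property
    def total(self):
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    oa: float
    per_class_iou: dict
    miou: float
    kappa: float
    class_names: tuple
    pixel_count: int

    def to_dict(self):
        return {"oa": self.oa, "per_class_iou": self.per_class_iou,
                "miou": self.miou, "kappa": self.kappa,
                "class_names": list(self.class_names),
                "pixel_count": self.pixel_count}


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, k: int,
                     mask: np.ndarray | None = None) -> ConfusionMatrix:
    """N_ij = number of pixels predicted i with reference j; `mask` marks
    pixels to ignore (True = ignore)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, truth {truth.shape}")
    p = pred.ravel()
    t = truth.ravel()
    if mask is not None:
        keep = ~np.asarray(mask).ravel()
        p, t = p[keep], t[keep]
    if len(p) and (p.min() < 0 or p.max() >= k or t.min() < 0 or t.max() >= k):
        raise ValueError(f"labels outside [0, {k})")
    counts = np.bincount(p.astype(np.int64) * k + t.astype(np.int64),
                         minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """OA = sum_i N_ii / N."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def per_class_iou(cm: ConfusionMatrix) -> dict:
    """IoU_i = N_ii / (N_i+ + N_+i - N_ii), omitting classes absent from
    both prediction and reference (with a warning)."""
    ious = {}
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    for i in range(cm.k):
        union = row[i] + col[i] - cm.counts[i, i]
        if union == 0:
            warnings.warn(f"class {i} absent from prediction and reference; "
                          "excluded from mean IoU", RuntimeWarning, stacklevel=2)
            continue
        ious[i] = float(cm.counts[i, i] / union)
    return ious


def mean_iou(cm: ConfusionMatrix) -> float:
    """Mean of the per-class IoU over the classes actually evaluated."""
    ious = per_class_iou(cm)
    if not ious:
        raise ValueError("no evaluable classes")
    return float(np.mean(list(ious.values())))


def kappa(cm: ConfusionMatrix) -> float:
    """kappa = (N*sum N_ii - sum N_i+ N_+i) / (N^2 - sum N_i+ N_+i)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    chance = int((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum())
    denom = n * n - chance
    if denom == 0:
        return float("nan")  # degenerate marginals: agreement by chance is total
    return float((n * np.trace(cm.counts) - chance) / denom)


def metrics_report(pred, truth, k: int = 3,
                   class_names=("other", "corn", "soybean"),
                   mask=None) -> MetricsReport:
    cm = confusion_matrix(pred, truth, k, mask=mask)
    ious = per_class_iou(cm)
    return MetricsReport(oa=overall_accuracy(cm),
                         per_class_iou={class_names[i]: v for i, v in ious.items()},
                         miou=float(np.mean(list(ious.values()))),
                         kappa=kappa(cm),
                         class_names=tuple(class_names),
                         pixel_count=cm.total)


def misclassification_map(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """1 where prediction differs from reference, 0 elsewhere."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    return (pred != truth).astype(np.uint8)


def boundary_error_fraction(err_map: np.ndarray, labels: np.ndarray,
                            width: int) -> float:
    """Fraction of misclassified pixels lying within `width` of a plot
    boundary (errors at mixed pixels / all errors)."""
    err = np.asarray(err_map, dtype=bool)
    total = int(err.sum())
    if total == 0:
        return 0.0
    near = boundary_mask(np.asarray(labels), width)
    return float((err & near).sum() / total)


# ---------------------------------------------------------------------------
# Hidden-feature embedding
# ---------------------------------------------------------------------------

def export_embedding(net: AttentionSegNet, stack: FeatureStack,
                     labels: np.ndarray, n: int = 3000, seed: int = 0,
                     crop_classes=(1, 2)) -> dict:
    """Project raw 8-channel pixel vectors and the network's penultimate
    features for `n` randomly sampled crop pixels to 2-D (t-SNE) and score
    both with the mean class silhouette.

    Returns a dict with 'raw_xy', 'net_xy' (n x 2), 'labels' (n,), and the
    two silhouette scores.
    """
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    labels = np.asarray(labels)
    rows, cols = np.where(np.isin(labels, crop_classes))
    if len(rows) == 0:
        raise ValueError("no crop pixels to sample")
    rng = np.random.default_rng(seed)
    if len(rows) < n:
        warnings.warn(f"only {len(rows)} crop pixels available; sampling all",
                      RuntimeWarning, stacklevel=2)
        sel = np.arange(len(rows))
    else:
        sel = rng.choice(len(rows), size=n, replace=False)
    r, c = rows[sel], cols[sel]
    raw = stack.values[r, c, :]
    feat_map = net.extract_features(
        stack.values.transpose(2, 0, 1)[None].astype(np.float32))[0]
    net_feats = feat_map[:, r, c].T
    y = labels[r, c]

    out = {"labels": y}
    for name, X in (("raw", raw), ("net", net_feats)):
        perp = min(30.0, max(2.0, len(X) / 4))
        xy = TSNE(n_components=2, random_state=seed, init="random",
                  perplexity=perp).fit_transform(X.astype(np.float64))
        out[f"{name}_xy"] = xy
        out[f"{name}_silhouette"] = (
            float(silhouette_score(X.astype(np.float64), y))
            if len(np.unique(y)) > 1 else float("nan"))
    return out


# ---------------------------------------------------------------------------
# Region prediction and cross-domain transfer
# ---------------------------------------------------------------------------

def predict_region(net: AttentionSegNet, stack: FeatureStack,
                   region: tiling.Region, spec: tiling.TileSpec,
                   batch_size: int = 8) -> np.ndarray:
    """Tile the region (edge-ignoring grid), predict each tile and stitch the
    central windows back into one label raster of the region's shape."""
    tileset = tiling.tile_test_region(stack.values, region, spec)
    X, _ = tileset.arrays()
    preds = []
    for i in range(0, len(X), batch_size):
        preds.extend(net.predict(X[i:i + batch_size]))
    return tiling.stitch_predictions(preds, tileset)


def cross_domain_eval(net: AttentionSegNet, train_stats: NormStats,
                      scene: MultispectralScene, labels: np.ndarray,
                      region: tiling.Region, spec: tiling.TileSpec,
                      index_choice: str = "rededge",
                      batch_size: int = 8) -> MetricsReport:
    """Evaluate a trained model on another domain's scene: build features,
    normalize with the *training* domain statistics, predict and score."""
    stack = normalize_stack(build_feature_stack(scene, index_choice), train_stats)
    pred = predict_region(net, stack, region, spec, batch_size)
    truth = np.asarray(labels)[region.r0:region.r1, region.c0:region.c1]
    return metrics_report(pred, truth, k=net.cfg.num_classes)


def transfer_matrix(models: dict, stats: dict, scenes: dict, labels: dict,
                    regions: dict, spec: tiling.TileSpec,
                    index_choice: str = "rededge") -> dict:
    """Full pairwise A->B evaluation: models[a] applied to domain b's test
    region with domain a's normalization statistics."""
    out = {}
    for a, net in models.items():
        for b in scenes:
            rep = cross_domain_eval(net, stats[a], scenes[b], labels[b],
                                    regions[b], spec, index_choice)
            out[(a, b)] = rep
    return out
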