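"""Derived-feature construction: vegetation indices and the 8-channel
network input stack (6 raw bands + NDVI + a red-edge index), plus
per-channel z-score normalization with reusable statistics.

Channel order of the stack is fixed:
(B02, B03, B04, B05, B06, B08, NDVI, red-edge index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .synthgen import MultispectralScene

STACK_CHANNELS = ("B02", "B03", "B04", "B05", "B06", "B08", "NDVI", "INDEX")
INDEX_CHOICES = ("rededge", "evi")


class IndexRaster(NamedTuple):
    """A single-channel index raster plus a mask of zero-denominator pixels."""

    values: np.ndarray
    invalid: np.ndarray


@dataclass
class NormStats:
    mean: np.ndarray  # (8,)
    sd: np.ndarray    # (8,)

    def to_dict(self):
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(mean=np.asarray(d["mean"], dtype=np.float64),
                   sd=np.asarray(d["sd"], dtype=np.float64))


@dataclass
class FeatureStack:
    """Rank-3 array rows x cols x 8 ready for the network."""

    values: np.ndarray
    channel_names: tuple = STACK_CHANNELS
    invalid: np.ndarray | None = None  # zero-denominator flags from the indices
    stats: NormStats | None = None     # set once normalized

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[2] != 8:
            raise ValueError("feature stack must have exactly 8 channels")
        if not np.isfinite(self.values).all():
            raise ValueError("feature stack contains non-finite values")

    @property
    def shape(self):
        return self.values.shape[:2]


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> IndexRaster:
    invalid = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(invalid, 0.0, num / np.where(invalid, 1.0, den))
    return IndexRaster(vals.astype(np.float32), invalid)


def compute_ndvi(scene: MultispectralScene) -> IndexRaster:
    """NDVI = (NIR - R) / (NIR + R) with NIR = band 8, R = band 4.

    Zero-denominator pixels yield 0 and are flagged in the invalid mask.
    """
    nir = scene.band("B08").astype(np.float64)
    red = scene.band("B04").astype(np.float64)
    return _safe_ratio(nir - red, nir + red)


def compute_rededge_index(scene: MultispectralScene) -> IndexRaster:
    """Red-edge normalized-difference index (B06 - B05) / (B06 + B05),
    i.e. the 740 nm / 705 nm red-edge NDVI."""
    b6 = scene.band("B06").astype(np.float64)
    b5 = scene.band("B05").astype(np.float64)
    return _safe_ratio(b6 - b5, b6 + b5)


def compute_evi(scene: MultispectralScene) -> IndexRaster:
    """EVI = 2.5 * (NIR - R) / (NIR + 6R - 7.5B + 1) with B = band 2."""
    nir = scene.band("B08").astype(np.float64)
    red = scene.band("B04").astype(np.float64)
    blue = scene.band("B02").astype(np.float64)
    return _safe_ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0)


def build_feature_stack(scene: MultispectralScene,
                        index_choice: str = "rededge") -> FeatureStack:
    """Stack the 6 raw bands plus NDVI and the chosen eighth index channel."""
    if index_choice not in INDEX_CHOICES:
        raise ValueError(f"index_choice must be one of {INDEX_CHOICES}")
    if scene.values.shape[2] != 6:
        raise ValueError(f"expected 6 raw bands, got {scene.values.shape[2]}")
    ndvi = compute_ndvi(scene)
    eighth = compute_rededge_index(scene) if index_choice == "rededge" else compute_evi(scene)
    values = np.dstack([scene.values,
                        ndvi.values[:, :, None],
                        eighth.values[:, :, None]])
    return FeatureStack(values=values, invalid=ndvi.invalid | eighth.invalid)


def normalize_stack(stack: FeatureStack, stats: NormStats | None = None) -> FeatureStack:
    """Per-channel z-score.  When `stats` is omitted they are computed from
    this stack and returned on the result, so a test split can reuse the
    training statistics."""
    if stats is None:
        mean = stack.values.reshape(-1, 8).mean(axis=0).astype(np.float64)
        sd = stack.values.reshape(-1, 8).std(axis=0).astype(np.float64)
        zero_var = sd == 0
        if zero_var.any():
            warnings.warn("zero-variance channel(s); using unit divisor",
                          RuntimeWarning, stacklevel=2)
            sd = np.where(zero_var, 1.0, sd)
        stats = NormStats(mean=mean, sd=sd)
    normed = (stack.values - stats.mean[None, None, :]) / stats.sd[None, None, :]
    return FeatureStack(values=normed.astype(np.float32),
                        channel_names=stack.channel_names,
                        invalid=stack.invalid, stats=stats)


def resample_nearest(raster: np.ndarray, factor: int) -> np.ndarray:
    """Convenience integer-factor nearest resampler (no reprojection)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.repeat(np.repeat(raster, factor, axis=0), factor, axis=1)
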