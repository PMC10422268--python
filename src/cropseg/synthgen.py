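"""Synthetic multispectral field mosaics with corn / soybean / other plots.

A scene is a rectangular partition of contiguous single-class plots
(split-and-merge of the full raster), rendered to 6-band reflectance from a
per-class spectral library with Gaussian within-field noise, box-averaged
mixed pixels along plot boundaries, and optional per-band gain/offset shifts
that emulate acquisition differences between years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

BAND_IDS = ("B02", "B03", "B04", "B05", "B06", "B08")
CLASS_NAMES = ("other", "corn", "soybean")
N_BANDS = 6
N_CLASSES = 3


class ConfigurationError(ValueError):
    pass


@dataclass
class MultispectralScene:
    """Rank-3 reflectance raster (rows x cols x bands) with band metadata."""

    values: np.ndarray
    band_ids: tuple = BAND_IDS
    mask: np.ndarray | None = None  # True where nodata

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ConfigurationError("scene values must be rows x cols x bands")
        if self.values.shape[2] != len(self.band_ids):
            raise ConfigurationError("band count does not match band_ids")

    @property
    def shape(self):
        return self.values.shape[:2]

    def band(self, band_id: str) -> np.ndarray:
        try:
            idx = self.band_ids.index(band_id)
        except ValueError:
            raise KeyError(f"band {band_id!r} not present; have {self.band_ids}")
        return self.values[:, :, idx]


@dataclass
class SpectralLibrary:
    """Per-class mean reflectance and band-wise noise sd over the 6 raw bands."""

    means: np.ndarray   # (n_classes, 6), reflectance in [0, 1]
    noise_sd: np.ndarray  # (n_classes, 6), >= 0
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=np.float64)
        self.noise_sd = np.asarray(self.noise_sd, dtype=np.float64)
        if self.means.shape != (len(self.class_names), N_BANDS):
            raise ConfigurationError("means must be (n_classes, 6)")
        if self.noise_sd.shape != self.means.shape:
            raise ConfigurationError("noise_sd must match means shape")
        if self.means.min() < 0 or self.means.max() > 1:
            raise ConfigurationError("means must lie in [0, 1]")
        if self.noise_sd.min() < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if len(self.class_names) < N_CLASSES:
            raise ConfigurationError("library must cover other/corn/soybean")


def default_library(noise_sd: float = 0.01) -> SpectralLibrary:
    """Fixture spectra: both crops high-NIR, separated mainly in the
    red-edge/NIR bands; 'other' spectrally flat with low NIR."""
    means = np.array([
        # B02    B03    B04    B05    B06    B08
        [0.110, 0.130, 0.155, 0.180, 0.200, 0.220],   # other (soil/urban)
        [0.040, 0.080, 0.055, 0.200, 0.350, 0.450],   # corn
        [0.045, 0.090, 0.045, 0.280, 0.430, 0.530],   # soybean
    ])
    sd = np.full_like(means, noise_sd)
    return SpectralLibrary(means=means, noise_sd=sd)


@dataclass
class MosaicConfig:
    height: int = 512
    width: int = 512
    plot_size_range: tuple = (40, 80)   # min/max plot side, pixels
    class_priors: tuple = (0.2, 0.4, 0.4)  # other, corn, soybean
    mix_width: int = 1
    seed: int = 0

    def validate(self):
        if self.height < 256 or self.width < 256:
            raise ConfigurationError("scene must be at least 256x256")
        lo, hi = self.plot_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid plot size range")
        if hi < 2 * lo - 1:
            raise ConfigurationError(
                "plot_size_range too narrow: need max >= 2*min - 1 so every "
                "oversized rectangle admits a valid split")
        priors = np.asarray(self.class_priors, dtype=np.float64)
        if priors.shape != (N_CLASSES,) or priors.min() < 0 or abs(priors.sum() - 1) > 1e-9:
            raise ConfigurationError("class priors must be 3 nonnegative values summing to 1")
        if self.mix_width < 0:
            raise ConfigurationError("mix width must be >= 0")


@dataclass
class YearShift:
    """Per-band multiplicative gain and additive offset (reflectance units)."""

    gains: np.ndarray = field(default_factory=lambda: np.ones(N_BANDS))
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(N_BANDS))

    def __post_init__(self):
        self.gains = np.broadcast_to(np.asarray(self.gains, dtype=np.float64), (N_BANDS,)).copy()
        self.offsets = np.broadcast_to(np.asarray(self.offsets, dtype=np.float64), (N_BANDS,)).copy()
        if self.gains.min() <= 0:
            raise ConfigurationError("gains must be > 0")


def _split_rects(height: int, width: int, lo: int, hi: int,
                 rng: np.random.Generator) -> list[tuple[int, int, int, int]]:
    """Recursively split the raster into rectangles with sides in [lo, hi]
    (sides may fall below lo only if the full raster itself is smaller)."""
    out = []
    stack = [(0, 0, height, width)]
    while stack:
        r0, c0, h, w = stack.pop()
        if h <= hi and w <= hi:
            out.append((r0, c0, h, w))
            continue
        # split the longer oversized side
        if h >= w:
            cut = int(rng.integers(lo, h - lo + 1))
            stack.append((r0, c0, cut, w))
            stack.append((r0 + cut, c0, h - cut, w))
        else:
            cut = int(rng.integers(lo, w - lo + 1))
            stack.append((r0, c0, h, cut))
            stack.append((r0, c0 + cut, h, w - cut))
    return out


def generate_field_mosaic(cfg: MosaicConfig) -> np.ndarray:
    """Partition the raster into contiguous single-class plots.

    Returns an int8 label raster with classes {0=other, 1=corn, 2=soybean}.
    Deterministic for a fixed config seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.plot_size_range
    rects = _split_rects(cfg.height, cfg.width, lo, hi, rng)
    labels = np.empty((cfg.height, cfg.width), dtype=np.int8)
    classes = rng.choice(N_CLASSES, size=len(rects), p=np.asarray(cfg.class_priors))
    for (r0, c0, h, w), cls in zip(rects, classes):
        labels[r0:r0 + h, c0:c0 + w] = cls
    return labels


def boundary_mask(labels: np.ndarray, width: int) -> np.ndarray:
    """True for pixels within `width` (Chebyshev distance) of a different class."""
    if width <= 0:
        return np.zeros(labels.shape, dtype=bool)
    size = 2 * width + 1
    lo = ndimage.minimum_filter(labels, size=size, mode="nearest")
    hi = ndimage.maximum_filter(labels, size=size, mode="nearest")
    return lo != hi


def render_reflectance(labels: np.ndarray, lib: SpectralLibrary, seed: int = 0,
                       mix_width: int = 1) -> MultispectralScene:
    """Render a label raster to 6-band reflectance.

    Each pixel draws class mean + Gaussian band noise; pixels within
    `mix_width` of a plot boundary are then replaced by their 3x3 box
    average (mixed pixels).  Values are clipped to [0, 1].
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if present.min() < 0 or present.max() >= len(lib.class_names):
        raise ConfigurationError(
            f"labels contain classes {present.tolist()} not covered by the library")
    rng = np.random.default_rng(seed)
    base = lib.means[labels] + rng.standard_normal(labels.shape + (N_BANDS,)) * lib.noise_sd[labels]
    base = base.astype(np.float32)
    if mix_width > 0:
        mixed = np.empty_like(base)
        for b in range(N_BANDS):
            mixed[:, :, b] = ndimage.uniform_filter(base[:, :, b], size=3, mode="nearest")
        bmask = boundary_mask(labels, mix_width)
        base = np.where(bmask[:, :, None], mixed, base)
    return MultispectralScene(values=np.clip(base, 0.0, 1.0))


def simulate_year_shift(scene: MultispectralScene, shift: YearShift) -> MultispectralScene:
    """Apply clip(gain_b * value + offset_b, 0, 1) band-wise; labels unchanged."""
    shifted = scene.values * shift.gains[None, None, :] + shift.offsets[None, None, :]
    return MultispectralScene(values=np.clip(shifted, 0.0, 1.0).astype(np.float32),
                              band_ids=scene.band_ids, mask=scene.mask)
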