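"""Spatial train/test split, random training-crop sampling and the
edge-ignoring test-tile grid with its prediction stitcher.

Test tiles overlap by twice the edge margin m: tiles are laid with stride
(size - 2m) and, after prediction, only each tile's central window is kept;
windows abutting the region border are extended to the border so the region
is covered by exactly one retained window per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class Region(NamedTuple):
    """Half-open rectangle [r0, r1) x [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    @property
    def height(self):
        return self.r1 - self.r0

    @property
    def width(self):
        return self.c1 - self.c0

    @property
    def area(self):
        return self.height * self.width


@dataclass
class TileSpec:
    size: int = 256
    margin: int = 32          # ignored edge width m for test tiles
    count: int = 800          # random crops per scene
    train_count: int = 600
    val_count: int = 200
    split_ratio: float = 0.6  # training share of the scene
    seed: int = 0

    def validate(self, for_test: bool = False):
        if self.size <= 0:
            raise ValueError("tile size must be positive")
        if for_test and not (0 < 2 * self.margin < self.size):
            raise ValueError("test tiles require 0 < 2*margin < size")
        if self.train_count + self.val_count != self.count:
            raise ValueError("count must equal train_count + val_count")


class Tile(NamedTuple):
    features: np.ndarray  # (size, size, C)
    labels: np.ndarray | None  # (size, size) or None for unlabeled test tiles
    row: int  # origin in scene coordinates
    col: int
    role: str  # train | val | test


@dataclass
class TileSet:
    tiles: list
    spec: TileSpec
    region: Region

    def __len__(self):
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def subset(self, role: str) -> "TileSet":
        return TileSet([t for t in self.tiles if t.role == role], self.spec, self.region)

    def arrays(self, role: str | None = None):
        """Return (X, y) with X in NCHW float32 and y int64, ready for the
        network; y is None if any selected tile is unlabeled."""
        tiles = [t for t in self.tiles if role is None or t.role == role]
        if not tiles:
            raise ValueError(f"no tiles with role {role!r}")
        X = np.stack([t.features.transpose(2, 0, 1) for t in tiles]).astype(np.float32)
        if any(t.labels is None for t in tiles):
            return X, None
        y = np.stack([t.labels for t in tiles]).astype(np.int64)
        return X, y


def split_train_test(scene_shape, ratio: float = 0.6, axis: int = 0):
    """Split the scene into two disjoint rectangles covering it, with the
    first (training) region taking `ratio` of the chosen axis."""
    h, w = scene_shape[:2]
    if h <= 1 or w <= 1:
        raise ValueError("degenerate scene")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if axis == 0:
        cut = int(round(h * ratio))
        return Region(0, cut, 0, w), Region(cut, h, 0, w)
    elif axis == 1:
        cut = int(round(w * ratio))
        return Region(0, h, 0, cut), Region(0, h, cut, w)
    raise ValueError("axis must be 0 (rows) or 1 (cols)")


def sample_training_tiles(features: np.ndarray, labels: np.ndarray,
                          region: Region, spec: TileSpec) -> TileSet:
    """Random (possibly overlapping) crops fully inside `region`, partitioned
    into train/val counts; deterministic for a fixed spec seed."""
    spec.validate()
    s = spec.size
    if region.height < s or region.width < s:
        raise ValueError("region smaller than tile size")
    rng = np.random.default_rng(spec.seed)
    rows = rng.integers(region.r0, region.r1 - s + 1, size=spec.count)
    cols = rng.integers(region.c0, region.c1 - s + 1, size=spec.count)
    tiles = []
    for i, (r, c) in enumerate(zip(rows, cols)):
        role = "train" if i < spec.train_count else "val"
        tiles.append(Tile(features[r:r + s, c:c + s], labels[r:r + s, c:c + s],
                          int(r), int(c), role))
    return TileSet(tiles, spec, region)


def _grid_origins(start: int, stop: int, size: int, stride: int) -> list[int]:
    n = max(1, int(np.ceil((stop - start - size) / stride)) + 1)
    return [min(start + i * stride, stop - size) for i in range(n)]


def _retained_intervals(origins, start, stop, size, m):
    """Half-open retained (central-window) interval per tile along one axis;
    first/last extend to the region border, and shifted final origins clip
    against the previous interval so the intervals partition [start, stop)."""
    out = []
    prev_end = start
    for i, o in enumerate(origins):
        a = prev_end
        b = stop if i == len(origins) - 1 else o + size - m
        out.append((a, b))
        prev_end = b
    return out


def tile_test_region(features: np.ndarray, region: Region, spec: TileSpec,
                     labels: np.ndarray | None = None) -> TileSet:
    """Lay test tiles on a stride (size - 2*margin) grid covering the region,
    shifting border tiles inward so no tile pads beyond the raster."""
    spec.validate(for_test=True)
    s = spec.size
    if region.height < s or region.width < s:
        raise ValueError("region smaller than tile size")
    stride = s - 2 * spec.margin
    row_origins = _grid_origins(region.r0, region.r1, s, stride)
    col_origins = _grid_origins(region.c0, region.c1, s, stride)
    tiles = []
    for r in row_origins:
        for c in col_origins:
            lab = labels[r:r + s, c:c + s] if labels is not None else None
            tiles.append(Tile(features[r:r + s, c:c + s], lab, int(r), int(c), "test"))
    return TileSet(tiles, spec, region)


def stitch_predictions(predictions, tileset: TileSet) -> np.ndarray:
    """Assemble per-tile class maps back into a single label raster for the
    tiled region, keeping only each tile's retained central window.

    `predictions` is a sequence of (size, size) class rasters in the same
    order as the tileset's tiles.  Returns an array of the region's shape.
    """
    region, spec = tileset.region, tileset.spec
    s, m = spec.size, spec.margin
    stride = s - 2 * m
    row_origins = _grid_origins(region.r0, region.r1, s, stride)
    col_origins = _grid_origins(region.c0, region.c1, s, stride)
    row_keep = _retained_intervals(row_origins, region.r0, region.r1, s, m)
    col_keep = _retained_intervals(col_origins, region.c0, region.c1, s, m)
    predictions = list(predictions)
    if len(predictions) != len(row_origins) * len(col_origins):
        raise ValueError(f"expected {len(row_origins) * len(col_origins)} "
                         f"prediction tiles, got {len(predictions)}")
    first = np.asarray(predictions[0])
    out = np.zeros((region.height, region.width), dtype=first.dtype)
    idx = 0
    for ro, (ra, rb) in zip(row_origins, row_keep):
        for co, (ca, cb) in zip(col_origins, col_keep):
            pred = np.asarray(predictions[idx])
            if pred.shape != (s, s):
                raise ValueError(f"prediction tile {idx} has shape {pred.shape}")
            out[ra - region.r0:rb - region.r0, ca - region.c0:cb - region.c0] = \
                pred[ra - ro:rb - ro, ca - co:cb - co]
            idx += 1
    return out


def retained_window_coverage(tileset: TileSet) -> np.ndarray:
    """Count, per region pixel, how many retained central windows own it.
    Coverage must be exactly 1 everywhere (test/diagnostic helper)."""
    region, spec = tileset.region, tileset.spec
    s, m = spec.size, spec.margin
    stride = s - 2 * m
    row_origins = _grid_origins(region.r0, region.r1, s, stride)
    col_origins = _grid_origins(region.c0, region.c1, s, stride)
    row_keep = _retained_intervals(row_origins, region.r0, region.r1, s, m)
    col_keep = _retained_intervals(col_origins, region.c0, region.c1, s, m)
    cov = np.zeros((region.height, region.width), dtype=np.int32)
    for ra, rb in row_keep:
        for ca, cb in col_keep:
            cov[ra - region.r0:rb - region.r0, ca - region.c0:cb - region.c0] += 1
    return cov
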