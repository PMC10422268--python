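"""Reading/writing scenes, label rasters, feature stacks and sidecar JSON.

Multi-band rasters go to TIFF (via tifffile) or .npy depending on the file
extension; labels additionally support PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .features import FeatureStack, NormStats
from .synthgen import BAND_IDS, MultispectralScene


def save_raster(arr: np.ndarray, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, arr)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, arr)
    elif path.suffix == ".png":
        import imageio.v3 as iio
        iio.imwrite(path, np.asarray(arr, dtype=np.uint8))
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")


def load_raster(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path)
    if path.suffix == ".png":
        import imageio.v3 as iio
        return np.asarray(iio.imread(path))
    raise ValueError(f"unsupported raster format: {path.suffix}")


def save_scene(scene: MultispectralScene, path, sidecar: dict | None = None):
    save_raster(scene.values, path)
    if sidecar is not None:
        meta = dict(sidecar)
        meta["band_ids"] = list(scene.band_ids)
        save_json(meta, Path(path).with_suffix(".json"))


def load_scene(path) -> MultispectralScene:
    arr = load_raster(path)
    meta_path = Path(path).with_suffix(".json")
    band_ids = BAND_IDS
    if meta_path.exists():
        band_ids = tuple(load_json(meta_path).get("band_ids", BAND_IDS))
    return MultispectralScene(values=arr, band_ids=band_ids)


def save_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2))


def load_json(path):
    return json.loads(Path(path).read_text())


def save_stats(stats: NormStats, path):
    save_json(stats.to_dict(), path)


def load_stats(path) -> NormStats:
    return NormStats.from_dict(load_json(path))


def save_stack(stack: FeatureStack, path):
    save_raster(stack.values, path)


def save_tileset(tileset, outdir):
    """Persist a TileSet as .npy pairs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"size": tileset.spec.size, "margin": tileset.spec.margin,
                "seed": tileset.spec.seed,
                "region": list(tileset.region), "tiles": []}
    for i, t in enumerate(tileset.tiles):
        np.save(outdir / f"tile_{i:05d}_x.npy", t.features)
        if t.labels is not None:
            np.save(outdir / f"tile_{i:05d}_y.npy", t.labels)
        manifest["tiles"].append({"row": t.row, "col": t.col, "role": t.role,
                                  "labeled": t.labels is not None})
    save_json(manifest, outdir / "manifest.json")


def load_tileset(outdir):
    from .tiling import Region, Tile, TileSet, TileSpec

    outdir = Path(outdir)
    manifest = load_json(outdir / "manifest.json")
    spec = TileSpec(size=manifest["size"], margin=manifest["margin"],
                    seed=manifest["seed"])
    tiles = []
    for i, entry in enumerate(manifest["tiles"]):
        feats = np.load(outdir / f"tile_{i:05d}_x.npy")
        labs = np.load(outdir / f"tile_{i:05d}_y.npy") if entry["labeled"] else None
        tiles.append(Tile(feats, labs, entry["row"], entry["col"], entry["role"]))
    spec.count = len(tiles)
    spec.train_count = sum(1 for t in tiles if t.role == "train")
    spec.val_count = sum(1 for t in tiles if t.role == "val")
    return TileSet(tiles, spec, Region(*manifest["region"]))
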