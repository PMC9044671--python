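"""Image/mask I/O, tile-grid planning, cropping, and dataset splitting.

Large UAV frames are cropped into fixed-size training tiles before
segmentation.  Coordinates are 0-based with the origin at the top-left
corner; an origin ``(x, y)`` means column ``x``, row ``y``, and a tile
occupies ``[y, y+tile_size) x [x, x+tile_size)``.

Three grid policies are provided:

``exact``
    non-overlapping tiles; requires the tile size to divide both extents.
``full-cover`` (default)
    the minimal number of evenly spaced, possibly overlapping origins per
    axis such that every pixel is covered.
``fixed-grid``
    a requested ``n_cols x n_rows`` lattice of evenly spaced origins; use
    20 x 10 to obtain 200 tiles from a 5472 x 3078 frame.

Masks are stored on disk as single-channel PNGs with values {0, 255}
(255 = cotton boll) and held in memory as {0, 1} arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import LabeledTile

__all__ = [
    "TileGrid",
    "DatasetSplit",
    "plan_grid",
    "crop_tiles",
    "split_dataset",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_polygons",
    "rasterize_polygons",
    "write_dataset",
    "read_manifest",
]


@dataclass(frozen=True)
class TileGrid:
    tile_size: int
    n_cols: int
    n_rows: int
    origins: tuple[tuple[int, int], ...]  # (x, y) top-left corners
    width: int
    height: int

    def __post_init__(self) -> None:
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("grid origins are not unique")
        for x, y in self.origins:
            if x < 0 or y < 0 or x + self.tile_size > self.width or y + self.tile_size > self.height:
                raise ValueError(f"origin ({x}, {y}) puts a tile out of bounds")


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    test: tuple
    fraction: float
    seed: int


def _axis_origins(extent: int, tile_size: int, n: int) -> list[int]:
    """n evenly spaced origins from 0 to extent - tile_size inclusive."""
    if n == 1:
        return [0]
    pos = np.linspace(0, extent - tile_size, n)
    return [int(round(p)) for p in pos]


def plan_grid(
    width: int,
    height: int,
    tile_size: int,
    policy: str = "full-cover",
    n_cols: int | None = None,
    n_rows: int | None = None,
) -> TileGrid:
    """Plan tile origins over a ``width x height`` frame."""
    if tile_size <= 0 or tile_size > min(width, height):
        raise ValueError(f"tile_size must be in (0, min(W, H)={min(width, height)}]")
    if policy == "exact":
        if width % tile_size or height % tile_size:
            raise ValueError(
                f"exact policy requires tile_size {tile_size} to divide both "
                f"extents ({width} x {height})"
            )
        nc, nr = width // tile_size, height // tile_size
        xs = [i * tile_size for i in range(nc)]
        ys = [j * tile_size for j in range(nr)]
    elif policy == "full-cover":
        nc = math.ceil(width / tile_size)
        nr = math.ceil(height / tile_size)
        xs = _axis_origins(width, tile_size, nc)
        ys = _axis_origins(height, tile_size, nr)
    elif policy == "fixed-grid":
        if n_cols is None or n_rows is None:
            raise ValueError("fixed-grid policy requires n_cols and n_rows")
        nc, nr = n_cols, n_rows
        xs = _axis_origins(width, tile_size, nc)
        ys = _axis_origins(height, tile_size, nr)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    origins = tuple((x, y) for y in ys for x in xs)
    return TileGrid(tile_size=tile_size, n_cols=nc, n_rows=nr, origins=origins,
                    width=width, height=height)


def crop_tiles(image: np.ndarray, mask: np.ndarray, grid: TileGrid) -> list[LabeledTile]:
    """Cut a frame and its mask into labeled tiles along a planned grid."""
    h, w = mask.shape
    if image.shape[:2] != (h, w):
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} sizes differ")
    if (w, h) != (grid.width, grid.height):
        raise ValueError(
            f"frame size {(w, h)} does not match grid size {(grid.width, grid.height)}"
        )
    ts = grid.tile_size
    tiles = []
    for x, y in grid.origins:
        sub_img = image[y : y + ts, x : x + ts].copy()
        sub_mask = mask[y : y + ts, x : x + ts].copy()
        tiles.append(
            LabeledTile(image=sub_img, mask=sub_mask, true_ratio=float(sub_mask.mean()))
        )
    return tiles


def split_dataset(tiles: Sequence, fraction: float, seed: int) -> DatasetSplit:
    """Random disjoint train/test split; |train| = round(fraction * total)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if len(tiles) == 0:
        raise ValueError("cannot split an empty tile list")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tiles))
    # round-half-up so 0.8 * total behaves like the usual 80/20 bookkeeping
    n_train = int(math.floor(fraction * len(tiles) + 0.5))
    train = tuple(tiles[i] for i in order[:n_train])
    test = tuple(tiles[i] for i in order[n_train:])
    return DatasetSplit(train=train, test=test, fraction=fraction, seed=seed)


def read_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a {0, 255} single-channel PNG as a {0, 1} uint8 array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(f"mask {path} is not binary; offending values: {bad.tolist()}")
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    bad = np.setdiff1d(np.unique(mask), [0, 1])
    if bad.size:
        raise ValueError(f"in-memory mask is not binary; offending values: {bad.tolist()}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def read_polygons(path: str | Path) -> list[dict]:
    """Read a minimal polygon-annotation JSON.

    Format: a list of objects ``{"label": str, "points": [[x, y], ...]}``
    where points trace one ring in pixel coordinates.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError("polygon JSON must be a list of {label, points} objects")
    return data


def rasterize_polygons(
    polygons: Sequence[dict], shape: tuple[int, int], label: str = "cotton"
) -> np.ndarray:
    """Rasterize labelled rings into a binary mask, even-odd rule.

    A pixel (row, col) is foreground when its centre (x=col, y=row) lies
    inside an odd number of rings carrying ``label``.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    px, py = xx.ravel().astype(float), yy.ravel().astype(float)
    for poly in polygons:
        if poly.get("label") != label:
            continue
        pts = np.asarray(poly["points"], dtype=float)
        if pts.shape[0] < 3:
            continue
        inside = np.zeros(px.shape, dtype=bool)
        x0, y0 = pts[-1]
        for x1, y1 in pts:  # crossing-number test, vectorized over pixels
            crosses = (y0 <= py) != (y1 <= py)
            with np.errstate(divide="ignore", invalid="ignore"):
                xcross = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            inside ^= crosses & (px < xcross)
            x0, y0 = x1, y1
        mask.ravel()[inside] ^= 1  # even-odd across rings
    return mask


def write_dataset(
    tiles: Sequence[LabeledTile],
    out_dir: str | Path,
    yields_g: Sequence[float] | None = None,
    prefix: str = "tile",
) -> pd.DataFrame:
    """Write tiles as PNG pairs plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tile in enumerate(tiles):
        img_path = out / f"{prefix}_{i:05d}.png"
        mask_path = out / f"{prefix}_{i:05d}_mask.png"
        write_image(tile.image, img_path)
        write_mask(tile.mask, mask_path)
        row = {
            "tile_path": img_path.name,
            "mask_path": mask_path.name,
            "true_ratio": tile.true_ratio,
        }
        if yields_g is not None:
            row["yield_g"] = float(yields_g[i])
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> list[LabeledTile]:
    """Load tiles listed in a manifest CSV (paths relative to the CSV)."""
    path = Path(path)
    df = pd.read_csv(path)
    tiles = []
    for _, row in df.iterrows():
        img = read_image(path.parent / row["tile_path"])
        mask = read_mask(path.parent / row["mask_path"])
        tiles.append(LabeledTile(image=img, mask=mask, true_ratio=float(mask.mean())))
    return tiles
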