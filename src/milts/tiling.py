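"""Slide rasters, tissue masking, tile extraction and stochastic augmentation.

A slide is handled as a plain H x W x 3 8-bit raster with a known
microns-per-pixel (mpp).  Tissue is segmented by hysteresis thresholding of
the HSV saturation channel of a downsampled thumbnail: stained tissue is
strongly saturated against the unstained white background, regardless of
the exact stain hue.  Tiles are cut on a non-overlapping grid anchored at
(0, 0) with half-open extents [x, x+side) x [y, y+side).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import transform as sktransform

from .errors import MiltsInputError

TILE_SIDE = 256
#: physical tile side in microns at 20x (0.5 um/px): 256 px * 0.5 um/px
TILE_MICRONS_AT_20X = TILE_SIDE * 0.5


@dataclasses.dataclass
class SlideImage:
    """An 8-bit RGB slide raster with its level-0 resolution."""

    slide_id: str
    pixels: np.ndarray
    mpp: float = 0.5

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise MiltsInputError(
                f"slide {self.slide_id!r}: expected an HxWx3 color raster, "
                f"got shape {self.pixels.shape}"
            )
        if self.mpp <= 0:
            raise MiltsInputError("mpp must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class TissueMask:
    """Binary tissue raster at ``downsample`` x reduction from level 0."""

    grid: np.ndarray
    downsample: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.downsample < 1:
            raise MiltsInputError("downsample must be a positive integer")


@dataclasses.dataclass
class Tile:
    """One fixed-size patch; (x, y) is its 0-based level-0 top-left corner."""

    slide_id: str
    x: int
    y: int
    patch: np.ndarray
    side_px: int = TILE_SIDE
    typicality: float | None = None
    tissue_fraction: float = 1.0


@dataclasses.dataclass
class AugmentParams:
    """Stochastic transform T: jitter half-widths, rotations, crop, flip.

    ``crop_scale_range`` is the linear side-fraction retained by the random
    crop before resizing back; (1, 1) disables cropping entirely so that the
    degenerate parameter set is an exact identity.
    """

    brightness: float = 0.25
    contrast: float = 0.25
    saturation: float = 0.25
    hue: float = 0.05
    rotation_set: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    crop_scale_range: tuple[float, float] = (0.8, 1.0)
    flip_enabled: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.crop_scale_range
        if not (0 < lo <= hi <= 1):
            raise MiltsInputError("crop_scale_range must satisfy 0 < lo <= hi <= 1")
        for name in ("brightness", "contrast", "saturation", "hue"):
            if getattr(self, name) < 0:
                raise MiltsInputError(f"{name} half-width must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(brightness=0, contrast=0, saturation=0, hue=0,
                   rotation_set=(0.0,), crop_scale_range=(1.0, 1.0),
                   flip_enabled=False)


def _block_reduce_mean(img: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool a 2-D or 3-D image by ``factor``, padding edges by replication."""
    h, w = img.shape[:2]
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        pad = [(0, ph), (0, pw)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad, mode="edge")
    hh, ww = img.shape[0] // factor, img.shape[1] // factor
    shaped = img.reshape(hh, factor, ww, factor, *img.shape[2:])
    return shaped.mean(axis=(1, 3))


def compute_tissue_mask(slide: SlideImage, low_thresh: float = 0.05,
                        high_thresh: float = 0.15, downsample: int = 32) -> TissueMask:
    """Segment stained tissue by hysteresis thresholding of HSV saturation.

    Pixels connected (8-connectivity) to a strongly saturated pixel
    (>= ``high_thresh``) through weakly saturated ones (>= ``low_thresh``)
    are tissue.
    """
    if not (0 <= low_thresh <= high_thresh <= 1):
        raise MiltsInputError("thresholds must satisfy 0 <= low <= high <= 1")
    thumb = _block_reduce_mean(slide.pixels.astype(np.float64) / 255.0, downsample)
    sat = skcolor.rgb2hsv(thumb)[:, :, 1]
    grid = skfilters.apply_hysteresis_threshold(sat, low_thresh, high_thresh)
    if not grid.any():
        warnings.warn(f"slide {slide.slide_id!r}: no tissue found (empty mask)",
                      stacklevel=2)
    return TissueMask(grid=grid, downsample=downsample)


def tile_tissue_fraction(mask: TissueMask, x: int, y: int, side_px: int) -> float:
    """Fraction of the tile footprint [x, x+side) x [y, y+side) that is tissue."""
    ds = mask.downsample
    sub = mask.grid[y // ds : -((y + side_px) // -ds),
                    x // ds : -((x + side_px) // -ds)]
    return float(sub.mean()) if sub.size else 0.0


def extract_tiles(slide: SlideImage, mask: TissueMask, side_px: int = TILE_SIDE,
                  min_tissue_fraction: float = 0.05) -> list[Tile]:
    """Cut the non-overlapping tile grid and keep sufficiently-tissue tiles."""
    if not (0 < min_tissue_fraction <= 1):
        raise MiltsInputError("min_tissue_fraction must be in (0, 1]")
    if slide.width_px < side_px or slide.height_px < side_px:
        warnings.warn(f"slide {slide.slide_id!r} smaller than one tile", stacklevel=2)
        return []
    tiles: list[Tile] = []
    for y in range(0, slide.height_px - side_px + 1, side_px):
        for x in range(0, slide.width_px - side_px + 1, side_px):
            frac = tile_tissue_fraction(mask, x, y, side_px)
            if frac >= min_tissue_fraction:
                patch = slide.pixels[y : y + side_px, x : x + side_px]
                tiles.append(Tile(slide.slide_id, x, y, patch, side_px,
                                  tissue_fraction=frac))
    return tiles


def _adjust_colors(img: np.ndarray, params: AugmentParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter on a float RGB image in [0,1]."""
    if params.brightness > 0:
        img = img * (1.0 + rng.uniform(-params.brightness, params.brightness))
    if params.contrast > 0:
        c = 1.0 + rng.uniform(-params.contrast, params.contrast)
        img = (img - img.mean()) * c + img.mean()
    img = np.clip(img, 0.0, 1.0)
    if params.saturation > 0 or params.hue > 0:
        hsv = skcolor.rgb2hsv(img)
        if params.saturation > 0:
            s = 1.0 + rng.uniform(-params.saturation, params.saturation)
            hsv[:, :, 1] = np.clip(hsv[:, :, 1] * s, 0.0, 1.0)
        if params.hue > 0:
            hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-params.hue, params.hue)) % 1.0
        img = skcolor.hsv2rgb(hsv)
    return np.clip(img, 0.0, 1.0)


def augment_array(img: np.ndarray, params: AugmentParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply T to a float RGB array in [0,1]; same rng state => same output."""
    side = img.shape[0]
    angle = float(rng.choice(np.asarray(params.rotation_set, dtype=float)))
    if angle % 360 != 0:
        if angle % 90 == 0:
            img = np.rot90(img, k=int(angle // 90) % 4)
        else:
            img = sktransform.rotate(img, angle, mode="reflect", order=1)
    if params.flip_enabled:
        if rng.random() < 0.5:
            img = img[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1, :]
    lo, hi = params.crop_scale_range
    if hi < 1 or lo < 1:
        scale = rng.uniform(lo, hi)
        crop = max(1, int(round(side * scale)))
        if crop < side:
            ox = rng.integers(0, side - crop + 1)
            oy = rng.integers(0, side - crop + 1)
            img = img[oy : oy + crop, ox : ox + crop]
            img = sktransform.resize(img, (side, side), order=1,
                                     anti_aliasing=False, preserve_range=True)
    return _adjust_colors(np.ascontiguousarray(img), params, rng)


def augment_tile(tile: Tile, params: AugmentParams,
                 rng: np.random.Generator) -> Tile:
    """Return a new tile whose patch is a stochastic transform of the input."""
    if tile.patch is None:
        raise MiltsInputError("tile has no pixel data")
    img = tile.patch.astype(np.float64) / 255.0
    out = augment_array(img, params, rng)
    patch = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return dataclasses.replace(tile, patch=patch)


def load_slide(path: str | Path, slide_id: str | None = None,
               mpp: float = 0.5) -> SlideImage:
    """Read a PNG/JPEG/TIFF raster into a SlideImage."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        import tifffile

        pixels = np.asarray(tifffile.imread(path))
    else:
        import imageio.v3 as iio

        pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    return SlideImage(slide_id or path.stem, pixels, mpp=mpp)


def write_tiles(tiles: list[Tile], out_dir: str | Path) -> Path:
    """Write tiles as PNGs plus a tile-index CSV; returns the index path."""
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tiles:
        name = f"{t.slide_id}_x{t.x}_y{t.y}.png"
        iio.imwrite(out_dir / name, t.patch)
        rows.append({"slide_id": t.slide_id, "x": t.x, "y": t.y,
                     "tissue_fraction": t.tissue_fraction})
    index = out_dir / "tile_index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index
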