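"""Synthetic slide cohorts with planted witness tiles.

The generator produces desk-scale stand-ins for stained whole-slide
images: a white background, an irregular pink/purple tissue region built
from smoothed random blobs, sparse light nuclei everywhere in the tissue,
and — on positive slides only — a contiguous block of tiles carrying a
dense dark-nucleus motif (the "witness" pattern).  The classic MIL bag
assumption holds by construction: a slide is positive iff it contains at
least one witness tile, and per-tile witness flags are recorded as ground
truth.  Expression values are drawn consistently with the slide label
around a fixed cutoff so that percentile dichotomization recovers the
planted labels.

All outputs are synthetic; filenames and ids carry a ``SYN`` marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw as skdraw
from skimage import transform as sktransform

from .errors import MiltsInputError
from .tiling import SlideImage, Tile

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticCohort",
           "generate_slide", "generate_expression", "generate_cohort"]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic cohort.

    Defaults give 1536 px slides (a 6x6 grid of 256 px tiles), roughly 70%
    tissue coverage and witness rates between 0.2 and 0.5 of the tissue
    tiles on positive slides.
    """

    n_patients: int = 20
    slides_per_patient: int = 1
    image_size: int = 1536
    tile_side: int = 256
    witness_rate_range: tuple[float, float] = (0.2, 0.5)
    tissue_coverage: float = 0.7
    base_color: tuple[int, int, int] = (232, 180, 214)
    nucleus_color: tuple[int, int, int] = (150, 105, 160)
    witness_color: tuple[int, int, int] = (62, 40, 105)
    nucleus_density: int = 14       # light nuclei per tissue tile
    witness_density: int = 85       # dark nuclei per witness tile
    expression_cutoff: float = 10.0
    mpp: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size % self.tile_side != 0:
            raise MiltsInputError("image_size must be a multiple of tile_side")
        lo, hi = self.witness_rate_range
        if not (0 < lo <= hi <= 1):
            raise MiltsInputError("witness_rate_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class GroundTruth:
    """Planted truth for one slide: per-tile flags and slide-level facts."""

    slide_id: str
    label: int
    witness_rate: float
    tiles: pd.DataFrame            # columns: x, y, is_tissue, witness
    tissue_mask: np.ndarray        # full-resolution boolean raster
    expression: float = float("nan")

    @property
    def witness_flags(self) -> np.ndarray:
        """Witness flags for tissue tiles, ordered like the tile grid."""
        t = self.tiles[self.tiles["is_tissue"]]
        return t["witness"].to_numpy(dtype=int)


@dataclass
class SyntheticCohort:
    spec: SyntheticSpec
    slides: list[SlideImage]
    truths: dict[str, GroundTruth]
    manifest: pd.DataFrame


def _tissue_blob_mask(size: int, coverage: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed low-resolution noise thresholded at the coverage quantile."""
    coarse = rng.normal(size=(12, 12))
    # center bias keeps the tissue blob away from the slide border
    yy, xx = np.mgrid[0:12, 0:12]
    dist = np.hypot(yy - 5.5, xx - 5.5) / 5.5
    coarse = coarse - 1.2 * dist
    smooth = sktransform.resize(coarse, (size, size), order=3, mode="reflect",
                                anti_aliasing=False)
    thresh = np.quantile(smooth, 1.0 - coverage)
    return smooth >= thresh


def _paint_nuclei(img: np.ndarray, region: np.ndarray, n: int,
                  color: tuple[int, int, int], radius: tuple[float, float],
                  rng: np.random.Generator) -> None:
    """Draw n randomly oriented dark ellipses at random points of ``region``."""
    ys, xs = np.nonzero(region)
    if ys.size == 0 or n <= 0:
        return
    picks = rng.integers(0, ys.size, size=n)
    for p in picks:
        r0 = rng.uniform(*radius)
        r1 = rng.uniform(*radius)
        rot = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(ys[p], xs[p], r0, r1, shape=img.shape[:2],
                                rotation=rot)
        shade = rng.uniform(0.85, 1.1)
        img[rr, cc] = [min(c * shade, 255.0) for c in color]


def generate_slide(label: int, witness_rate: float, spec: SyntheticSpec,
                   rng: np.random.Generator, slide_id: str = "SYN-S0"
                   ) -> tuple[SlideImage, GroundTruth]:
    """Render one synthetic slide and its planted ground truth."""
    if label not in (0, 1):
        raise MiltsInputError("label must be 0 or 1")
    if label == 1 and witness_rate <= 0:
        raise MiltsInputError("positive slides need witness_rate > 0")
    size, side = spec.image_size, spec.tile_side
    tissue = _tissue_blob_mask(size, spec.tissue_coverage, rng)

    img = np.full((size, size, 3), 255.0, dtype=np.float32)
    base = np.asarray(spec.base_color, dtype=np.float32)
    # low-frequency stain variation over the tissue
    texture = sktransform.resize(rng.normal(0, 1, (24, 24)).astype(np.float32),
                                 (size, size), order=1, anti_aliasing=False)
    tint = np.clip(1.0 + 0.05 * texture[tissue, None], 0.0, None)
    img[tissue] = np.minimum(base[None, :] * tint, 255.0)

    grid = size // side
    coords = [(x * side, y * side) for y in range(grid) for x in range(grid)]
    tissue_frac = {
        (x, y): tissue[y : y + side, x : x + side].mean() for x, y in coords
    }
    tissue_tiles = [c for c in coords if tissue_frac[c] >= 0.5]

    # background (light) nuclei across the whole tissue
    n_bg = spec.nucleus_density * max(len(tissue_tiles), 1)
    _paint_nuclei(img, tissue, n_bg, spec.nucleus_color, (3.0, 6.0), rng)

    witness_set: set[tuple[int, int]] = set()
    if label == 1 and tissue_tiles:
        n_wit = min(len(tissue_tiles),
                    max(1, int(round(witness_rate * len(tissue_tiles)))))
        witness_set = _grow_contiguous(tissue_tiles, n_wit, side, rng)
        for x, y in sorted(witness_set):
            # paint inside the tile's sub-view to keep drawing local
            sub_img = img[y : y + side, x : x + side]
            sub_tis = tissue[y : y + side, x : x + side]
            _paint_nuclei(sub_img, sub_tis, spec.witness_density,
                          spec.witness_color, (5.0, 10.0), rng)

    rows = [{"x": x, "y": y, "is_tissue": (x, y) in set(tissue_tiles),
             "witness": int((x, y) in witness_set)} for x, y in coords]
    truth = GroundTruth(
        slide_id=slide_id,
        label=label,
        witness_rate=(witness_rate if label == 1 else 0.0),
        tiles=pd.DataFrame(rows),
        tissue_mask=tissue,
    )
    slide = SlideImage(slide_id, np.clip(np.rint(img), 0, 255).astype(np.uint8),
                       mpp=spec.mpp)
    return slide, truth


def _grow_contiguous(tissue_tiles: list[tuple[int, int]], n: int, side: int,
                     rng: np.random.Generator) -> set[tuple[int, int]]:
    """Grow a connected set of n tiles over the tissue tile grid (4-adjacency)."""
    remaining = set(tissue_tiles)
    chosen: set[tuple[int, int]] = set()
    frontier: list[tuple[int, int]] = []
    while len(chosen) < n and remaining:
        if not frontier:
            seed = tuple(tissue_tiles[rng.integers(0, len(tissue_tiles))])
            while seed not in remaining:
                seed = tuple(tissue_tiles[rng.integers(0, len(tissue_tiles))])
            frontier = [seed]
        idx = rng.integers(0, len(frontier))
        tile = frontier.pop(idx)
        if tile not in remaining:
            continue
        remaining.discard(tile)
        chosen.add(tile)
        x, y = tile
        for nb in ((x + side, y), (x - side, y), (x, y + side), (x, y - side)):
            if nb in remaining:
                frontier.append(nb)
    return chosen


def generate_expression(label: int, cutoff: float,
                        rng: np.random.Generator) -> float:
    """Draw an expression value consistent with the slide label.

    Positive slides draw strictly above the cutoff (shifted lognormal),
    negative slides within [0, cutoff].
    """
    if cutoff <= 0:
        raise MiltsInputError("cutoff must be positive")
    if label == 1:
        return float(cutoff * (1.0 + rng.lognormal(mean=-0.7, sigma=0.6)))
    return float(cutoff * rng.beta(2.0, 2.0))


def generate_cohort(spec: SyntheticSpec, out_dir: str | Path | None = None
                    ) -> SyntheticCohort:
    """Generate a balanced cohort of slides, manifest and ground truth.

    Half the patients are positive; every slide of a patient shares the
    patient's label.  When ``out_dir`` is given, slide PNGs, the manifest
    CSV and the ground-truth CSV are also written there.
    """
    if spec.n_patients < 4:
        raise MiltsInputError("need at least 4 patients")
    rng = np.random.default_rng(spec.seed)
    n_pos = spec.n_patients // 2
    slides: list[SlideImage] = []
    truths: dict[str, GroundTruth] = {}
    rows = []
    for p in range(spec.n_patients):
        patient_id = f"SYN-P{p:03d}"
        label = int(p < n_pos)
        for s in range(spec.slides_per_patient):
            slide_id = f"{patient_id}-S{s}"
            rate = float(rng.uniform(*spec.witness_rate_range)) if label else 0.0
            slide, truth = generate_slide(label, rate, spec, rng, slide_id=slide_id)
            truth.expression = generate_expression(label, spec.expression_cutoff, rng)
            slides.append(slide)
            truths[slide_id] = truth
            rows.append({"slide_id": slide_id, "patient_id": patient_id,
                         "cancer_type": "SYN", "fpkm_uq": truth.expression,
                         "label": label})
    manifest = pd.DataFrame(rows)
    cohort = SyntheticCohort(spec=spec, slides=slides, truths=truths,
                             manifest=manifest)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    import imageio.v3 as iio

    slide_dir = out_dir / "slides"
    slide_dir.mkdir(parents=True, exist_ok=False)
    for slide in cohort.slides:
        iio.imwrite(slide_dir / f"{slide.slide_id}.png", slide.pixels)
    cohort.manifest.to_csv(out_dir / "manifest.csv", index=False)
    gt = pd.concat(
        [t.tiles.assign(slide_id=sid) for sid, t in cohort.truths.items()],
        ignore_index=True,
    )
    gt.to_csv(out_dir / "ground_truth.csv", index=False)


def cohort_tiles(cohort: SyntheticCohort, slide_id: str,
                 tissue_only: bool = True) -> list[Tile]:
    """Materialize the tile objects of one generated slide (views, no copy)."""
    slide = next(s for s in cohort.slides if s.slide_id == slide_id)
    truth = cohort.truths[slide_id]
    side = cohort.spec.tile_side
    rows = truth.tiles
    if tissue_only:
        rows = rows[rows["is_tissue"]]
    return [
        Tile(slide_id, int(r.x), int(r.y),
             slide.pixels[int(r.y): int(r.y) + side, int(r.x): int(r.x) + side],
             side)
        for r in rows.itertuples()
    ]
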