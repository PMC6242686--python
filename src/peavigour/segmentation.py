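"""Colour-rule segmentation of multi-view plant images and digital traits.

The imaging setup photographs each potted seedling from above (top view)
and from three sides at 0/120/240 degree rotations.  Plant tissue is green,
the wire support cage is blue and pot/background are near-white, so plant
pixels are recovered by a hue-saturation-value rule: keep pixels inside a
green hue window with sufficient saturation and brightness, and reject
pixels matching the blue cage rule.  Small connected components are then
discarded as noise.

From the four masks the standard digital vigour traits are computed, all
pixel-based (1 kPix = 1000 pixels):

EB
    estimated shoot biomass — sum of plant-pixel counts over the three
    side views plus the top view.
TVA
    top-view area — plant-pixel count of the top view.
TVCH
    top-view convex hull — rasterised filled convex hull of the top-view
    plant object.
TVCOM
    top-view compactness — TVA / TVCH, in (0, 1].
EH
    estimated plant height — maximum vertical pixel extent over the three
    side views.

Convex-hull convention: pixels are treated as unit squares; the hull is
taken over all pixel corner points and a grid cell belongs to the filled
hull when its centre lies inside or on the hull boundary.  This guarantees
the hull is a superset of the mask, hence TVCOM <= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import ConvexHull
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_objects

logger = logging.getLogger("peavigour.segmentation")

__all__ = [
    "ColourRule",
    "PlantMask",
    "MultiViewImageSet",
    "TraitRecord",
    "EmptyMaskError",
    "segment_plant",
    "denoise_mask",
    "convex_hull_area",
    "plant_height",
    "extract_traits",
]

SIDE_VIEWS = ("side0", "side120", "side240")
VIEWS = ("top",) + SIDE_VIEWS


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one plant pixel."""


@dataclass(frozen=True)
class ColourRule:
    """HSV windows separating plant tissue from cage and background.

    Hue is on the [0, 1) circle (green ~ 1/3, blue ~ 2/3).  A pixel is
    plant when it falls in the plant hue window with saturation and value
    above the minima, and does not satisfy the cage (blue) rule.  Defaults
    suit the green-plant / blue-cage / white-background palette of the
    synthetic scenes.
    """

    plant_hue: tuple[float, float] = (0.17, 0.50)
    plant_sat_min: float = 0.25
    plant_val_min: float = 0.10
    cage_hue: tuple[float, float] = (0.52, 0.80)
    cage_sat_min: float = 0.25


@dataclass
class PlantMask:
    """A binary plant mask for one view."""

    view: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class MultiViewImageSet:
    """One plant-day's top view plus three side views (8-bit RGB)."""

    plant_id: str
    genotype: str
    das: int
    top: np.ndarray
    sides: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.sides) != set(SIDE_VIEWS):
            raise ValueError(f"sides must be exactly {SIDE_VIEWS}, got {tuple(self.sides)}")
        for name, img in self.views().items():
            img = np.asarray(img)
            if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
                raise ValueError(f"view {name!r} must be a non-empty 3-channel raster")

    def views(self) -> dict[str, np.ndarray]:
        return {"top": self.top, **dict(self.sides)}


@dataclass
class TraitRecord:
    """Digital vigour traits for one plant on one day.

    Fields that cannot be computed (an empty mask in a required view) are
    NaN and the reason is recorded in ``flags`` — missing data is explicit,
    never a silent zero.
    """

    plant_id: str
    genotype: str
    das: int
    eb_kpix: float
    tva_kpix: float
    tvch_kpix: float
    tvcom: float
    eh_pix: float
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


def segment_plant(rgb: np.ndarray, rule: ColourRule = ColourRule(), view: str = "") -> PlantMask:
    """Segment plant pixels from an RGB raster by the HSV colour rule.

    An all-false mask is a legal result (logged, not raised): downstream
    trait extraction flags it.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    hsv = rgb2hsv(rgb)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    plant = (
        (h >= rule.plant_hue[0]) & (h <= rule.plant_hue[1])
        & (s >= rule.plant_sat_min) & (v >= rule.plant_val_min)
    )
    cage = (h >= rule.cage_hue[0]) & (h <= rule.cage_hue[1]) & (s >= rule.cage_sat_min)
    mask = plant & ~cage
    if not mask.any():
        logger.warning("segment_plant: empty mask in view %r", view)
    return PlantMask(view=view, mask=mask)


def denoise_mask(mask: PlantMask, min_size: int = 50) -> PlantMask:
    """Drop 8-connected components smaller than ``min_size`` pixels."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    # max_size removes components <= its value, so strictly-smaller-than
    # min_size maps to max_size = min_size - 1
    cleaned = remove_small_objects(mask.mask, max_size=min_size - 1, connectivity=2)
    return PlantMask(view=mask.view, mask=cleaned)


def _hull_fill(mask: np.ndarray) -> np.ndarray:
    """Rasterised filled convex hull of a boolean mask (corner-point hull)."""
    rows, cols = np.nonzero(mask)
    # corners of each true pixel's unit square
    pts = np.stack([rows, cols], axis=1).astype(float)
    corners = np.concatenate([pts + d for d in
                              ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))])
    hull = ConvexHull(corners)
    # half-plane representation: A @ p + b <= 0 inside
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    rr, cc = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    centres = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    inside = (centres @ a.T + b <= 1e-9).all(axis=1)
    return inside.reshape(mask.shape)


def convex_hull_area(mask: PlantMask) -> float:
    """Area of the rasterised filled convex hull of the mask, in kPix.

    Raises :class:`EmptyMaskError` when the mask has no plant pixel.
    """
    if not mask.mask.any():
        raise EmptyMaskError(f"no plant object in view {mask.view!r}")
    return _hull_fill(mask.mask).sum() / 1000.0


def plant_height(mask: PlantMask) -> int:
    """Vertical extent of the plant in pixels (inclusive row span).

    Rows are indexed from the image top; height is
    ``max_row - min_row + 1`` over the true pixels.
    """
    rows = np.nonzero(mask.mask.any(axis=1))[0]
    if len(rows) == 0:
        raise EmptyMaskError(f"no plant object in view {mask.view!r}")
    return int(rows[-1] - rows[0] + 1)


def extract_traits(
    imageset: MultiViewImageSet,
    rule: ColourRule = ColourRule(),
    min_size: int = 50,
) -> TraitRecord:
    """Segment all four views and compute the digital vigour traits.

    Each view is segmented with :func:`segment_plant` then cleaned with
    :func:`denoise_mask`.  EB sums the four mask counts; TVA/TVCH/TVCOM
    come from the top view; EH is the maximum height over the side views.
    Views with empty masks produce NaN in the dependent traits and an
    ``empty_mask:<view>`` flag.
    """
    masks: dict[str, PlantMask] = {}
    for name, img in imageset.views().items():
        masks[name] = denoise_mask(segment_plant(img, rule, view=name), min_size=min_size)

    flags = tuple(f"empty_mask:{name}" for name in VIEWS if masks[name].count == 0)
    empty = set(f.split(":", 1)[1] for f in flags)

    nan = float("nan")
    if empty:
        eb = nan  # the four-view sum is incomplete
    else:
        eb = sum(masks[v].count for v in VIEWS) / 1000.0

    if "top" in empty:
        tva = tvch = tvcom = nan
    else:
        tva = masks["top"].count / 1000.0
        tvch = convex_hull_area(masks["top"])
        tvcom = tva / tvch

    side_heights = [plant_height(masks[v]) for v in SIDE_VIEWS if v not in empty]
    eh = float(max(side_heights)) if side_heights else nan

    for name in VIEWS:
        logger.info(
            "traits %s das=%d view=%s plant_pixels=%d",
            imageset.plant_id, imageset.das, name, masks[name].count,
        )
    return TraitRecord(
        plant_id=imageset.plant_id,
        genotype=imageset.genotype,
        das=imageset.das,
        eb_kpix=eb,
        tva_kpix=tva,
        tvch_kpix=tvch,
        tvcom=tvcom,
        eh_pix=eh,
        flags=flags,
    )
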