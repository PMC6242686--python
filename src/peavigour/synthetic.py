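"""Synthetic phenotyping scenes and growth series with known ground truth.

No raw images or harvest data were ever deposited for the pea early-vigour
experiment this package models, so every downstream stage is exercised on
synthetic inputs generated here:

* colour-separable plant scenes — green plant tissue, a blue support cage
  and a white pot/background, rendered as one top view plus three side
  views with per-channel Gaussian pixel noise.  The exact painted masks
  are returned as :class:`GroundTruth`, the oracle for segmentation tests;
* two-phase biomass trajectories — replicate series drawn around the
  continuous broken-stick model with multiplicative (CV-parameterised)
  noise;
* field reflectance records — two-band (670/760 nm) pairs whose NDVI is an
  affine function of genotype biomass plus noise, emulating a field
  validation trial.

All generators are deterministic given their seed (PCG64 via
``numpy.random.default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from skimage.draw import disk

from .growth import GrowthSeries, broken_stick_value
from .segmentation import SIDE_VIEWS, VIEWS, MultiViewImageSet, _hull_fill
from .vigour import ReflectanceRecord

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "GrowthParams",
    "make_scene",
    "parametric_plant_shapes",
    "parametric_scene",
    "simulate_growth",
    "simulate_field_ndvi",
]

#: default palette: green plant, blue cage, white background (8-bit RGB)
PLANT_COLOUR = (0, 160, 0)
CAGE_COLOUR = (40, 60, 200)
BACKGROUND_COLOUR = (245, 245, 245)

#: positive floor (kPix) applied to noisy simulated biomass
BIOMASS_FLOOR = 1e-3

PixelSet = "set[tuple[int, int]]"


def _per_view(shape) -> dict:
    """Normalise a pixel set (shared by all views) or per-view mapping."""
    if isinstance(shape, Mapping):
        unknown = set(shape) - set(VIEWS)
        if unknown:
            raise ValueError(f"unknown view labels: {sorted(unknown)}")
        return {v: set(shape.get(v, set())) for v in VIEWS}
    return {v: set(shape) for v in VIEWS}


@dataclass
class SceneSpec:
    """Declarative description of one multi-view plant scene.

    ``plant_shape`` and ``cage_geometry`` are sets of (row, col) pixels,
    either one set shared by all four views or a per-view mapping.  Where
    cage and plant overlap, the cage wins (it sits in front of the plant).
    The three scene colours must be pairwise separated by more than
    ``2 * noise_sd`` in at least one channel, so that a colour rule can in
    principle separate the classes.
    """

    image_width: int
    image_height: int
    plant_shape: object
    cage_geometry: object = field(default_factory=set)
    plant_colour: tuple[int, int, int] = PLANT_COLOUR
    cage_colour: tuple[int, int, int] = CAGE_COLOUR
    background_colour: tuple[int, int, int] = BACKGROUND_COLOUR
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width < 1 or self.image_height < 1:
            raise ValueError("image dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.plant_shape = _per_view(self.plant_shape)
        self.cage_geometry = _per_view(self.cage_geometry)
        if all(len(s) == 0 for s in self.plant_shape.values()):
            raise ValueError("plant_shape must be non-empty")
        for view in VIEWS:
            for r, c in self.plant_shape[view] | self.cage_geometry[view]:
                if not (0 <= r < self.image_height and 0 <= c < self.image_width):
                    raise ValueError(f"pixel ({r}, {c}) outside {view} image bounds")
        colours = {
            "plant": self.plant_colour,
            "cage": self.cage_colour,
            "background": self.background_colour,
        }
        names = list(colours)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                sep = max(abs(x - y) for x, y in zip(colours[a], colours[b]))
                if sep <= 2 * self.noise_sd:
                    raise ValueError(
                        f"{a}/{b} colours separated by {sep} <= 2*noise_sd "
                        f"({2 * self.noise_sd}); classes not separable"
                    )


@dataclass
class GroundTruth:
    """Noiseless per-view truth for a rendered scene.

    ``plant_pixels`` counts visible plant pixels (after cage occlusion);
    ``top_hull_pixels`` is the rasterised convex-hull area of the top-view
    plant object; ``side_heights`` the inclusive row span per side view.
    """

    plant_pixels: dict[str, int]
    top_hull_pixels: int
    side_heights: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.plant_pixels.values()):
            raise ValueError("pixel counts must be >= 0")
        if self.top_hull_pixels < self.plant_pixels.get("top", 0):
            raise ValueError("hull area cannot be smaller than the plant area")


def _paint(spec: SceneSpec, view: str, rng: np.random.Generator):
    """Render one view; returns (noisy image, visible plant mask)."""
    h, w = spec.image_height, spec.image_width
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_colour

    def as_mask(pixels) -> np.ndarray:
        m = np.zeros((h, w), dtype=bool)
        if pixels:
            idx = np.array(sorted(pixels), dtype=int)
            m[idx[:, 0], idx[:, 1]] = True
        return m

    plant = as_mask(spec.plant_shape[view])
    cage = as_mask(spec.cage_geometry[view])
    visible = plant & ~cage  # cage sits in front of the plant
    img[visible] = spec.plant_colour
    img[cage] = spec.cage_colour
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), visible


def make_scene(
    spec: SceneSpec, plant_id: str = "plant", genotype: str = "", das: int = 0
) -> tuple[MultiViewImageSet, GroundTruth]:
    """Render the four views of a scene and compute its ground truth.

    Ground truth comes from the noiseless label masks, so it is invariant
    to ``noise_sd``; rendering is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for view in VIEWS:  # fixed order keeps the noise stream reproducible
        images[view], masks[view] = _paint(spec, view, rng)

    counts = {v: int(masks[v].sum()) for v in VIEWS}
    hull = int(_hull_fill(masks["top"]).sum()) if counts["top"] else 0
    heights = {}
    for v in SIDE_VIEWS:
        rows = np.nonzero(masks[v].any(axis=1))[0]
        heights[v] = int(rows[-1] - rows[0] + 1) if len(rows) else 0

    imageset = MultiViewImageSet(
        plant_id=plant_id, genotype=genotype, das=das,
        top=images["top"], sides={v: images[v] for v in SIDE_VIEWS},
    )
    return imageset, GroundTruth(
        plant_pixels=counts, top_hull_pixels=hull, side_heights=heights
    )


def parametric_plant_shapes(
    width: int, height: int, target_pixels: Mapping[str, int] | int, seed: int = 0
) -> dict[str, set]:
    """Generate stylised plant pixel sets with exact per-view pixel counts.

    Side views get a vertical stem rising from the pot line with leaf
    blobs scattered along it; the top view is a rosette of blobs around
    the image centre.  Pixels are accumulated in a deterministic order and
    truncated to the target count, so each view's set has exactly
    ``target_pixels[view]`` pixels.  Segmentation correctness depends only
    on colour separation, not on realistic pea morphology.
    """
    targets = (
        {v: int(target_pixels) for v in VIEWS}
        if not isinstance(target_pixels, Mapping) else
        {v: int(target_pixels[v]) for v in VIEWS}
    )
    shapes: dict[str, set] = {}
    for vi, view in enumerate(VIEWS):
        target = targets[view]
        if target < 1:
            raise ValueError(f"target pixel count for {view} must be >= 1")
        if target > 0.5 * width * height:
            raise ValueError(f"target {target} exceeds half the {view} raster")
        rng = np.random.default_rng([seed, vi])
        chunks: list[np.ndarray] = []  # (n, 2) row/col arrays in paint order

        def blob(r0: int, c0: int, rad: int) -> None:
            rr, cc = disk((r0, c0), rad, shape=(height, width))
            chunks.append(np.stack([rr, cc], axis=1))

        if view == "top":
            centre = (height // 2, width // 2)
            blob(*centre, max(5, min(height, width) // 20))
            spread = int(np.clip(np.ceil(np.sqrt(2.0 * target)),
                                 min(height, width) // 6, min(height, width) // 2 - 2))
            max_rad = max(3, min(height, width) // 12)
        else:
            col = width // 2
            stem_h = int(np.clip(target // 3, 30, height - 4))
            base = height - 2
            rows = np.arange(base, base - stem_h, -1)
            stem = np.stack([np.repeat(rows, 2), np.tile([col, col + 1], len(rows))], axis=1)
            chunks.append(stem)
            # widen the leaf band so it can hold the target count
            half_w = int(np.clip(np.ceil(1.5 * target / max(stem_h, 1)), 12, width // 2 - 2))
            max_rad = 7

        def ordered_unique() -> np.ndarray:
            pts = np.concatenate(chunks)
            _, idx = np.unique(pts[:, 0] * width + pts[:, 1], return_index=True)
            return pts[np.sort(idx)]

        pts = ordered_unique()
        attempts = 0
        while len(pts) < target:
            attempts += 1
            if attempts > 500:
                raise ValueError(
                    f"cannot reach {target} pixels in the {view} plant region"
                )
            for _ in range(16):
                rad = int(rng.integers(2, max_rad + 1))
                if view == "top":
                    off = rng.integers(-spread, spread + 1, size=2)
                    blob(centre[0] + off[0], centre[1] + off[1], rad)
                else:
                    blob(int(rng.integers(base - stem_h, base)),
                         col + int(rng.integers(-half_w, half_w + 1)), rad)
            pts = ordered_unique()
        pts = pts[:target]
        shapes[view] = {(int(r), int(c)) for r, c in pts}
    return shapes


def _cage_shapes(width: int, height: int) -> dict[str, set]:
    """Blue wire cage: two uprights in side views, a ring in the top view."""
    shapes: dict[str, set] = {}
    off = max(4, width // 6)
    for v in SIDE_VIEWS:
        px = set()
        for c in (width // 2 - off, width // 2 + off):
            px.update((r, c) for r in range(height // 6, height - 1))
        shapes[v] = px
    centre = (height // 2, width // 2)
    radius = min(height, width) // 3
    theta = np.linspace(0, 2 * np.pi, 8 * radius, endpoint=False)
    ring = {
        (int(round(centre[0] + radius * np.sin(t))),
         int(round(centre[1] + radius * np.cos(t))))
        for t in theta
    }
    shapes["top"] = {
        (r, c) for r, c in ring if 0 <= r < height and 0 <= c < width
    }
    return shapes


def parametric_scene(
    width: int,
    height: int,
    target_pixels: Mapping[str, int] | int,
    noise_sd: float = 0.0,
    seed: int = 0,
    with_cage: bool = True,
) -> SceneSpec:
    """Convenience constructor: parametric plant plus standard cage."""
    return SceneSpec(
        image_width=width,
        image_height=height,
        plant_shape=parametric_plant_shapes(width, height, target_pixels, seed=seed),
        cage_geometry=_cage_shapes(width, height) if with_cage else set(),
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class GrowthParams:
    """Generating parameters for a two-phase biomass trajectory.

    ``x_day``/``y_kpix``/``slope1``/``slope2`` parameterise the continuous
    broken-stick mean curve; replicates are drawn as
    ``m(t) * (1 + cv * eps)`` with standard-normal ``eps`` on the integer
    day grid ``[day_start, day_end]``.
    """

    genotype: str
    x_day: float
    y_kpix: float
    slope1: float
    slope2: float
    day_start: int = 11
    day_end: int = 39
    cv: float = 0.03
    n_reps: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.day_start < self.x_day < self.day_end:
            raise ValueError(
                f"breakpoint {self.x_day} must lie inside ({self.day_start}, {self.day_end})"
            )
        if self.slope1 <= 0:
            raise ValueError("slope1 must be positive")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        m = self.mean_curve()
        # published lag-line parameters can extrapolate marginally below
        # zero at the very first day; the simulator clamps that to the
        # positive floor, but a curve non-positive anywhere later (or far
        # below zero at the start) is not a growth trajectory
        if np.any(m[1:] <= 0) or m[0] <= -0.05 * self.y_kpix:
            raise ValueError("model value must stay positive over the day grid")

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.day_start, self.day_end + 1, dtype=float)

    def mean_curve(self) -> np.ndarray:
        return broken_stick_value(self.days, self.x_day, self.y_kpix,
                                  self.slope1, self.slope2)


def simulate_growth(params: GrowthParams) -> list[GrowthSeries]:
    """Draw replicate biomass series around the two-phase mean curve.

    With ``cv=0`` the series reproduce the piecewise model exactly on the
    day grid.  Noisy draws are truncated at a small positive floor so the
    series stay valid biomass values.
    """
    m = params.mean_curve()
    rng = np.random.default_rng(params.seed)
    eps = rng.standard_normal(size=(params.n_reps, len(m)))
    values = np.maximum(m[None, :] * (1.0 + params.cv * eps), BIOMASS_FLOOR)
    return [
        GrowthSeries(params.genotype, rep + 1, params.days, values[rep])
        for rep in range(params.n_reps)
    ]


def simulate_field_ndvi(
    genotype_means: Mapping[str, float],
    link: tuple[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    total_reflectance: float = 0.8,
    n_plots: int = 1,
) -> list[ReflectanceRecord]:
    """Emit reflectance pairs whose NDVI tracks genotype biomass.

    For each genotype with mean biomass ``eb`` the target index is
    ``link[0] + link[1] * eb`` plus Gaussian noise, and the (R760, R670)
    pair is solved from the target index ``v`` and the fixed band sum
    ``S = total_reflectance``::

        R760 = S * (1 + v) / 2,   R670 = S * (1 - v) / 2

    Links whose noiseless index leaves the open interval (-1, 1) for any
    genotype are rejected; noisy draws are clipped just inside it.
    """
    if not 0 < total_reflectance <= 1.0:
        raise ValueError("total_reflectance must be in (0, 1]")
    a, b = link
    clean = {g: a + b * eb for g, eb in genotype_means.items()}
    bad = {g: v for g, v in clean.items() if not -1.0 < v < 1.0}
    if bad:
        raise ValueError(f"link maps NDVI outside (-1, 1) for: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    records = []
    for g, v0 in clean.items():
        for k in range(n_plots):
            v = float(np.clip(v0 + rng.normal(0.0, noise_sd) if noise_sd > 0 else v0,
                              -1 + 1e-9, 1 - 1e-9))
            records.append(ReflectanceRecord(
                plot_id=f"{g}-p{k + 1}",
                genotype=g,
                r760=total_reflectance * (1 + v) / 2,
                r670=total_reflectance * (1 - v) / 2,
            ))
    return records
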