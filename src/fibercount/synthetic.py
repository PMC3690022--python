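"""Synthetic dual-mode slide generator with ground truth.

Renders registered reflection/fluorescence tile grids that emulate scanned
asbestos slide samples: bright elongated fibers of two mineral classes
(chrysotile, which carries the fluorescent label and is visible in both
modes; amosite, visible in reflection only), round-to-elliptical debris,
annular air-bubble menisci (reflection only), a smooth background
illumination gradient, and additive Gaussian noise.  Every placed object is
recorded in a registry so downstream segmentation and counting can be
validated against exact ground truth.

Geometry notes
--------------
Fibers are straight capsules (rectangle with semicircular caps).  A capsule
at geometric aspect ratio exactly 3 measures a circularity of about 0.686,
*above* the 0.663 ellipse-equivalent cutoff that enforces the aspect-ratio
rule, so the generator keeps fiber aspect ratios >= ~4.5 by construction;
real chrysotile in these preparations is mostly much more elongated still
(alpha >= 7).  Debris aspect ratios stay <= 2.5, safely on the round side of
the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .pipeline import TILE_EXTENT_UM, TileImage

__all__ = [
    "SceneParams",
    "TileGeometry",
    "GroundTruthRecord",
    "SlidePair",
    "generate_slide",
    "generate_dilution_series",
    "generate_bead_field",
]


@dataclass(frozen=True)
class TileGeometry:
    """Pixel calibration and physical extent of one tile."""

    pixel_size: float = 0.4  # um/pixel
    extent_um: tuple[float, float] = TILE_EXTENT_UM  # (x, y)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) pixel shape of one tile."""
        ex, ey = self.extent_um
        return (int(round(ey / self.pixel_size)), int(round(ex / self.pixel_size)))

    @property
    def area_mm2(self) -> float:
        ex, ey = self.extent_um
        return ex * ey * 1e-6


@dataclass(frozen=True)
class SceneParams:
    """Contents and photometry of one synthetic slide.

    Counts are objects per slide (whole tile grid).  Lengths and widths are
    in um; intensities are additive amplitudes on the 16-bit scale above the
    local background.  ``background`` is (base level, gradient amplitude,
    gradient direction in degrees) applied across the whole slide canvas.
    """

    n_chrysotile: int = 20
    n_amosite: int = 0
    n_debris: int = 0
    n_bubbles: int = 0
    fiber_length_median_um: float = 18.0
    fiber_length_sigma: float = 0.35
    fiber_width_um: tuple[float, float] = (1.3, 2.6)
    min_fiber_aspect: float = 4.5
    amosite_scale: float = 0.55  # amosite is much smaller than chrysotile
    debris_diameter_um: tuple[float, float] = (4.0, 12.0)
    debris_aspect: tuple[float, float] = (1.0, 2.5)
    bubble_radius_um: tuple[float, float] = (15.0, 35.0)
    bubble_ring_width_um: float = 2.0
    intensity: dict = field(
        default_factory=lambda: {
            ("chrysotile", "reflection"): 12000.0,
            ("chrysotile", "fluorescence"): 8000.0,
            ("amosite", "reflection"): 11000.0,
            ("debris", "reflection"): 12000.0,
            ("bubble", "reflection"): 9000.0,
        }
    )
    background: tuple[float, float, float] = (8000.0, 2000.0, 30.0)
    fluorescence_background: tuple[float, float, float] = (600.0, 150.0, 30.0)
    noise_sigma: float = 60.0
    separation_um: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chrysotile", "n_amosite", "n_debris", "n_bubbles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.debris_aspect[1] >= 3.0:
            raise ValueError("debris aspect ratios must stay < 3")
        if self.min_fiber_aspect < 3.0:
            raise ValueError("fiber aspect ratios must be >= 3 by construction")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Registry row for one placed object."""

    object_id: int
    obj_class: str  # chrysotile | amosite | debris | bubble
    tile_row: int
    tile_col: int
    center_x_um: float
    center_y_um: float
    length_um: float
    width_um: float
    orientation_deg: float
    visible_in: tuple[str, ...]


@dataclass
class SlidePair:
    """A registered pair of tile grids plus the ground-truth registry."""

    reflection: list[TileImage]
    fluorescence: list[TileImage]
    registry: list[GroundTruthRecord]
    grid: tuple[int, int]
    geometry: TileGeometry
    seed: int

    def registry_frame(self) -> pd.DataFrame:
        rows = [
            {
                "object_id": r.object_id,
                "class": r.obj_class,
                "tile_row": r.tile_row,
                "tile_col": r.tile_col,
                "center_x_um": r.center_x_um,
                "center_y_um": r.center_y_um,
                "length_um": r.length_um,
                "width_um": r.width_um,
                "orientation_deg": r.orientation_deg,
                "visible_in": "+".join(r.visible_in),
            }
            for r in self.registry
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "object_id",
                "class",
                "tile_row",
                "tile_col",
                "center_x_um",
                "center_y_um",
                "length_um",
                "width_um",
                "orientation_deg",
                "visible_in",
            ],
        )

    def class_count(self, *classes: str) -> int:
        return sum(1 for r in self.registry if r.obj_class in classes)

    def visible_count(self, mode: str) -> int:
        return sum(1 for r in self.registry if mode in r.visible_in)


VISIBILITY = {
    "chrysotile": ("reflection", "fluorescence"),
    "amosite": ("reflection",),
    "debris": ("reflection",),
    "bubble": ("reflection",),
}


def _render_capsule(canvas, cx, cy, length_px, width_px, theta_deg, amplitude):
    """Add a rotated capsule (stadium) with a ~1-px anti-aliased edge."""
    half = length_px / 2.0
    r = width_px / 2.0
    pad = int(math.ceil(half + r + 2))
    x0, x1 = int(cx) - pad, int(cx) + pad + 1
    y0, y1 = int(cy) - pad, int(cy) + pad + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, canvas.shape[1]), min(y1, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    t = math.radians(theta_deg)
    u = (xx - cx) * math.cos(t) + (yy - cy) * math.sin(t)
    v = -(xx - cx) * math.sin(t) + (yy - cy) * math.cos(t)
    # distance to the capsule spine segment
    seg = half - r
    u_clamped = np.clip(u, -seg, seg)
    dist = np.hypot(u - u_clamped, v)
    coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
    canvas[y0:y1, x0:x1] += amplitude * coverage


def _render_ellipse(canvas, cx, cy, a_px, b_px, theta_deg, amplitude):
    """Add a filled rotated ellipse (semi-axes a >= b) with soft edge."""
    pad = int(math.ceil(a_px + 2))
    x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, canvas.shape[1])
    y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    t = math.radians(theta_deg)
    u = (xx - cx) * math.cos(t) + (yy - cy) * math.sin(t)
    v = -(xx - cx) * math.sin(t) + (yy - cy) * math.cos(t)
    rho = np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)
    coverage = np.clip((1.0 - rho) * b_px + 0.5, 0.0, 1.0)
    canvas[y0:y1, x0:x1] += amplitude * coverage


def _render_annulus(canvas, cx, cy, radius_px, ring_w_px, amplitude, interior_dip):
    """Add a bright ring with a slightly darker interior (bubble meniscus)."""
    pad = int(math.ceil(radius_px + ring_w_px + 2))
    x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, canvas.shape[1])
    y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    ring = np.clip(ring_w_px / 2.0 + 0.5 - np.abs(d - radius_px), 0.0, 1.0)
    interior = np.clip(radius_px - ring_w_px / 2.0 - d, 0.0, 1.0)
    canvas[y0:y1, x0:x1] += amplitude * ring - interior_dip * interior


def _background_canvas(shape, params, rng, noise_sigma):
    base, grad_amp, grad_dir = params
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    t = math.radians(grad_dir)
    if max(h, w) > 1:
        proj = (xx * math.cos(t) + yy * math.sin(t)) / max(h, w)
    else:  # pragma: no cover
        proj = np.zeros(shape)
    canvas = base + grad_amp * proj
    if noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, noise_sigma, size=shape)
    return canvas


@dataclass
class _Placement:
    obj_class: str
    cx_px: float
    cy_px: float
    length_um: float
    width_um: float
    theta_deg: float
    radius_px: float  # bounding radius for separation checks
    tile: tuple[int, int]


def _place_objects(scene, grid, geom, rng, max_tries=400):
    """Rejection-sample non-overlapping placements, each inside one tile.

    Objects are kept clear of tile borders (by their bounding radius plus an
    edge margin) so that no object is split across tiles, and clear of each
    other by ``separation_um``.
    """
    th, tw = geom.shape
    rows, cols = grid
    sep_px = scene.separation_um / geom.pixel_size
    placed: list[_Placement] = []

    def try_place(obj_class: str, length_um, width_um, bounding_um, theta):
        bound_px = bounding_um / geom.pixel_size
        for _ in range(max_tries):
            r = int(rng.integers(rows))
            c = int(rng.integers(cols))
            margin = bound_px + 3.0
            if 2 * margin >= min(th, tw):
                continue
            cy = rng.uniform(margin, th - margin) + r * th
            cx = rng.uniform(margin, tw - margin) + c * tw
            ok = True
            for p in placed:
                if math.hypot(cx - p.cx_px, cy - p.cy_px) < bound_px + p.radius_px + sep_px:
                    ok = False
                    break
            if ok:
                placed.append(
                    _Placement(obj_class, cx, cy, length_um, width_um, theta, bound_px, (r, c))
                )
                return
        raise RuntimeError(
            f"could not place {obj_class} after {max_tries} tries; "
            "scene too crowded for the tile grid"
        )

    for _ in range(scene.n_chrysotile):
        length = float(np.clip(rng.lognormal(math.log(scene.fiber_length_median_um), scene.fiber_length_sigma), 8.0, 60.0))
        wlo, whi = scene.fiber_width_um
        width = float(rng.uniform(wlo, whi))
        width = min(width, length / scene.min_fiber_aspect)
        try_place("chrysotile", length, width, length / 2.0, float(rng.uniform(0, 180)))
    for _ in range(scene.n_amosite):
        s = scene.amosite_scale
        length = float(np.clip(rng.lognormal(math.log(scene.fiber_length_median_um * s), scene.fiber_length_sigma), 7.0, 40.0))
        wlo, whi = scene.fiber_width_um
        width = float(rng.uniform(wlo * s, whi * s))
        width = min(width, length / scene.min_fiber_aspect)
        try_place("amosite", length, width, length / 2.0, float(rng.uniform(0, 180)))
    for _ in range(scene.n_debris):
        dia = float(rng.uniform(*scene.debris_diameter_um))
        aspect = float(rng.uniform(*scene.debris_aspect))
        try_place("debris", dia, dia / aspect, dia / 2.0, float(rng.uniform(0, 180)))
    for _ in range(scene.n_bubbles):
        radius = float(rng.uniform(*scene.bubble_radius_um))
        try_place("bubble", 2 * radius, scene.bubble_ring_width_um, radius + scene.bubble_ring_width_um, 0.0)
    return placed


def generate_slide(
    scene: SceneParams,
    grid: tuple[int, int] = (1, 1),
    geometry: TileGeometry | None = None,
) -> SlidePair:
    """Render one dual-mode slide and its ground-truth registry.

    Both modes share identical object geometry (perfect registration); only
    chrysotile contributes signal to the fluorescence canvas.  Background
    gradient and Gaussian noise are added per mode.  Fully determined by
    ``scene.seed``.
    """
    geometry = geometry or TileGeometry()
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one tile in each axis")
    th, tw = geometry.shape
    rng = np.random.default_rng(scene.seed)
    placed = _place_objects(scene, grid, geometry, rng)

    canvas_shape = (rows * th, cols * tw)
    refl = _background_canvas(canvas_shape, scene.background, rng, scene.noise_sigma)
    fluo = _background_canvas(
        canvas_shape, scene.fluorescence_background, rng, scene.noise_sigma
    )

    ps = geometry.pixel_size
    registry: list[GroundTruthRecord] = []
    for i, p in enumerate(placed):
        modes = VISIBILITY[p.obj_class]
        for mode, canvas in (("reflection", refl), ("fluorescence", fluo)):
            if mode not in modes:
                continue
            amp = scene.intensity.get((p.obj_class, mode), 0.0)
            if amp <= 0:
                continue
            if p.obj_class in ("chrysotile", "amosite"):
                _render_capsule(canvas, p.cx_px, p.cy_px, p.length_um / ps, p.width_um / ps, p.theta_deg, amp)
            elif p.obj_class == "debris":
                _render_ellipse(canvas, p.cx_px, p.cy_px, p.length_um / (2 * ps), p.width_um / (2 * ps), p.theta_deg, amp)
            else:  # bubble
                _render_annulus(canvas, p.cx_px, p.cy_px, p.length_um / (2 * ps), p.width_um / ps, amp, interior_dip=0.1 * amp)
        registry.append(
            GroundTruthRecord(
                object_id=i,
                obj_class=p.obj_class,
                tile_row=p.tile[0],
                tile_col=p.tile[1],
                center_x_um=p.cx_px * ps,
                center_y_um=p.cy_px * ps,
                length_um=p.length_um,
                width_um=p.width_um,
                orientation_deg=p.theta_deg,
                visible_in=VISIBILITY[p.obj_class],
            )
        )

    def to_tiles(canvas: np.ndarray, mode: str) -> list[TileImage]:
        tiles = []
        clipped = np.clip(canvas, 0, 65535).astype(np.uint16)
        for r in range(rows):
            for c in range(cols):
                tiles.append(
                    TileImage(
                        pixels=clipped[r * th : (r + 1) * th, c * tw : (c + 1) * tw],
                        pixel_size=ps,
                        mode=mode,
                        bit_depth=16,
                        tile_index=(r, c),
                        stage_position=(c * tw * ps, r * th * ps),
                    )
                )
        return tiles

    return SlidePair(
        reflection=to_tiles(refl, "reflection"),
        fluorescence=to_tiles(fluo, "fluorescence"),
        registry=registry,
        grid=grid,
        geometry=geometry,
        seed=scene.seed,
    )


@dataclass(frozen=True)
class DilutionLevel:
    """One concentration level of a dilution series."""

    factor: float
    expected_mean: float  # base count x factor
    slides: tuple[SlidePair, ...]


def generate_dilution_series(
    base: SceneParams,
    factors: Iterable[float] = (1.0, 0.5, 0.25, 0.125),
    n_slides_per_level: int = 3,
    master_seed: int = 0,
    grid: tuple[int, int] = (1, 1),
    geometry: TileGeometry | None = None,
) -> list[DilutionLevel]:
    """Serial dilution: per-slide object counts are Poisson around base x factor.

    Models pipetting variability in a serially diluted suspension: at each
    level every object class count is drawn Poisson with mean equal to the
    base count times the dilution factor; replicate slides at a level differ
    only by their derived seed.  Seeds derive deterministically from
    ``master_seed`` so regeneration is bit-identical.
    """
    factors = list(factors)
    if any(f <= 0 for f in factors):
        raise ValueError("dilution factors must be positive")
    if factors != sorted(factors, reverse=True):
        raise ValueError("dilution factors must be descending")
    levels = []
    for li, f in enumerate(factors):
        slides = []
        for rep in range(n_slides_per_level):
            ss = np.random.SeedSequence([int(master_seed), li, rep])
            child = np.random.default_rng(ss)
            seed = int(child.integers(0, 2**31 - 1))
            counts = {
                name: int(child.poisson(getattr(base, name) * f))
                for name in ("n_chrysotile", "n_amosite", "n_debris", "n_bubbles")
            }
            scene = replace(base, seed=seed, **counts)
            slides.append(generate_slide(scene, grid=grid, geometry=geometry))
        levels.append(
            DilutionLevel(factor=f, expected_mean=base.n_chrysotile * f, slides=tuple(slides))
        )
    return levels


def generate_bead_field(
    bead_diameter_um: float = 2.0,
    expected_density_per_mm2: float = 100.0,
    geometry: TileGeometry | None = None,
    grid: tuple[int, int] = (1, 1),
    seed: int = 0,
    amplitude: float = 8000.0,
    background: tuple[float, float, float] = (600.0, 150.0, 30.0),
    noise_sigma: float = 60.0,
) -> tuple[list[TileImage], int]:
    """Fluorescent bead QC field: Gaussian spots at a Poisson-drawn count.

    Beads of the given nominal diameter are rendered as Gaussian spots whose
    FWHM equals the diameter; the true count is Poisson(density x imaged
    area) and is returned alongside the tiles.
    """
    if expected_density_per_mm2 < 0:
        raise ValueError("density must be >= 0")
    geometry = geometry or TileGeometry()
    rows, cols = grid
    th, tw = geometry.shape
    rng = np.random.default_rng(seed)
    area_mm2 = geometry.area_mm2 * rows * cols
    count = int(rng.poisson(expected_density_per_mm2 * area_mm2))
    shape = (rows * th, cols * tw)
    canvas = _background_canvas(shape, background, rng, noise_sigma)
    sigma_px = (bead_diameter_um / geometry.pixel_size) / 2.3548  # FWHM = diameter
    margin = 4 * sigma_px + 2
    for _ in range(count):
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        pad = int(math.ceil(4 * sigma_px))
        y0, y1 = int(cy) - pad, int(cy) + pad + 1
        x0, x1 = int(cx) - pad, int(cx) + pad + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1] += amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)
        )
    clipped = np.clip(canvas, 0, 65535).astype(np.uint16)
    tiles = [
        TileImage(
            pixels=clipped[r * th : (r + 1) * th, c * tw : (c + 1) * tw],
            pixel_size=geometry.pixel_size,
            mode="fluorescence",
            bit_depth=16,
            tile_index=(r, c),
            stage_position=(c * tw * geometry.pixel_size, r * th * geometry.pixel_size),
        )
        for r in range(rows)
        for c in range(cols)
    ]
    return tiles, count
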