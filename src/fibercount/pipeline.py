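"""Per-tile image processing: background subtraction, local thresholding,
smoothing, particle labeling and measurement.

The chain mirrors the classic particle-analysis recipe for scanned microscopy
tiles: (1) remove the smooth illumination background by grayscale morphological
opening and subtraction ("rolling-ball" style), (2) binarize with a local
adaptive threshold (window statistic + offset), with a 3x3 mean smoothing of
the grayscale image in between, and (3) label 8-connected components and
measure each one (area, perimeter, moments ellipse, circularity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import (
    maximum_filter,
    median_filter,
    minimum_filter,
    uniform_filter,
    uniform_filter1d,
)
from skimage.measure import find_contours, label as sk_label, regionprops

from .shapes import measured_circularity

Mode = Literal["reflection", "fluorescence"]

__all__ = [
    "TileImage",
    "PipelineParams",
    "Particle",
    "subtract_background",
    "local_threshold",
    "smooth",
    "label_particles",
    "measure_particle",
    "run_pipeline",
    "particles_to_frame",
]

#: physical tile extent of the stage scan, um (display-window size)
TILE_EXTENT_UM = (650.0, 490.0)


@dataclass
class TileImage:
    """One calibrated grayscale tile.

    Pixel centers sit at integer coordinates, origin top-left, x rightward,
    y downward; ``stage_position`` is the tile's top-left corner in slide
    coordinates (um), first tile at (0, 0).
    """

    pixels: np.ndarray
    pixel_size: float  # um/pixel, isotropic
    mode: Mode = "reflection"
    bit_depth: int = 16
    tile_index: tuple[int, int] = (0, 0)  # (row, col)
    stage_position: tuple[float, float] = (0.0, 0.0)  # (x um, y um)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("tile pixels must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (um/pixel)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def extent_um(self) -> tuple[float, float]:
        """(x, y) physical extent in um."""
        h, w = self.pixels.shape
        return (w * self.pixel_size, h * self.pixel_size)


@dataclass(frozen=True)
class PipelineParams:
    """Tunable knobs of the four processing stages.

    ``background_radius`` is the opening radius in px (must exceed the
    half-width of the widest object to keep); ``threshold_radius`` is the
    local-window radius r so the window is (2r+1) square; ``threshold_offset``
    is in intensity units above the local statistic.  The smoothing kernel is
    a fixed 3x3 mean and connectivity is fixed at 8, matching the recipe.
    """

    background_radius: int = 25
    threshold_radius: int = 15
    threshold_method: Literal["mean", "median", "midgrey"] = "mean"
    threshold_offset: float = 4000.0
    smooth_before_threshold: bool = True
    background_footprint: Literal["square", "disk"] = "square"

    def __post_init__(self) -> None:
        if not self.background_radius > 0:
            raise ValueError("background_radius must be > 0")
        if not self.threshold_radius >= 1:
            raise ValueError("threshold_radius must be >= 1")
        if self.threshold_method not in ("mean", "median", "midgrey"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


#: defaults per imaging mode; fluorescence tiles are near-zero background so a
#: lower offset keeps dim labeled fibers while the dark field stays empty.
DEFAULT_PARAMS: dict[str, PipelineParams] = {
    "reflection": PipelineParams(),
    "fluorescence": PipelineParams(threshold_offset=2800.0),
}


@dataclass
class Particle:
    """One segmented connected component with its measurements."""

    label: int
    centroid_x_px: float
    centroid_y_px: float
    area_px2: float
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    circularity: float
    major_um: float
    minor_um: float
    angle_deg: float
    length_um: float  # max Feret (caliper) diameter
    aspect_ratio: float  # major/minor of the moments ellipse


def _as_float(img: np.ndarray | TileImage) -> np.ndarray:
    pixels = img.pixels if isinstance(img, TileImage) else img
    return np.asarray(pixels, dtype=np.float64)


def _replace_pixels(tile: TileImage, pixels: np.ndarray) -> TileImage:
    return TileImage(
        pixels=pixels,
        pixel_size=tile.pixel_size,
        mode=tile.mode,
        bit_depth=tile.bit_depth,
        tile_index=tile.tile_index,
        stage_position=tile.stage_position,
    )


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def subtract_background(tile: TileImage, radius: int | None = None) -> TileImage:
    """Remove the smooth illumination background by opening-and-subtract.

    Grayscale opening (erosion then dilation) with a flat structuring element
    of the given radius estimates the background: any bright structure
    narrower than the element is flattened out, while variations on scales
    larger than the element survive into the background estimate and are
    subtracted.  Output is clipped at zero.

    The default footprint is a (2r+1) square, which is separable and fast; a
    true disk is available via ``PipelineParams.background_footprint``.
    """
    radius = 25 if radius is None else int(radius)
    if not radius > 0:
        raise ValueError("background radius must be > 0")
    img = _as_float(tile)
    if 2 * radius + 1 > max(img.shape):
        raise ValueError(
            f"background radius {radius} exceeds image extent {img.shape}"
        )
    size = 2 * radius + 1
    background = maximum_filter(
        minimum_filter(img, size=size, mode="nearest"), size=size, mode="nearest"
    )
    out = np.clip(img - background, 0.0, None)
    return _replace_pixels(tile, out)


def _subtract_background_disk(img: np.ndarray, radius: int) -> np.ndarray:
    """Opening-and-subtract with a true disk footprint (slower; for tests)."""
    fp = _disk_footprint(radius)
    background = maximum_filter(
        minimum_filter(img, footprint=fp, mode="nearest"), footprint=fp, mode="nearest"
    )
    return np.clip(img - background, 0.0, None)


def local_threshold(tile: TileImage, params: PipelineParams) -> np.ndarray:
    """Binarize: foreground iff intensity > local window statistic + offset.

    The window is the (2r+1)x(2r+1) neighborhood of each pixel (edge
    replicated), with the statistic chosen by ``threshold_method``: mean,
    median, or midgrey ((min+max)/2).  Because the threshold tracks the local
    neighborhood, a smooth illumination gradient does not shift the mask.
    """
    img = _as_float(tile)
    size = 2 * int(params.threshold_radius) + 1
    if params.threshold_method == "mean":
        stat = uniform_filter(img, size=size, mode="nearest")
    elif params.threshold_method == "median":
        stat = median_filter(img, size=size, mode="nearest")
    else:  # midgrey
        stat = 0.5 * (
            minimum_filter(img, size=size, mode="nearest")
            + maximum_filter(img, size=size, mode="nearest")
        )
    return img > stat + params.threshold_offset


def smooth(image: np.ndarray | TileImage) -> np.ndarray | TileImage:
    """3x3 mean filter with edge replication; returns the input's type."""
    img = _as_float(image)
    out = uniform_filter(img, size=3, mode="nearest")
    if isinstance(image, TileImage):
        return _replace_pixels(image, out)
    return out


def label_particles(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling, labels 1..N in raster order."""
    return sk_label(np.asarray(mask, dtype=bool), connectivity=2)


def _smoothed_contour_perimeter(mask: np.ndarray, win: int = 5) -> float:
    """Perimeter from marching-squares contours with vertex smoothing.

    Sub-pixel contours at the 0.5 level are extracted from the zero-padded
    mask; closed contours are smoothed with a circular moving average of
    ``win`` vertices to remove the staircase bias of the pixel grid before
    summing segment lengths.
    """
    padded = np.pad(mask.astype(np.float64), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        pts = contour[:-1] if closed else contour
        if closed and len(pts) >= win:
            pts = uniform_filter1d(pts, size=win, axis=0, mode="wrap")
        if closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.diff(pts, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def measure_particle(region, pixel_size: float) -> Particle:
    """Measure one labeled region into a :class:`Particle`.

    Area is the pixel count; the perimeter comes from the smoothed
    sub-pixel contour; ellipse axes are those of the ellipse with the same
    normalized second central moments as the region; circularity is
    ``4*pi*area/perimeter**2`` clamped to 1.  Length is the maximum Feret
    (caliper) diameter in um: for solid ellipses it coincides with the
    moments major axis, while for rod-like particles the moments axis
    overshoots the physical length by up to 15%, so the caliper length is
    the faithful fiber length.  The minor axis is floored at one pixel so
    degenerate (single-pixel or single-row) regions stay finite.
    """
    if region.area == 0:
        raise ValueError("region is empty")
    perimeter_px = _smoothed_contour_perimeter(region.image)
    if perimeter_px <= 0:  # pragma: no cover - single pixel still yields a contour
        perimeter_px = 4.0
    area_px2 = float(region.area)
    major_px = float(region.axis_major_length)
    minor_px = float(region.axis_minor_length)
    major_px = max(major_px, 1.0)
    minor_px = min(max(minor_px, 1.0), major_px)
    length_px = max(float(region.feret_diameter_max), 1.0)
    cy, cx = region.centroid
    return Particle(
        label=int(region.label),
        centroid_x_px=float(cx),
        centroid_y_px=float(cy),
        area_px2=area_px2,
        area_um2=area_px2 * pixel_size**2,
        perimeter_px=perimeter_px,
        perimeter_um=perimeter_px * pixel_size,
        circularity=measured_circularity(area_px2, perimeter_px),
        major_um=major_px * pixel_size,
        minor_um=minor_px * pixel_size,
        angle_deg=float(np.degrees(region.orientation)),
        length_um=length_px * pixel_size,
        aspect_ratio=major_px / minor_px,
    )


def measure_labeled(labels: np.ndarray, pixel_size: float) -> list[Particle]:
    """Measure every labeled region (labels 1..N) of a label image."""
    return [measure_particle(r, pixel_size) for r in regionprops(labels)]


def run_pipeline(
    tile: TileImage, params: PipelineParams | None = None
) -> list[Particle]:
    """Run the full four-stage chain on one tile; returns unfiltered particles.

    Order: background subtraction -> 3x3 mean smoothing of the grayscale
    (before thresholding by default; after, on the mask, if
    ``smooth_before_threshold`` is False, in which case the smoothed mask is
    re-binarized at 0.5) -> local threshold -> labeling and measurement.
    Deterministic for fixed inputs.
    """
    if params is None:
        params = DEFAULT_PARAMS.get(tile.mode, PipelineParams())
    if params.background_footprint == "disk":
        stage = _replace_pixels(
            tile, _subtract_background_disk(_as_float(tile), params.background_radius)
        )
    else:
        stage = subtract_background(tile, params.background_radius)
    if params.smooth_before_threshold:
        stage = smooth(stage)
        mask = local_threshold(stage, params)
    else:
        mask = local_threshold(stage, params)
        mask = np.asarray(smooth(mask.astype(np.float64))) >= 0.5
    labels = label_particles(mask)
    return measure_labeled(labels, tile.pixel_size)


PARTICLE_COLUMNS = [
    "tile_row",
    "tile_col",
    "mode",
    "label",
    "centroid_x_px",
    "centroid_y_px",
    "area_px2",
    "area_um2",
    "perimeter_um",
    "circularity",
    "major_um",
    "minor_um",
    "angle_deg",
    "aspect_ratio",
]


def particles_to_frame(
    particles: list[Particle],
    tile_index: tuple[int, int] = (0, 0),
    mode: str = "reflection",
) -> pd.DataFrame:
    """Tabulate particles of one tile as a DataFrame (one row per particle)."""
    rows = [
        {
            "tile_row": tile_index[0],
            "tile_col": tile_index[1],
            "mode": mode,
            "label": p.label,
            "centroid_x_px": p.centroid_x_px,
            "centroid_y_px": p.centroid_y_px,
            "area_px2": p.area_px2,
            "area_um2": p.area_um2,
            "perimeter_um": p.perimeter_um,
            "circularity": p.circularity,
            "major_um": p.major_um,
            "minor_um": p.minor_um,
            "angle_deg": p.angle_deg,
            "aspect_ratio": p.aspect_ratio,
        }
        for p in particles
    ]
    return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)
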