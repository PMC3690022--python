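"""Stage raster scan-plan model.

The motorized stage steps the slide under the objective in fixed increments
(defaults 650 um in x, 490 um in y — the display-window size, so tiles abut
without overlap), covering a rectangular extent.  The fluorescence pass
revisits the identical positions ("regression" return pass), giving
registered dual-mode tile pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: area of one conventional PCM counting field (0.1 mm diameter), mm^2
PCM_FIELD_AREA_MM2 = 0.00785


@dataclass(frozen=True)
class ScanPlan:
    step_x: float
    step_y: float
    extent_x: float
    extent_y: float
    tiles_x: int
    tiles_y: int
    positions: tuple[tuple[float, float], ...]
    order: str  # "serpentine" | "raster"
    pass2_registered: bool = True

    @property
    def n_tiles(self) -> int:
        return self.tiles_x * self.tiles_y

    @property
    def tile_area_mm2(self) -> float:
        return self.step_x * self.step_y * 1e-6

    def pcm_field_ratio(self) -> float:
        """How many PCM fields fit in one tile (throughput bookkeeping)."""
        return self.tile_area_mm2 / PCM_FIELD_AREA_MM2

    def fluorescence_positions(self) -> tuple[tuple[float, float], ...]:
        """Second-pass positions; identical to the first pass when registered."""
        return self.positions


def plan_scan(
    extent_x: float,
    extent_y: float,
    step_x: float = 650.0,
    step_y: float = 490.0,
    order: str = "serpentine",
) -> ScanPlan:
    """Build the deterministic stage position list covering the extent.

    Tile counts per axis follow the ceiling rule, so a step larger than the
    extent yields a single tile, never an error.  Serpentine ordering
    (default) alternates the x direction on each row so consecutive
    positions always differ by exactly one step along one axis; plain raster
    is available by flag.
    """
    if not (extent_x > 0 and extent_y > 0 and step_x > 0 and step_y > 0):
        raise ValueError("extents and steps must be positive")
    if order not in ("serpentine", "raster"):
        raise ValueError(f"unknown scan order {order!r}")
    tiles_x = max(1, math.ceil(extent_x / step_x))
    tiles_y = max(1, math.ceil(extent_y / step_y))
    positions: list[tuple[float, float]] = []
    for row in range(tiles_y):
        cols = range(tiles_x)
        if order == "serpentine" and row % 2 == 1:
            cols = reversed(cols)  # type: ignore[assignment]
        for col in cols:
            positions.append((col * step_x, row * step_y))
    return ScanPlan(
        step_x=step_x,
        step_y=step_y,
        extent_x=extent_x,
        extent_y=extent_y,
        tiles_x=tiles_x,
        tiles_y=tiles_y,
        positions=tuple(positions),
        order=order,
    )
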