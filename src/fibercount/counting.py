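"""Fiber counting, dual-mode aggregation, density/concentration conversion,
bead QC arithmetic, and dilution-series calibration statistics.

Counting applies the shape rules to measured particles; the dual-mode logic
pairs each reflection tile with its registered fluorescence tile, so the
reflection count is the *total* fiber count while the fluorescence count is
the selectively labeled (chrysotile) count.  Calibration uses a linear
regression through the origin of measured vs. expected counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pipeline import Particle
from .shapes import CountingRules, qualifies_as_fiber

__all__ = [
    "SlideCounts",
    "BeadSpec",
    "DilutionReport",
    "count_fibers",
    "dual_mode_counts",
    "fiber_density",
    "fiber_concentration",
    "beads_per_ml",
    "regression_through_origin",
    "manual_comparison_report",
]


def count_fibers(
    particles: list[Particle], rules: CountingRules
) -> tuple[int, list[Particle]]:
    """Count particles passing the fiber rules; returns (count, accepted)."""
    accepted = [p for p in particles if qualifies_as_fiber(p, rules)]
    return len(accepted), accepted


@dataclass
class SlideCounts:
    """Per-slide dual-mode fiber counts and densities."""

    slide_id: str
    n_tiles: int
    tile_area_mm2: float
    total_fibers_reflection: int
    chrysotile_fibers_fluorescence: int
    per_tile_reflection: dict
    per_tile_fluorescence: dict

    @property
    def chrysotile_fraction(self) -> float | None:
        """Fluorescence/reflection count ratio; None (flagged) when 0/0."""
        if self.total_fibers_reflection == 0:
            return None
        return self.chrysotile_fibers_fluorescence / self.total_fibers_reflection

    @property
    def density_reflection(self) -> float:
        return fiber_density(self.total_fibers_reflection, self.n_tiles, self.tile_area_mm2)

    @property
    def density_fluorescence(self) -> float:
        return fiber_density(
            self.chrysotile_fibers_fluorescence, self.n_tiles, self.tile_area_mm2
        )

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "n_tiles": self.n_tiles,
            "tile_area_mm2": self.tile_area_mm2,
            "total_fibers_reflection": self.total_fibers_reflection,
            "chrysotile_fibers_fluorescence": self.chrysotile_fibers_fluorescence,
            "chrysotile_fraction": self.chrysotile_fraction,
            "density_reflection_f_per_mm2": self.density_reflection,
            "density_fluorescence_f_per_mm2": self.density_fluorescence,
            "per_tile_reflection": {f"{k[0]}_{k[1]}": v for k, v in self.per_tile_reflection.items()},
            "per_tile_fluorescence": {f"{k[0]}_{k[1]}": v for k, v in self.per_tile_fluorescence.items()},
        }


def dual_mode_counts(
    reflection_particles: dict[tuple[int, int], list[Particle]],
    fluorescence_particles: dict[tuple[int, int], list[Particle]],
    rules: CountingRules,
    tile_area_mm2: float,
    fluorescence_rules: CountingRules | None = None,
    slide_id: str = "slide",
) -> SlideCounts:
    """Aggregate per-tile particle lists from both registered modes.

    Both modes must cover the same tile grid.  Reflection and fluorescence
    tiles are counted independently, with ``fluorescence_rules`` defaulting
    to the shared rules.
    """
    if set(reflection_particles) != set(fluorescence_particles):
        raise ValueError(
            "mode tile grids differ: "
            f"{sorted(set(reflection_particles) ^ set(fluorescence_particles))}"
        )
    fl_rules = fluorescence_rules or rules
    per_refl = {k: count_fibers(v, rules)[0] for k, v in reflection_particles.items()}
    per_fluo = {k: count_fibers(v, fl_rules)[0] for k, v in fluorescence_particles.items()}
    return SlideCounts(
        slide_id=slide_id,
        n_tiles=len(per_refl),
        tile_area_mm2=tile_area_mm2,
        total_fibers_reflection=sum(per_refl.values()),
        chrysotile_fibers_fluorescence=sum(per_fluo.values()),
        per_tile_reflection=per_refl,
        per_tile_fluorescence=per_fluo,
    )


def fiber_density(count: int, n_tiles: int, tile_area_mm2: float) -> float:
    """Fiber density in f/mm2: count / (n_tiles x tile_area)."""
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if not tile_area_mm2 > 0:
        raise ValueError("tile_area_mm2 must be positive")
    return count / (n_tiles * tile_area_mm2)


def fiber_concentration(
    density_per_mm2: float, effective_filter_area_mm2: float, air_volume_cc: float
) -> float:
    """Fiber concentration in f/cc, filter-count convention.

    density x effective filter area / sampled air volume.  The filter area
    and air volume are survey-specific configuration, not constants.
    """
    if not effective_filter_area_mm2 > 0:
        raise ValueError("effective filter area must be positive")
    if not air_volume_cc > 0:
        raise ValueError("air volume must be positive")
    return density_per_mm2 * effective_filter_area_mm2 / air_volume_cc


@dataclass(frozen=True)
class BeadSpec:
    """Fluorescent bead suspension: concentration, polymer density, diameter."""

    concentration_g_per_ml: float
    polymer_density_g_per_ml: float = 1.05
    diameter_um: float = 2.0

    def __post_init__(self) -> None:
        for name in ("concentration_g_per_ml", "polymer_density_g_per_ml", "diameter_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def beads_per_ml(spec: BeadSpec) -> float:
    """Theoretical bead number per mL: 6*C*1e12 / (rho*pi*phi^3).

    C in g/mL, rho in g/mL, phi (diameter) in um; each bead has mass
    rho*pi*phi^3/6 x 1e-12 g, so this is just concentration over bead mass.
    """
    return (
        6.0
        * spec.concentration_g_per_ml
        * 1e12
        / (spec.polymer_density_g_per_ml * math.pi * spec.diameter_um**3)
    )


def regression_through_origin(x, y) -> tuple[float, float]:
    """Least-squares slope through the origin and its R^2.

    slope = sum(x*y)/sum(x^2); R^2 = 1 - SS_res/SS_tot with SS_tot taken
    about the mean of y (the common spreadsheet convention for trendlines
    forced through zero intercept is uncentered, but the centered form is
    used here and documented).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with >= 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all x are zero; through-origin slope undefined")
    slope = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return slope, r2


@dataclass
class DilutionReport:
    """Calibration summary of a dilution series."""

    levels: list[tuple[float, float]]  # (relative concentration, mean measured count)
    slope: float
    r_squared: float

    @classmethod
    def from_level_counts(
        cls, expected: list[float], measured_means: list[float]
    ) -> "DilutionReport":
        slope, r2 = regression_through_origin(expected, measured_means)
        return cls(
            levels=list(zip(expected, measured_means)), slope=slope, r_squared=r2
        )

    @classmethod
    def from_replicates(
        cls, expected: list[float], counts_per_level: list[list[float]]
    ) -> "DilutionReport":
        """Average each level over all its replicate slides, then regress.

        Follows the reporting convention of averaging replicate counts at a
        concentration before the calibration fit; when several independent
        series are pooled, all their replicates at a level enter the mean.
        """
        if len(expected) != len(counts_per_level):
            raise ValueError("one replicate list required per level")
        means = [float(np.mean(c)) for c in counts_per_level]
        return cls.from_level_counts(list(expected), means)

    def to_dict(self) -> dict:
        return {
            "levels": [
                {"expected": e, "measured_mean": m} for e, m in self.levels
            ],
            "slope": self.slope,
            "r_squared": self.r_squared,
        }


def manual_comparison_report(auto_counts, manual_counts) -> dict:
    """Percent bias of automatic vs. manual counts.

    Through-origin slope of auto on manual; bias = (slope - 1) x 100 %.
    Series are paired (same slides/areas), already averaged over replicates
    per the reporting convention.
    """
    auto = np.asarray(auto_counts, dtype=float)
    manual = np.asarray(manual_counts, dtype=float)
    if auto.shape != manual.shape:
        raise ValueError("auto and manual series must be paired (equal length)")
    slope, r2 = regression_through_origin(manual, auto)
    return {"slope": slope, "r_squared": r2, "bias_percent": (slope - 1.0) * 100.0}
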