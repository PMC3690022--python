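"""Shape scoring for fiber counting.

The counting rules used in phase-contrast / HTM asbestos analysis (NIOSH 7400)
define a countable fiber by its length (> 5 um) and aspect ratio (>= 3).  In a
particle-analysis pipeline the aspect-ratio criterion is enforced through an
equivalent *circularity* interval: for an ellipse of aspect ratio ``alpha``,
the dimensionless circularity ``4*pi*area/perimeter**2`` is a strictly
decreasing function of ``alpha`` (using Ramanujan's perimeter approximation),

    C(alpha) = 4*alpha / (3*(1 + alpha) - sqrt((3 + alpha)*(1 + 3*alpha)))**2

so ``alpha >= 3`` maps onto ``circularity <= C(3) = 0.663``.  This module
provides the forward relation, its numerical inverse, measured circularity
from area/perimeter, and the fiber-qualification predicate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

from scipy.optimize import brentq

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import Particle

__all__ = [
    "CountingRules",
    "circularity_of_aspect",
    "aspect_of_circularity",
    "measured_circularity",
    "qualifies_as_fiber",
]


def circularity_of_aspect(alpha: float) -> float:
    """Circularity of an ideal ellipse with aspect ratio ``alpha``.

    Uses Ramanujan's first approximation for the ellipse perimeter, which for
    an ellipse with semi-axes ``a = alpha*b`` and ``b`` gives

        P ~ pi * b * (3*(1 + alpha) - sqrt((3 + alpha)*(1 + 3*alpha)))

    and hence ``4*pi*A/P**2`` as above.  Strictly decreasing in ``alpha``;
    equals 1 for a circle (``alpha = 1``).

    Parameters
    ----------
    alpha : float
        Aspect ratio, long axis over short axis; must be >= 1.

    Returns
    -------
    float
        Circularity in (0, 1].
    """
    if not alpha >= 1:
        raise ValueError(f"aspect ratio must be >= 1 (long/short), got {alpha!r}")
    denom = 3.0 * (1.0 + alpha) - math.sqrt((3.0 + alpha) * (1.0 + 3.0 * alpha))
    return 4.0 * alpha / denom**2


def aspect_of_circularity(c: float, xtol: float = 1e-12) -> float:
    """Aspect ratio of the ideal ellipse with circularity ``c``.

    Numerical inverse of :func:`circularity_of_aspect` by monotone bracketing
    (Brent's method); unique because the forward map is strictly decreasing.

    Parameters
    ----------
    c : float
        Circularity in (0, 1].
    xtol : float
        Absolute tolerance on the returned aspect ratio.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError(f"circularity must lie in (0, 1], got {c!r}")
    if c == 1.0:
        return 1.0
    hi = 2.0
    while circularity_of_aspect(hi) > c:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for c > 0
            raise RuntimeError("failed to bracket aspect ratio")
    return float(brentq(lambda a: circularity_of_aspect(a) - c, 1.0, hi, xtol=xtol))


def measured_circularity(area: float, perimeter: float) -> float:
    """Circularity ``4*pi*area/perimeter**2`` of a measured particle.

    Discrete perimeter estimators can under-estimate the true contour length,
    pushing the raw value above 1; such values are clamped to 1 (the standard
    particle-analysis convention).

    Parameters
    ----------
    area : float
        Particle area (any unit; must be consistent with ``perimeter``).
    perimeter : float
        Particle perimeter; same length unit as ``sqrt(area)``.
    """
    if not area > 0:
        raise ValueError(f"area must be positive, got {area!r}")
    if not perimeter > 0:
        raise ValueError(f"perimeter must be positive, got {perimeter!r}")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


@dataclass(frozen=True)
class CountingRules:
    """Fiber-qualification thresholds.

    A particle is counted as a fiber iff its length (fitted-ellipse major
    axis, um) strictly exceeds ``min_length_um``, its circularity lies within
    ``[circularity_min, circularity_max]``, and its pixel area lies within
    ``[area_min_px2, area_max_px2]``.  The aspect-ratio rule (>= 3) is carried
    by the circularity upper bound via the ellipse relation; the fitted
    aspect ratio itself is reported for diagnostics only.
    """

    min_length_um: float = 5.0
    min_aspect_ratio: float = 3.0
    circularity_min: float = 0.0
    circularity_max: float = field(default=0.663)
    area_min_px2: float = 10.0
    area_max_px2: float = 1e5

    def __post_init__(self) -> None:
        if not 0.0 <= self.circularity_min <= self.circularity_max <= 1.0:
            raise ValueError(
                "circularity range must satisfy 0 <= min <= max <= 1, got "
                f"[{self.circularity_min}, {self.circularity_max}]"
            )
        if not self.min_aspect_ratio >= 1:
            raise ValueError("min_aspect_ratio must be >= 1")
        if not self.min_length_um > 0:
            raise ValueError("min_length_um must be > 0")
        if not self.area_min_px2 < self.area_max_px2:
            raise ValueError("area bounds must satisfy min < max")

    @classmethod
    def from_aspect_ratio(
        cls,
        min_aspect_ratio: float = 3.0,
        *,
        min_length_um: float = 5.0,
        area_min_px2: float = 10.0,
        area_max_px2: float = 1e5,
    ) -> "CountingRules":
        """Derive the circularity upper bound from an aspect-ratio threshold."""
        c_max = circularity_of_aspect(min_aspect_ratio)
        return cls(
            min_length_um=min_length_um,
            min_aspect_ratio=min_aspect_ratio,
            circularity_min=0.0,
            circularity_max=c_max,
            area_min_px2=area_min_px2,
            area_max_px2=area_max_px2,
        )

    @classmethod
    def from_config(cls, source: str | Path | dict) -> "CountingRules":
        """Load rules from a JSON file or a plain dict.

        Keys: ``min_length_um``, ``min_aspect_ratio``, ``circularity_min``,
        ``circularity_max`` (the string ``"auto"`` derives it from
        ``min_aspect_ratio``), ``area_min_px2``, ``area_max_px2``.  Missing
        keys fall back to the defaults.
        """
        if isinstance(source, (str, Path)):
            cfg = json.loads(Path(source).read_text())
        else:
            cfg = dict(source)
        min_ar = float(cfg.get("min_aspect_ratio", 3.0))
        c_max = cfg.get("circularity_max", 0.663)
        if c_max == "auto":
            c_max = circularity_of_aspect(min_ar)
        return cls(
            min_length_um=float(cfg.get("min_length_um", 5.0)),
            min_aspect_ratio=min_ar,
            circularity_min=float(cfg.get("circularity_min", 0.0)),
            circularity_max=float(c_max),
            area_min_px2=float(cfg.get("area_min_px2", 10.0)),
            area_max_px2=float(cfg.get("area_max_px2", 1e5)),
        )


def qualifies_as_fiber(particle: "Particle", rules: CountingRules) -> bool:
    """True iff ``particle`` passes all counting thresholds.

    Length must *strictly* exceed the minimum ("longer than 5 um"); the
    circularity and area intervals are inclusive at both ends.
    """
    for name in ("length_um", "circularity", "area_px2"):
        value = getattr(particle, name, None)
        if value is None:
            raise ValueError(f"particle is missing required measurement {name!r}")
    return (
        particle.length_um > rules.min_length_um
        and rules.circularity_min <= particle.circularity <= rules.circularity_max
        and rules.area_min_px2 <= particle.area_px2 <= rules.area_max_px2
    )
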