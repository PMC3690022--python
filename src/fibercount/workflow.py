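"""End-to-end orchestration: generate (optional) -> per-tile pipeline in both
modes -> fiber counting -> slide report, with provenance logging.

The in-memory entry points (:func:`analyze_tiles`, :func:`analyze_slide_pair`)
are what the file-based :func:`run_full_analysis` wraps; tests and scripted
analyses use them directly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as fio
from .counting import DilutionReport, SlideCounts, dual_mode_counts
from .pipeline import (
    DEFAULT_PARAMS,
    PipelineParams,
    TileImage,
    particles_to_frame,
    run_pipeline,
)
from .shapes import CountingRules
from .synthetic import (
    SceneParams,
    SlidePair,
    TileGeometry,
    generate_dilution_series,
    generate_slide,
)

logger = logging.getLogger("fibercount")

__all__ = [
    "analyze_tiles",
    "analyze_slide_pair",
    "run_dilution_calibration",
    "run_full_analysis",
]


def run_dilution_calibration(
    base: SceneParams,
    factors=(1.0, 0.5, 0.25, 0.125),
    n_slides_per_level: int = 3,
    master_seeds=(0,),
    grid: tuple[int, int] = (1, 1),
    geometry: TileGeometry | None = None,
    rules: CountingRules | None = None,
    mode: str = "fluorescence",
) -> DilutionReport:
    """Generate, analyze and calibrate a dilution series.

    Runs the full series for each master seed, counts fibers in the requested
    mode on every slide, averages each concentration level over all replicate
    slides (pooling the seeds), and fits the through-origin calibration line
    of measured vs. expected counts.
    """
    rules = rules or CountingRules()
    factors = list(factors)
    counts_per_level: list[list[float]] = [[] for _ in factors]
    for ms in master_seeds:
        levels = generate_dilution_series(
            base, factors, n_slides_per_level, master_seed=ms, grid=grid, geometry=geometry
        )
        for li, level in enumerate(levels):
            for slide in level.slides:
                counts, _ = analyze_slide_pair(slide, rules)
                n = (
                    counts.chrysotile_fibers_fluorescence
                    if mode == "fluorescence"
                    else counts.total_fibers_reflection
                )
                counts_per_level[li].append(n)
    expected = [base.n_chrysotile * f for f in factors]
    return DilutionReport.from_replicates(expected, counts_per_level)


def analyze_tiles(
    tiles_by_mode: dict[str, list[TileImage]],
    rules: CountingRules,
    params_by_mode: dict[str, PipelineParams] | None = None,
    fluorescence_rules: CountingRules | None = None,
    slide_id: str = "slide",
) -> tuple[SlideCounts, pd.DataFrame]:
    """Run the pipeline on every tile of both modes and aggregate counts.

    Returns the slide-level counts and the concatenated particle table
    (all tiles, both modes, unfiltered).
    """
    params_by_mode = params_by_mode or DEFAULT_PARAMS
    particles: dict[str, dict[tuple[int, int], list]] = {}
    frames = []
    tile_area = None
    for mode, tiles in tiles_by_mode.items():
        per_tile = {}
        for tile in tiles:
            plist = run_pipeline(tile, params_by_mode.get(mode))
            per_tile[tile.tile_index] = plist
            frames.append(particles_to_frame(plist, tile.tile_index, mode))
            ex, ey = tile.extent_um
            tile_area = ex * ey * 1e-6
        particles[mode] = per_tile
        logger.info(
            "mode %s: %d tiles, %d particles",
            mode,
            len(per_tile),
            sum(len(v) for v in per_tile.values()),
        )
    counts = dual_mode_counts(
        particles["reflection"],
        particles["fluorescence"],
        rules,
        tile_area_mm2=tile_area,
        fluorescence_rules=fluorescence_rules,
        slide_id=slide_id,
    )
    frames = [f for f in frames if len(f)]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else particles_to_frame([])
    )
    return counts, table


def analyze_slide_pair(
    slide: SlidePair,
    rules: CountingRules | None = None,
    params_by_mode: dict[str, PipelineParams] | None = None,
    slide_id: str = "slide",
) -> tuple[SlideCounts, pd.DataFrame]:
    """Convenience wrapper for a generated :class:`SlidePair`."""
    rules = rules or CountingRules()
    return analyze_tiles(
        {"reflection": slide.reflection, "fluorescence": slide.fluorescence},
        rules,
        params_by_mode=params_by_mode,
        slide_id=slide_id,
    )


def _scene_from_config(cfg: dict, seed: int | None) -> SceneParams:
    scene_cfg = dict(cfg)
    if seed is not None:
        scene_cfg["seed"] = seed
    allowed = set(SceneParams.__dataclass_fields__)
    unknown = set(scene_cfg) - allowed
    if unknown:
        raise ValueError(f"unknown scene parameters: {sorted(unknown)}")
    if "fiber_width_um" in scene_cfg:
        scene_cfg["fiber_width_um"] = tuple(scene_cfg["fiber_width_um"])
    return SceneParams(**scene_cfg)


def run_full_analysis(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """File-based end-to-end run driven by a JSON-style config.

    The config names either ``input_dir`` (a written slide directory) or
    ``scene`` (synthetic scene parameters; the slide is generated, written
    under ``out_dir/slide``, then analyzed).  Writes ``particles.csv``,
    ``report.json`` and a log; the report echoes the fully resolved
    parameter set and seed.  Identical config + seed give identical outputs.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    has_scene = "scene" in config
    has_input = "input_dir" in config
    if has_scene == has_input:
        raise ValueError("config must name exactly one of 'scene' or 'input_dir'")

    rules = CountingRules.from_config(config.get("rules", {}))
    params_by_mode = dict(DEFAULT_PARAMS)
    for mode, pcfg in config.get("pipeline", {}).items():
        params_by_mode[mode] = PipelineParams(**pcfg)

    registry_frame = None
    if has_scene:
        grid = tuple(config.get("grid", (1, 1)))
        geometry = TileGeometry(pixel_size=config.get("pixel_size", 0.4))
        scene = _scene_from_config(config["scene"], seed)
        slide = generate_slide(scene, grid=grid, geometry=geometry)
        slide_dir = out_dir / "slide"
        fio.write_slide(slide, slide_dir)
        tiles = {"reflection": slide.reflection, "fluorescence": slide.fluorescence}
        registry_frame = slide.registry_frame()
        used_seed = scene.seed
    else:
        pixel_size = config.get("pixel_size")
        if pixel_size is None:
            meta_path = Path(config["input_dir"]) / "scene.json"
            if meta_path.exists():
                pixel_size = json.loads(meta_path.read_text())["pixel_size_um"]
            else:
                raise ValueError("pixel_size required when input slide has no scene.json")
        tiles = fio.read_slide_tiles(config["input_dir"], pixel_size)
        used_seed = seed

    counts, table = analyze_tiles(tiles, rules, params_by_mode)
    fio.write_particle_table(table, out_dir / "particles.csv")

    report = {
        "seed": used_seed,
        "rules": {
            "min_length_um": rules.min_length_um,
            "min_aspect_ratio": rules.min_aspect_ratio,
            "circularity_min": rules.circularity_min,
            "circularity_max": rules.circularity_max,
            "area_min_px2": rules.area_min_px2,
            "area_max_px2": rules.area_max_px2,
        },
        "pipeline": {
            mode: vars(p).copy() for mode, p in params_by_mode.items()
        },
        "counts": counts.to_dict(),
        "config": {k: v for k, v in config.items()},
        "out_dir": str(out_dir),
    }
    if registry_frame is not None:
        report["registry_counts"] = (
            registry_frame["class"].value_counts().to_dict()
        )
    fio.write_json_report(report, out_dir / "report.json")
    logger.info(
        "slide %s: reflection=%d fluorescence=%d",
        counts.slide_id,
        counts.total_fibers_reflection,
        counts.chrysotile_fibers_fluorescence,
    )
    return report
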