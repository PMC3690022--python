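"""Slide-level file layout: tile images, registries, particle tables, reports.

Layout of one written slide::

    <slide_dir>/
      scene.json                  # generator parameters (when synthetic)
      registry.csv                # ground-truth registry (when synthetic)
      reflection/r{row}_c{col}.tif
      fluorescence/r{row}_c{col}.tif

Tiles are 16-bit grayscale TIFF by default (8/16-bit PNG also readable).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .pipeline import TileImage
from .synthetic import SlidePair

_TILE_RE = re.compile(r"r(\d+)_c(\d+)\.(tif|tiff|png)$")

MODES = ("reflection", "fluorescence")


def read_tile_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_tile_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def write_slide(slide: SlidePair, slide_dir: str | Path, fmt: str = "tif") -> Path:
    """Write both tile grids, the registry CSV and the seed header."""
    slide_dir = Path(slide_dir)
    for mode, tiles in (("reflection", slide.reflection), ("fluorescence", slide.fluorescence)):
        mode_dir = slide_dir / mode
        mode_dir.mkdir(parents=True, exist_ok=True)
        for t in tiles:
            r, c = t.tile_index
            write_tile_image(mode_dir / f"r{r}_c{c}.{fmt}", t.pixels)
    reg = slide.registry_frame()
    reg_path = slide_dir / "registry.csv"
    with open(reg_path, "w") as fh:
        fh.write(f"# master_seed={slide.seed}\n")
        reg.to_csv(fh, index=False)
    meta = {
        "seed": slide.seed,
        "grid": list(slide.grid),
        "pixel_size_um": slide.geometry.pixel_size,
        "tile_extent_um": list(slide.geometry.extent_um),
    }
    (slide_dir / "scene.json").write_text(json.dumps(meta, indent=2))
    return slide_dir


def read_slide_tiles(
    slide_dir: str | Path, pixel_size: float, modes: tuple[str, ...] = MODES
) -> dict[str, list[TileImage]]:
    """Read the tile grids of a written slide back into TileImage lists."""
    slide_dir = Path(slide_dir)
    out: dict[str, list[TileImage]] = {}
    for mode in modes:
        mode_dir = slide_dir / mode
        if not mode_dir.is_dir():
            raise FileNotFoundError(f"missing mode directory {mode_dir}")
        tiles = []
        for path in sorted(mode_dir.iterdir()):
            m = _TILE_RE.search(path.name)
            if not m:
                continue
            r, c = int(m.group(1)), int(m.group(2))
            pixels = read_tile_image(path)
            tiles.append(
                TileImage(
                    pixels=pixels,
                    pixel_size=pixel_size,
                    mode=mode,  # type: ignore[arg-type]
                    bit_depth=16 if pixels.dtype.itemsize > 1 else 8,
                    tile_index=(r, c),
                    stage_position=(
                        c * pixels.shape[1] * pixel_size,
                        r * pixels.shape[0] * pixel_size,
                    ),
                )
            )
        tiles.sort(key=lambda t: t.tile_index)
        out[mode] = tiles
    shapes = {m: sorted(t.tile_index for t in ts) for m, ts in out.items()}
    grids = set(tuple(v) for v in shapes.values())
    if len(grids) > 1:
        raise ValueError(f"mode grids of unequal shape: {shapes}")
    return out


def read_registry(slide_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(slide_dir) / "registry.csv", comment="#")


def write_particle_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
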