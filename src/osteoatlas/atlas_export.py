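"""Static slippy-map export of panoramas with annotated cell pins.

Replaces a hosted web-maps layer with a viewer-agnostic tile pyramid: the
panorama at native resolution is the deepest zoom level, each coarser level
is a 2x area-averaged reduction, and every level is cut into fixed-size
tiles written as ``tiles/{z}/{x}/{y}.png``.  The plane is flat specimen
space (XYZ scheme, y down) — no map projection is involved.

Pins mark classified cells: green for viable, red for pyknotic, shown only
above a display confidence floor (strictly greater than 70% by default).
They are exported as a GeoJSON FeatureCollection in normalized map
coordinates plus a CSV mirror; the normalized <-> native transforms are
exact inverses up to float quantization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import CellRecord
from .geometry import Panorama

__all__ = [
    "TilePyramid",
    "PyramidLevel",
    "Pin",
    "PinSet",
    "pyramid_levels",
    "build_tile_pyramid",
    "write_pyramid",
    "display_filter",
    "export_pins",
    "export_atlas",
]

PIN_COLORS = {"viable": "#2ca02c", "pyknotic": "#d62728"}


@dataclass(frozen=True)
class PyramidLevel:
    zoom: int
    width: int
    height: int
    tiles_x: int
    tiles_y: int


@dataclass
class TilePyramid:
    """All zoom levels of one panorama; images held in memory until written."""

    levels: list[PyramidLevel]
    images: list[np.ndarray]
    tile_size: int
    background: int = 200

    @property
    def max_zoom(self) -> int:
        return self.levels[-1].zoom

    @property
    def native_size(self) -> tuple[int, int]:
        lv = self.levels[-1]
        return lv.width, lv.height


@dataclass(frozen=True)
class Pin:
    cell_id: int
    x_px: float
    y_px: float
    status: str
    p: float
    n_processes: Optional[int] = None


@dataclass
class PinSet:
    pins: list[Pin]
    display_floor: float = 0.7

    def __len__(self) -> int:
        return len(self.pins)


def pyramid_levels(width: int, height: int, tile_size: int = 256) -> list[PyramidLevel]:
    """Pure level arithmetic: grid dimensions per zoom, without pixels.

    ``max_zoom = ceil(log2(max_dim / tile_size))`` (clamped at 0); level z-1
    image dimensions are ``ceil(level-z dims / 2)``, so level-0 always fits
    in a single tile and grid dims satisfy the same halving law.
    """
    if width < 1 or height < 1:
        raise ValueError("panorama dimensions must be positive")
    max_zoom = max(0, math.ceil(math.log2(max(width, height) / tile_size)))
    dims = [(width, height)]
    for _ in range(max_zoom):
        w, h = dims[-1]
        dims.append((math.ceil(w / 2), math.ceil(h / 2)))
    dims.reverse()  # index by zoom: 0 .. max_zoom
    return [
        PyramidLevel(
            zoom=z,
            width=w,
            height=h,
            tiles_x=math.ceil(w / tile_size),
            tiles_y=math.ceil(h / tile_size),
        )
        for z, (w, h) in enumerate(dims)
    ]


def _halve(img: np.ndarray, background: int) -> np.ndarray:
    """2x area-averaged reduction; odd edges padded with background."""
    h, w = img.shape
    ph, pw = h + (h & 1), w + (w & 1)
    if (ph, pw) != (h, w):
        padded = np.full((ph, pw), background, dtype=np.float64)
        padded[:h, :w] = img
    else:
        padded = img.astype(np.float64)
    blocks = padded.reshape(ph // 2, 2, pw // 2, 2).mean(axis=(1, 3))
    return np.clip(np.rint(blocks), 0, 255).astype(np.uint8)


def build_tile_pyramid(
    pano: Panorama | np.ndarray, tile_size: int = 256, background: int = 200
) -> TilePyramid:
    """Build every zoom level of the pyramid from the native panorama."""
    img = pano.pixels if isinstance(pano, Panorama) else np.asarray(pano, dtype=np.uint8)
    if img.size == 0:
        raise ValueError("cannot build a pyramid from an empty panorama")
    levels = pyramid_levels(img.shape[1], img.shape[0], tile_size)
    images = [img]
    for _ in range(len(levels) - 1):
        images.append(_halve(images[-1], background))
    images.reverse()  # index by zoom
    return TilePyramid(levels=levels, images=images, tile_size=tile_size, background=background)


def write_pyramid(pyr: TilePyramid, out_dir: str | Path) -> int:
    """Write ``tiles/{z}/{x}/{y}.png``; edge tiles padded with background.

    Returns the number of tiles written.
    """
    out = Path(out_dir)
    n = 0
    ts = pyr.tile_size
    for level, img in zip(pyr.levels, pyr.images):
        for tx in range(level.tiles_x):
            for ty in range(level.tiles_y):
                tile = np.full((ts, ts), pyr.background, dtype=np.uint8)
                sub = img[ty * ts : (ty + 1) * ts, tx * ts : (tx + 1) * ts]
                tile[: sub.shape[0], : sub.shape[1]] = sub
                d = out / "tiles" / str(level.zoom) / str(tx)
                d.mkdir(parents=True, exist_ok=True)
                iio.imwrite(d / f"{ty}.png", tile)
                n += 1
    return n


def display_filter(cells: Sequence[CellRecord], floor: float = 0.7) -> PinSet:
    """Pins for confidently classified cells: strictly p > floor.

    Unsegmentable and ghost-suspect records never receive a pin.
    """
    pins = []
    for i, c in enumerate(cells):
        if c.status is None or c.ghost_suspect:
            continue
        if c.detection.p > floor:
            pins.append(
                Pin(
                    cell_id=i,
                    x_px=c.detection.X,
                    y_px=c.detection.Y,
                    status=c.status,
                    p=c.detection.p,
                    n_processes=c.n_processes,
                )
            )
    return PinSet(pins=pins, display_floor=floor)


def export_pins(pins: PinSet, pyramid: TilePyramid, out_dir: str | Path) -> tuple[Path, Path]:
    """Write pins as GeoJSON (normalized map coordinates) plus a CSV mirror.

    Normalized coordinates are native px divided by the native panorama
    dimensions, so (0.5, 0.5) is the panorama centre and the round trip back
    to pixels is exact to float precision.  A pin outside the panorama is a
    hard error naming the cell.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w, h = pyramid.native_size
    features = []
    rows = []
    for pin in pins.pins:
        if not (0.0 <= pin.x_px <= w and 0.0 <= pin.y_px <= h):
            raise ValueError(
                f"pin for cell {pin.cell_id} at ({pin.x_px:.1f}, {pin.y_px:.1f}) "
                f"lies outside the {w}x{h} panorama"
            )
        xn, yn = pin.x_px / w, pin.y_px / h
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [xn, yn]},
                "properties": {
                    "cell_id": pin.cell_id,
                    "status": pin.status,
                    "p": pin.p,
                    "n_processes": pin.n_processes,
                    "color": PIN_COLORS.get(pin.status, "#7f7f7f"),
                },
            }
        )
        rows.append(
            {
                "cell_id": pin.cell_id,
                "x_px": pin.x_px,
                "y_px": pin.y_px,
                "x_norm": xn,
                "y_norm": yn,
                "status": pin.status,
                "p": pin.p,
                "n_processes": pin.n_processes if pin.n_processes is not None else -1,
            }
        )
    geojson_path = out / "pins.geojson"
    geojson_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    csv_path = out / "pins.csv"
    pd.DataFrame(
        rows,
        columns=["cell_id", "x_px", "y_px", "x_norm", "y_norm", "status", "p", "n_processes"],
    ).to_csv(csv_path, index=False)
    return geojson_path, csv_path


_VIEWER_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>osteoatlas</title></head>
<body style="margin:0;background:#111;color:#eee;font-family:sans-serif">
<p style="padding:1em">Static tile pyramid under <code>tiles/{z}/{x}/{y}.png</code>;
pins in <code>pins.geojson</code> (green = viable, red = pyknotic).
Point any slippy-map viewer at this directory.</p>
</body></html>
"""


def export_atlas(
    pano: Panorama,
    cells: Sequence[CellRecord],
    out_dir: str | Path,
    tile_size: int = 256,
    display_floor: float = 0.7,
) -> TilePyramid:
    """One-call export: pyramid tiles, filtered pins, and a stub viewer page."""
    out = Path(out_dir)
    pyr = build_tile_pyramid(pano, tile_size=tile_size)
    write_pyramid(pyr, out)
    pins = display_filter(cells, floor=display_floor)
    export_pins(pins, pyr, out)
    (out / "index.html").write_text(_VIEWER_PAGE)
    return pyr
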