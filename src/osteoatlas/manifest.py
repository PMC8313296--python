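"""Tile manifests: the hand-off format between acquisition, phantom and stitching.

A manifest lists one record per beam image with its recorded stage
coordinates in panorama pixels.  Records may reference a file on disk
(``path``) or carry their raster in memory (``data``); the stitcher accepts
either, so phantom round-trip tests never touch the filesystem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

MANIFEST_COLUMNS = ["tile_id", "mfov", "beam", "x_px", "y_px", "width", "height", "path"]


@dataclass
class TileRecord:
    """One per-beam image with its recorded panorama-frame offset."""

    tile_id: str
    mfov: int
    beam: int
    x_px: int
    y_px: int
    width: int
    height: int
    path: Optional[str] = None
    data: Optional[np.ndarray] = field(default=None, repr=False)

    def load(self, root: Optional[Path] = None) -> np.ndarray:
        """Return the tile raster, reading from ``path`` if not in memory."""
        if self.data is not None:
            return self.data
        if self.path is None:
            raise FileNotFoundError(f"tile {self.tile_id!r} has neither data nor path")
        p = Path(self.path)
        if root is not None and not p.is_absolute():
            p = root / p
        if not p.exists():
            raise FileNotFoundError(f"tile {self.tile_id!r}: missing file {p}")
        return tifffile.imread(p)


@dataclass
class TileManifest:
    tiles: list[TileRecord]
    pixel_size_nm: float = 12.0
    root: Optional[Path] = None

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tile_id": t.tile_id,
                "mfov": t.mfov,
                "beam": t.beam,
                "x_px": t.x_px,
                "y_px": t.y_px,
                "width": t.width,
                "height": t.height,
                "path": t.path if t.path is not None else "",
            }
            for t in self.tiles
        ]
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "pixel_size_nm": self.pixel_size_nm,
            "tiles": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, pixel_size_nm: float = 12.0, root: Optional[Path] = None
    ) -> "TileManifest":
        tiles = [
            TileRecord(
                tile_id=str(r.tile_id),
                mfov=int(r.mfov),
                beam=int(r.beam),
                x_px=int(r.x_px),
                y_px=int(r.y_px),
                width=int(r.width),
                height=int(r.height),
                path=(str(r.path) if isinstance(r.path, str) and r.path else None),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(tiles=tiles, pixel_size_nm=pixel_size_nm, root=root)

    @classmethod
    def read_csv(cls, path: str | Path, pixel_size_nm: float = 12.0) -> "TileManifest":
        frame = pd.read_csv(path, keep_default_na=False)
        return cls.from_frame(frame, pixel_size_nm=pixel_size_nm, root=Path(path).parent)

    @classmethod
    def read_json(cls, path: str | Path) -> "TileManifest":
        payload = json.loads(Path(path).read_text())
        frame = pd.DataFrame(payload["tiles"], columns=MANIFEST_COLUMNS)
        return cls.from_frame(
            frame, pixel_size_nm=float(payload.get("pixel_size_nm", 12.0)), root=Path(path).parent
        )


def tile_filename(mfov: int, beam: int) -> str:
    return f"m{mfov:05d}_b{beam:02d}.tif"


def write_tiles(manifest: TileManifest, out_dir: str | Path) -> TileManifest:
    """Materialize in-memory tiles as 8-bit greyscale TIFFs under ``out_dir``.

    Returns a new manifest whose records reference the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiles = []
    for t in manifest:
        name = tile_filename(t.mfov, t.beam)
        tifffile.imwrite(out / name, np.asarray(t.load(), dtype=np.uint8))
        tiles.append(
            TileRecord(
                tile_id=t.tile_id,
                mfov=t.mfov,
                beam=t.beam,
                x_px=t.x_px,
                y_px=t.y_px,
                width=t.width,
                height=t.height,
                path=name,
                data=None,
            )
        )
    return TileManifest(tiles=tiles, pixel_size_nm=manifest.pixel_size_nm, root=out)
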