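"""Acquisition geometry accounting and mosaic preprocessing.

Multibeam SEM acquires one multibeam field of view (mFOV) per stage position;
an array of beams (61 on the prototype used here as the default) images the
mFOV simultaneously, each beam producing one tile.  This module carries the
bookkeeping that relates mFOV counts to image counts and storage, and the
"Module A" preprocessing: stitching per-beam tiles into a region-wide
panorama by their recorded stage coordinates, then downscaling so a cell
occupies roughly 200 px for the detector.

Stitching is a pure copy at recorded offsets (last writer wins in overlaps by
default); no cross-correlation refinement is attempted, matching the
coordinate-based mosaicking of the acquisition software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from skimage.transform import resize

from .manifest import TileManifest

__all__ = [
    "AcquisitionGeometry",
    "Panorama",
    "expected_tile_count",
    "storage_estimate",
    "stitch",
    "downscale_for_detection",
    "hex_beam_offsets",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Static description of one acquisition configuration.

    ``overlap_px`` is the nominal overlap between neighbouring tiles in the
    panorama frame; the tiling stride is ``tile - overlap``.
    """

    beams_per_mfov: int = 61
    tile_width_px: int = 512
    tile_height_px: int = 512
    pixel_size_nm: float = 12.0
    overlap_px: int = 32
    mfov_layout: Literal["hexagonal", "rectangular"] = "rectangular"
    n_mfov: int = 1

    def __post_init__(self) -> None:
        if self.beams_per_mfov < 1:
            raise ValueError("beams_per_mfov must be >= 1")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.overlap_px < 0 or self.overlap_px >= min(self.tile_width_px, self.tile_height_px):
            raise ValueError("overlap_px must be in [0, min(tile dims))")
        if self.n_mfov < 0:
            raise ValueError("n_mfov must be >= 0")

    @property
    def total_tiles(self) -> int:
        return expected_tile_count(self.n_mfov, self.beams_per_mfov)

    @property
    def stride_x(self) -> int:
        return self.tile_width_px - self.overlap_px

    @property
    def stride_y(self) -> int:
        return self.tile_height_px - self.overlap_px


@dataclass
class Panorama:
    """A stitched greyscale mosaic with its physical pixel size."""

    pixels: np.ndarray
    origin_offset: tuple[int, int] = (0, 0)
    pixel_size_nm: float = 12.0
    provenance: Optional[str] = None

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def expected_tile_count(n_mfov: int, beams_per_mfov: int) -> int:
    """Total number of beam images for ``n_mfov`` multibeam fields of view.

    Exact integer accounting: each mFOV yields one tile per beam.
    """
    if n_mfov < 0 or beams_per_mfov < 0:
        raise ValueError("tile counts require non-negative inputs")
    return int(n_mfov) * int(beams_per_mfov)


def storage_estimate(total_pixels: float, bytes_per_pixel: int = 1) -> float:
    """Raw storage in terabytes (1 TB = 1e12 bytes) for a pixel count.

    Greyscale mSEM output is 1 byte/px; megapixel counts should be converted
    to pixels (x 1e6) before calling.
    """
    if total_pixels < 0 or bytes_per_pixel < 0:
        raise ValueError("storage estimate requires non-negative inputs")
    return float(total_pixels) * float(bytes_per_pixel) / 1e12


def hex_beam_offsets(
    beams_per_mfov: int, pitch_x: float, pitch_y: float
) -> list[tuple[float, float]]:
    """Per-beam centre offsets for a hexagonal mFOV, in ring order.

    Ring order: 1 central beam, then concentric hexagonal rings of
    6, 12, 18, 24, ... beams (1 + 6 + 12 + 18 + 24 = 61 for the prototype).
    Offsets are in panorama pixels given the beam pitches.
    """
    if beams_per_mfov < 1:
        raise ValueError("beams_per_mfov must be >= 1")
    offsets: list[tuple[float, float]] = [(0.0, 0.0)]
    ring = 1
    while len(offsets) < beams_per_mfov:
        n_in_ring = 6 * ring
        for k in range(n_in_ring):
            theta = 2.0 * math.pi * k / n_in_ring
            offsets.append((ring * pitch_x * math.cos(theta), ring * pitch_y * math.sin(theta)))
            if len(offsets) == beams_per_mfov:
                break
        ring += 1
    return offsets


def stitch(
    manifest: TileManifest,
    blend: Literal["last", "mean"] = "last",
    fill_value: int = 0,
) -> Panorama:
    """Compose tiles into a panorama at their recorded coordinates.

    Overlap handling: ``"last"`` (default) copies tiles in manifest order so
    the later-indexed tile wins; ``"mean"`` averages contributions.  No
    resampling or registration is performed.  A missing tile file is a hard
    error naming the tile; duplicate recorded origins raise a warning only.
    """
    if len(manifest) == 0:
        raise ValueError("cannot stitch an empty manifest")
    xs0 = min(t.x_px for t in manifest)
    ys0 = min(t.y_px for t in manifest)
    xs1 = max(t.x_px + t.width for t in manifest)
    ys1 = max(t.y_px + t.height for t in manifest)

    seen_origins: set[tuple[int, int]] = set()
    for t in manifest:
        o = (t.x_px, t.y_px)
        if o in seen_origins:
            warnings.warn(f"tile {t.tile_id!r} duplicates recorded origin {o}", stacklevel=2)
        seen_origins.add(o)

    h, w = ys1 - ys0, xs1 - xs0
    if blend == "mean":
        acc = np.zeros((h, w), dtype=np.float64)
        cnt = np.zeros((h, w), dtype=np.int32)
        for t in manifest:
            img = np.asarray(t.load(manifest.root))
            sy, sx = t.y_px - ys0, t.x_px - xs0
            acc[sy : sy + t.height, sx : sx + t.width] += img
            cnt[sy : sy + t.height, sx : sx + t.width] += 1
        out = np.full((h, w), fill_value, dtype=np.uint8)
        mask = cnt > 0
        out[mask] = np.rint(acc[mask] / cnt[mask]).astype(np.uint8)
    else:
        out = np.full((h, w), fill_value, dtype=np.uint8)
        for t in manifest:
            img = np.asarray(t.load(manifest.root))
            sy, sx = t.y_px - ys0, t.x_px - xs0
            out[sy : sy + t.height, sx : sx + t.width] = img
    return Panorama(
        pixels=out,
        origin_offset=(xs0, ys0),
        pixel_size_nm=manifest.pixel_size_nm,
        provenance=str(manifest.root) if manifest.root else "in-memory manifest",
    )


def downscale_for_detection(
    pano: Panorama, native_cell_px: float, target_cell_px: float = 200.0
) -> tuple[Panorama, float]:
    """Area-average the panorama so a cell occupies ~``target_cell_px``.

    Returns the (possibly identical) panorama and the applied scale,
    ``scale = min(1, target/native)``; upsampling is never performed.  The
    returned panorama records the composite pixel size
    ``pixel_size_nm / scale``.
    """
    if native_cell_px <= 0 or target_cell_px <= 0:
        raise ValueError("cell sizes must be positive")
    scale = min(1.0, float(target_cell_px) / float(native_cell_px))
    if scale == 1.0:
        return pano, 1.0
    new_shape = (
        max(1, int(round(pano.height * scale))),
        max(1, int(round(pano.width * scale))),
    )
    small = resize(
        pano.pixels.astype(np.float64),
        new_shape,
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return (
        Panorama(
            pixels=np.clip(np.rint(small), 0, 255).astype(np.uint8),
            origin_offset=pano.origin_offset,
            pixel_size_nm=pano.pixel_size_nm / scale,
            provenance=pano.provenance,
        ),
        scale,
    )
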