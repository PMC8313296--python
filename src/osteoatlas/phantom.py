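"""Synthetic multibeam-SEM phantoms of osteocyte fields with ground truth.

The phantom emulates a carbon-coated, etched PMMA block face imaged by
backscatter: light resin background, dark elliptical osteocyte somata, and
thin radial dendritic processes.  Viable cells carry three or more visible
processes, pyknotic cells fewer than three; "ghost osteocytes" are
resin-filled empty lacunae rendered as a smooth outline with no processes
and no interior texture.  Every generated panorama comes with a per-cell
ground-truth table, so detection, classification and network stages can be
benchmarked without any acquired data.

All randomness flows through one ``numpy`` generator seeded from the spec;
identical (spec, geometry) inputs produce byte-identical tiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .geometry import AcquisitionGeometry, Panorama
from .manifest import TileManifest, TileRecord, write_tiles

__all__ = [
    "PhantomSpec",
    "GroundTruthCell",
    "PlacementError",
    "render_cell",
    "generate_phantom",
    "generate_phantom_panorama",
    "tile_partition",
    "write_ground_truth",
    "read_ground_truth",
]

CellStatus = Literal["viable", "pyknotic", "ghost"]

# Grey-level conventions for 8-bit backscatter-like contrast.
SOMA_LEVEL = 60.0
NUCLEUS_LEVEL = 25.0
PROCESS_LEVEL = 60.0
GHOST_RIM_LEVEL = 100.0
GHOST_FILL_LEVEL = 150.0

#: Minimum angular separation between rendered processes (degrees).
MIN_PROCESS_SEPARATION_DEG = 20.0

#: Nominal square bounding-box side for a whole cell (soma + processes), px.
CELL_BOX_PX = 96


class PlacementError(RuntimeError):
    """Raised when the requested cell count exceeds packing capacity."""


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic osteocyte field.

    ``viable_fraction`` defaults to 600/650, the composition of the manual
    pretraining set (600 living, 50 pyknotic); ``ghost_fraction`` is the
    probability that a lacuna is an empty, resin-filled ghost.  Process
    counts are drawn conditioned on status: viable cells draw uniformly from
    {3..8}, pyknotic from {0..2}.
    """

    n_cells: int = 200
    viable_fraction: float = 600.0 / 650.0
    ghost_fraction: float = 0.05
    soma_axes_px: tuple[float, float] = (20.0, 12.0)
    process_length_px: float = 40.0
    noise_sd: float = 8.0
    background_level: float = 200.0
    seed: int = 0
    distractors: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.viable_fraction <= 1.0):
            raise ValueError("viable_fraction must be in [0, 1]")
        if not (0.0 <= self.ghost_fraction <= 1.0):
            raise ValueError("ghost_fraction must be in [0, 1]")
        if min(self.soma_axes_px) <= 0 or self.process_length_px < 0:
            raise ValueError("geometric sizes must be positive")

    @property
    def min_spacing_px(self) -> float:
        # Non-overlapping somata: twice the largest full soma axis.
        return 2.0 * max(self.soma_axes_px)

    @property
    def cell_extent_px(self) -> float:
        """Full footprint diameter of a rendered cell (soma + processes)."""
        return 2.0 * (self.process_length_px + max(self.soma_axes_px) / 2.0) + 8.0


@dataclass(frozen=True)
class GroundTruthCell:
    """Known truth for one rendered lacuna, in panorama pixel coordinates."""

    id: int
    center: tuple[float, float]
    bbox: tuple[float, float, float, float]  # (X, Y, W, H), centre format
    n_processes: int
    status: CellStatus

    def __post_init__(self) -> None:
        _, _, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError("bbox extents must be positive")
        if self.status == "ghost":
            if self.n_processes != 0:
                raise ValueError("ghost cells carry no processes")
        elif (self.status == "viable") != (self.n_processes >= 3):
            raise ValueError("status must match the 3-process rule")


def _sample_process_angles(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random ray angles (radians) with pairwise separation >= 20 degrees."""
    min_sep = math.radians(MIN_PROCESS_SEPARATION_DEG)
    for _ in range(2000):
        ang = np.sort(rng.uniform(0.0, 2.0 * math.pi, size=n))
        if n < 2:
            return ang
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2.0 * math.pi]]))
        if gaps.min() >= min_sep:
            return ang
    # Deterministic fallback: evenly spaced with a random phase.
    phase = rng.uniform(0.0, 2.0 * math.pi)
    return np.sort((phase + np.arange(n) * 2.0 * math.pi / max(n, 1)) % (2.0 * math.pi))


def _ellipse_radius(a: float, b: float, theta: float) -> float:
    """Boundary radius of an axis-aligned ellipse at polar angle theta."""
    c, s = math.cos(theta), math.sin(theta)
    return (a * b) / math.sqrt((b * c) ** 2 + (a * s) ** 2)


def render_cell(
    status: CellStatus,
    n_processes: int,
    orientation: float = 0.0,
    spec: Optional[PhantomSpec] = None,
    ray_angles: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Render one cell on a background patch (uint8, no noise).

    The soma is a dark ellipse at ``orientation`` (radians); viable and
    pyknotic cells carry a darker nucleus blob and ``n_processes`` thin rays
    at distinct angles (>= 20 degrees apart; evenly spaced by default).
    Ghosts render as a smooth resin-filled lacuna outline with no rays.
    """
    spec = spec or PhantomSpec()
    if n_processes < 0 or n_processes > 8:
        raise ValueError("n_processes must be in 0..8")
    if status == "ghost" and n_processes != 0:
        raise ValueError("ghost cells have no processes")
    if status == "viable" and n_processes < 3:
        raise ValueError("viable cells require >= 3 processes")
    if status == "pyknotic" and n_processes >= 3:
        raise ValueError("pyknotic cells require < 3 processes")

    a = spec.soma_axes_px[0] / 2.0  # semi-major
    b = spec.soma_axes_px[1] / 2.0  # semi-minor
    side = int(math.ceil(spec.cell_extent_px)) | 1  # odd side, centred cell
    c0 = side // 2
    patch = np.full((side, side), spec.background_level, dtype=np.float64)

    if status == "ghost":
        rr, cc = draw_ellipse(c0, c0, b, a, shape=patch.shape, rotation=-orientation)
        patch[rr, cc] = GHOST_FILL_LEVEL
        outer = np.zeros_like(patch, dtype=bool)
        outer[rr, cc] = True
        rr_i, cc_i = draw_ellipse(c0, c0, b - 2.0, a - 2.0, shape=patch.shape, rotation=-orientation)
        inner = np.zeros_like(outer)
        inner[rr_i, cc_i] = True
        patch[outer & ~inner] = GHOST_RIM_LEVEL
        return np.clip(np.rint(patch), 0, 255).astype(np.uint8)

    # Processes first so the soma overwrites their roots cleanly.
    if ray_angles is None:
        ray_angles = (orientation + np.arange(n_processes) * 2.0 * math.pi / max(n_processes, 1)) % (
            2.0 * math.pi
        )
    ray_angles = np.asarray(ray_angles, dtype=float)
    if len(ray_angles) != n_processes:
        raise ValueError("ray_angles length must equal n_processes")
    ray_mask = np.zeros((side, side), dtype=bool)
    for theta in ray_angles:
        r0 = _ellipse_radius(a, b, theta - orientation) - 2.0
        r1 = r0 + spec.process_length_px + 2.0
        y0 = int(round(c0 + r0 * math.sin(theta)))
        x0 = int(round(c0 + r0 * math.cos(theta)))
        y1 = int(round(c0 + r1 * math.sin(theta)))
        x1 = int(round(c0 + r1 * math.cos(theta)))
        y0, x0 = np.clip(y0, 0, side - 1), np.clip(x0, 0, side - 1)
        y1, x1 = np.clip(y1, 0, side - 1), np.clip(x1, 0, side - 1)
        rr, cc = draw_line(y0, x0, y1, x1)
        ray_mask[rr, cc] = True
    if n_processes:
        ray_mask = dilation(ray_mask, disk(1))
        patch[ray_mask] = PROCESS_LEVEL

    rr, cc = draw_ellipse(c0, c0, b, a, shape=patch.shape, rotation=-orientation)
    patch[rr, cc] = SOMA_LEVEL
    # Nucleus: central darker blob; gives real cells the interior texture
    # that distinguishes them from smooth ghost fills.
    rr, cc = draw_ellipse(c0, c0, b * 0.5, a * 0.4, shape=patch.shape, rotation=-orientation)
    patch[rr, cc] = NUCLEUS_LEVEL
    return np.clip(np.rint(patch), 0, 255).astype(np.uint8)


def _panorama_grid(geom: AcquisitionGeometry) -> tuple[int, int]:
    """Near-square (rows, cols) factorization of the total tile count."""
    total = geom.total_tiles
    if total < 1:
        raise ValueError("geometry must define >= 1 mFOV with >= 1 beam")
    best = (total, 1)
    for cols in range(1, int(math.isqrt(total)) + 1):
        if total % cols == 0:
            best = (total // cols, cols)
    rows, cols = best
    return (rows, cols) if rows >= cols else (cols, rows)


def _panorama_shape(geom: AcquisitionGeometry) -> tuple[int, int]:
    rows, cols = _panorama_grid(geom)
    h = geom.tile_height_px + (rows - 1) * geom.stride_y
    w = geom.tile_width_px + (cols - 1) * geom.stride_x
    return h, w


def generate_phantom_panorama(
    spec: PhantomSpec, geom: AcquisitionGeometry
) -> tuple[Panorama, list[GroundTruthCell]]:
    """Render the full phantom panorama and its ground truth, in memory.

    Cell centres are uniform over the admissible interior (rejection-sampled
    for the minimum spacing), statuses drawn per the viable/ghost fractions,
    process counts conditioned on status, then additive Gaussian noise over
    the whole field.  Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = _panorama_shape(geom)
    margin = spec.cell_extent_px / 2.0 + 4.0
    if spec.n_cells > 0 and (w <= 2 * margin or h <= 2 * margin):
        raise PlacementError("panorama too small for any full cell")

    # Placement: uniform with hard-core rejection for the minimum spacing.
    centers: list[tuple[float, float]] = []
    min_sp2 = spec.min_spacing_px**2
    attempts_left = 2000 * max(spec.n_cells, 1)
    while len(centers) < spec.n_cells:
        if attempts_left <= 0:
            raise PlacementError(
                f"could not place {spec.n_cells} cells with spacing "
                f"{spec.min_spacing_px:.0f} px in a {w}x{h} panorama"
            )
        attempts_left -= 1
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sp2 for px, py in centers):
            centers.append((cx, cy))

    cells: list[GroundTruthCell] = []
    pano = np.full((h, w), spec.background_level, dtype=np.float64)
    for i, (cx, cy) in enumerate(centers):
        is_ghost = rng.uniform() < spec.ghost_fraction
        if is_ghost:
            status: CellStatus = "ghost"
            n_proc = 0
        else:
            viable = rng.uniform() < spec.viable_fraction
            status = "viable" if viable else "pyknotic"
            n_proc = int(rng.integers(3, 9)) if viable else int(rng.integers(0, 3))
        orientation = rng.uniform(0.0, math.pi)
        angles = _sample_process_angles(n_proc, rng) if n_proc else np.empty(0)
        patch = render_cell(status, n_proc, orientation, spec, ray_angles=angles).astype(np.float64)
        side = patch.shape[0]
        y0 = int(round(cy)) - side // 2
        x0 = int(round(cx)) - side // 2
        region = pano[y0 : y0 + side, x0 : x0 + side]
        # Dark features win where cells' processes cross.
        np.minimum(region, patch, out=region)
        cells.append(
            GroundTruthCell(
                id=i,
                center=(cx, cy),
                bbox=(cx, cy, float(CELL_BOX_PX), float(CELL_BOX_PX)),
                n_processes=n_proc,
                status=status,
            )
        )

    if spec.distractors:
        # Blood-vessel / bone-lining-like clutter: large faint ellipses that
        # stress the detector but carry no ground-truth entry.
        for _ in range(max(1, spec.n_cells // 10)):
            dy = rng.uniform(margin, h - margin)
            dx = rng.uniform(margin, w - margin)
            rot = rng.uniform(0.0, math.pi)
            rr, cc = draw_ellipse(dy, dx, 20.0, 45.0, shape=pano.shape, rotation=-rot)
            pano[rr, cc] = np.minimum(pano[rr, cc], 170.0)

    if spec.noise_sd > 0:
        pano = pano + rng.normal(0.0, spec.noise_sd, size=pano.shape)
    pixels = np.clip(np.rint(pano), 0, 255).astype(np.uint8)
    return (
        Panorama(pixels=pixels, pixel_size_nm=geom.pixel_size_nm, provenance="phantom"),
        cells,
    )


def tile_partition(panorama: Panorama, geom: AcquisitionGeometry) -> TileManifest:
    """Cut a panorama into overlapping tiles with recorded coordinates.

    Tiles are laid on a stride grid (stride = tile - overlap); the final
    row/column is shifted inward so the union of footprints equals the
    panorama exactly.  Overlap regions are copies, so a subsequent stitch is
    pixel-identical.  Beam/mFOV ids are assigned by chunking tiles in
    row-major order into groups of ``beams_per_mfov``.
    """
    h, w = panorama.pixels.shape
    tw, th = geom.tile_width_px, geom.tile_height_px
    if w < tw or h < th:
        raise ValueError("panorama must be at least one tile in size")

    def _origins(extent: int, tile: int, stride: int) -> list[int]:
        if extent == tile:
            return [0]
        n = math.ceil((extent - tile) / stride) + 1
        return [min(i * stride, extent - tile) for i in range(n)]

    xs = _origins(w, tw, geom.stride_x)
    ys = _origins(h, th, geom.stride_y)
    tiles: list[TileRecord] = []
    idx = 0
    for y in ys:
        for x in xs:
            mfov, beam = divmod(idx, geom.beams_per_mfov)
            tiles.append(
                TileRecord(
                    tile_id=f"m{mfov:05d}_b{beam:02d}",
                    mfov=mfov,
                    beam=beam,
                    x_px=x,
                    y_px=y,
                    width=tw,
                    height=th,
                    data=panorama.pixels[y : y + th, x : x + tw].copy(),
                )
            )
            idx += 1
    return TileManifest(tiles=tiles, pixel_size_nm=panorama.pixel_size_nm)


def generate_phantom(
    spec: PhantomSpec,
    geom: AcquisitionGeometry,
    out_dir: Optional[str | Path] = None,
) -> tuple[TileManifest, list[GroundTruthCell]]:
    """Generate a phantom tile set (and optionally write it to disk).

    Returns the tile manifest and the ground-truth cell list.  With
    ``out_dir`` set, tiles are written as 8-bit TIFFs plus CSV/JSON manifests
    and a ground-truth CSV.
    """
    pano, cells = generate_phantom_panorama(spec, geom)
    manifest = tile_partition(pano, geom)
    if out_dir is not None:
        out = Path(out_dir)
        manifest = write_tiles(manifest, out)
        manifest.write_csv(out / "manifest.csv")
        manifest.write_json(out / "manifest.json")
        write_ground_truth(cells, out / "ground_truth.csv")
    return manifest, cells


def write_ground_truth(cells: list[GroundTruthCell], path: str | Path) -> None:
    rows = [
        {
            "cell_id": c.id,
            "cx": c.center[0],
            "cy": c.center[1],
            "X": c.bbox[0],
            "Y": c.bbox[1],
            "W": c.bbox[2],
            "H": c.bbox[3],
            "n_processes": c.n_processes,
            "status": c.status,
        }
        for c in cells
    ]
    pd.DataFrame(
        rows, columns=["cell_id", "cx", "cy", "X", "Y", "W", "H", "n_processes", "status"]
    ).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> list[GroundTruthCell]:
    frame = pd.read_csv(path)
    return [
        GroundTruthCell(
            id=int(r.cell_id),
            center=(float(r.cx), float(r.cy)),
            bbox=(float(r.X), float(r.Y), float(r.W), float(r.H)),
            n_processes=int(r.n_processes),
            status=str(r.status),
        )
        for r in frame.itertuples(index=False)
    ]
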