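"""Morphological viability classification of detected osteocytes.

Each detected cell is cropped, segmented, and its visible dendritic
processes counted; the viability surrogate is a pure threshold on that
count: three or more visible processes -> viable, fewer -> pyknotic.  (The
body of evidence behind that surrogate is weak — process count is not
inextricably tied to viability — so the classifier is exactly that: a
morphological surrogate, not a biochemical claim.)

Process counting works on the segmented mask: the mask is skeletonized, and
skeleton crossings of an annulus drawn at 1.2x the soma-equivalent radius
are counted, merging crossings closer than 15 degrees of arc.  The soma is
isolated from the mask by a morphological opening that removes the thin
processes; the annulus is centred on the soma blob nearest the patch
centre, which keeps the count local when processes of neighbouring cells
wander into the crop.

Resin-filled "ghost" lacunae have smooth, texture-free interiors; records
whose soma interior variance falls below a threshold are flagged
``ghost_suspect`` rather than being forced into a viable/pyknotic call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops
from skimage.morphology import closing, erosion, opening, disk, skeletonize

from .detect import Detection
from .geometry import Panorama

__all__ = [
    "ClassifierConfig",
    "CellRecord",
    "segment_cell",
    "count_processes",
    "classify",
    "classify_detections",
    "emit_records",
    "records_frame",
    "read_records",
]

PROCESS_THRESHOLD = 3  # >= 3 visible processes -> viable


@dataclass(frozen=True)
class ClassifierConfig:
    """Constants of the process-counting procedure (all config-exposed)."""

    patch_factor: float = 1.5  # crop side = factor x detection box
    annulus_factor: float = 1.2  # annulus radius / soma-equivalent radius
    annulus_halfwidth_px: float = 1.25
    merge_arc_deg: float = 15.0
    opening_radius_px: int = 3  # removes thin processes, keeps the soma
    min_mask_area_px: int = 30
    ghost_variance_floor: float = 150.0  # grey^2; below -> ghost_suspect


@dataclass
class CellRecord:
    """A classified cell: detection, process count, status, physical centre."""

    detection: Detection
    n_processes: Optional[int]
    status: Optional[str]
    physical_center_um: tuple[float, float]
    ghost_suspect: bool = False
    unsegmentable: bool = False


def classify(n_processes: int) -> str:
    """Viability surrogate: three or more visible processes -> viable."""
    if n_processes < 0:
        raise ValueError("process count must be >= 0")
    return "viable" if n_processes >= PROCESS_THRESHOLD else "pyknotic"


def segment_cell(patch: np.ndarray, cfg: Optional[ClassifierConfig] = None) -> Optional[np.ndarray]:
    """Segment the cell (soma + processes) in a cropped patch.

    Cells are dark on a light resin background and occupy a small fraction
    of the crop, so the threshold is set robustly from the background mode:
    median minus 4 MAD-based sigmas (at least 5 grey levels).  Morphological
    closing with a 1 px element, then the connected component containing —
    or nearest to — the patch centre.  Returns ``None`` for an
    unsegmentable patch (blank, or no credible foreground near the centre).
    """
    cfg = cfg or ClassifierConfig()
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0 or patch.max() == patch.min():
        return None
    med = np.median(patch)
    sigma = 1.4826 * np.median(np.abs(patch - med))
    fg = patch < med - max(4.0 * sigma, 5.0)
    if not fg.any():
        return None
    fg = closing(fg, disk(1))
    lbl = label(fg)
    cy, cx = patch.shape[0] // 2, patch.shape[1] // 2
    chosen = lbl[cy, cx]
    if chosen == 0:
        # Nearest component centroid within a soma-scale radius.
        best, best_d = 0, np.inf
        for r in regionprops(lbl):
            d = math.hypot(r.centroid[0] - cy, r.centroid[1] - cx)
            if d < best_d:
                best, best_d = r.label, d
        if best == 0 or best_d > min(patch.shape) / 3:
            return None
        chosen = best
    mask = lbl == chosen
    if mask.sum() < cfg.min_mask_area_px:
        return None
    return mask


def _soma_blob(mask: np.ndarray, cfg: ClassifierConfig) -> Optional[np.ndarray]:
    """Isolate the central soma: opening removes thin processes."""
    opened = opening(mask, disk(cfg.opening_radius_px))
    if not opened.any():
        return None
    lbl = label(opened)
    cy, cx = mask.shape[0] // 2, mask.shape[1] // 2
    at_center = lbl[cy, cx]
    if at_center:
        return lbl == at_center
    best, best_d = 0, np.inf
    for r in regionprops(lbl):
        d = math.hypot(r.centroid[0] - cy, r.centroid[1] - cx)
        if d < best_d:
            best, best_d = r.label, d
    return (lbl == best) if best else None


def count_processes(mask: np.ndarray, cfg: Optional[ClassifierConfig] = None) -> int:
    """Count visible processes on a segmented cell mask.

    Skeleton crossings of an annulus at ``annulus_factor`` x the
    soma-equivalent radius, centred on the soma blob; crossings within
    ``merge_arc_deg`` of arc merge into one.  A candidate crossing must have
    skeleton support beyond the annulus (processes extend outward; boundary
    spurs do not), which rejects segmentation-noise spurs.
    """
    cfg = cfg or ClassifierConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("count_processes requires a non-empty mask")
    soma = _soma_blob(mask, cfg)
    if soma is None:
        return 0
    ys, xs = np.nonzero(soma)
    cy, cx = float(ys.mean()), float(xs.mean())
    # Equivalent radius of the whole mask: the annulus moves outward as more
    # (or longer) processes are present, to where adjacent rays no longer
    # form a merged wedge near the soma boundary.
    r_eq = math.sqrt(mask.sum() / math.pi)
    r = cfg.annulus_factor * r_eq

    skel = skeletonize(mask)
    sy, sx = np.nonzero(skel)
    if sy.size == 0:
        return 0
    dist = np.hypot(sy - cy, sx - cx)
    ang = np.degrees(np.arctan2(sy - cy, sx - cx)) % 360.0

    band = np.abs(dist - r) <= cfg.annulus_halfwidth_px
    if not band.any():
        return 0
    band_angles = np.sort(ang[band])
    outer = ang[dist > r + 2.0]

    # Circular gap clustering: split where consecutive angles (cyclically)
    # are more than merge_arc_deg apart.
    gaps = np.diff(np.concatenate([band_angles, [band_angles[0] + 360.0]]))
    breaks = np.nonzero(gaps > cfg.merge_arc_deg)[0]
    if breaks.size == 0:
        clusters = [band_angles]  # one smeared crossing (or a full ring)
    else:
        start = int(breaks[-1]) + 1  # first member after the largest-index gap
        rot = np.concatenate([band_angles[start:], band_angles[:start] + 360.0])
        cut = np.nonzero(np.diff(rot) > cfg.merge_arc_deg)[0] + 1
        clusters = np.split(rot, cut)

    count = 0
    for cl in clusters:
        if cl.size == 0:
            continue
        lo = cl.min() - cfg.merge_arc_deg / 2.0
        hi = cl.max() + cfg.merge_arc_deg / 2.0
        # Require skeleton support beyond the annulus inside this arc
        # (processes extend outward; boundary spurs do not).
        in_arc = ((outer - lo) % 360.0) <= min(hi - lo, 360.0)
        if outer.size and in_arc.any():
            count += 1
    return count


def _interior_variance(patch: np.ndarray, soma: np.ndarray) -> float:
    # Erode enough to shed the lacuna rim: only the interior should decide
    # whether the texture looks cellular or like a smooth resin fill.
    core = erosion(soma, disk(4))
    if core.sum() < 10:
        core = erosion(soma, disk(2))
    if core.sum() < 10:
        core = soma
    return float(np.var(patch[core]))


def classify_detections(
    pano: Panorama,
    dets: Sequence[Detection],
    cfg: Optional[ClassifierConfig] = None,
) -> list[CellRecord]:
    """Crop, segment and classify every detection against the panorama.

    Sets each detection's class C from the process-count rule; records that
    cannot be segmented are flagged and left unclassified, and smooth
    low-variance interiors are flagged ``ghost_suspect``.
    """
    cfg = cfg or ClassifierConfig()
    img = pano.pixels
    h, w = img.shape
    um_per_px = pano.pixel_size_nm / 1000.0
    records: list[CellRecord] = []
    for det in dets:
        half = cfg.patch_factor * max(det.W, det.H) / 2.0
        y0 = max(0, int(round(det.Y - half)))
        y1 = min(h, int(round(det.Y + half)))
        x0 = max(0, int(round(det.X - half)))
        x1 = min(w, int(round(det.X + half)))
        patch = img[y0:y1, x0:x1]
        center_um = (det.X * um_per_px, det.Y * um_per_px)
        mask = segment_cell(patch, cfg) if patch.size else None
        if mask is None:
            records.append(
                CellRecord(
                    detection=det,
                    n_processes=None,
                    status=None,
                    physical_center_um=center_um,
                    unsegmentable=True,
                )
            )
            continue
        n = count_processes(mask, cfg)
        status = classify(n)
        det.C = status
        soma = _soma_blob(mask, cfg)
        ghost = soma is not None and _interior_variance(patch, soma) < cfg.ghost_variance_floor
        records.append(
            CellRecord(
                detection=det,
                n_processes=n,
                status=status,
                physical_center_um=center_um,
                ghost_suspect=ghost,
            )
        )
    return records


RECORD_COLUMNS = [
    "X",
    "Y",
    "W",
    "H",
    "p",
    "n_processes",
    "status",
    "ghost_suspect",
    "cx_um",
    "cy_um",
]


def records_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = [
        {
            "X": r.detection.X,
            "Y": r.detection.Y,
            "W": r.detection.W,
            "H": r.detection.H,
            "p": r.detection.p,
            "n_processes": r.n_processes if r.n_processes is not None else -1,
            "status": r.status if r.status is not None else "unsegmentable",
            "ghost_suspect": r.ghost_suspect,
            "cx_um": r.physical_center_um[0],
            "cy_um": r.physical_center_um[1],
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def emit_records(
    dets: Sequence[Detection],
    masks: Sequence[Optional[np.ndarray]],
    counts: Sequence[Optional[int]],
    pixel_size_nm: float = 12.0,
) -> list[CellRecord]:
    """Assemble records from aligned detections, masks and counts.

    Lengths must agree; a ``None`` mask flags the record unsegmentable.
    Physical coordinates are appended from the panorama pixel size.
    """
    if not (len(dets) == len(masks) == len(counts)):
        raise ValueError("dets, masks and counts must have equal length")
    um_per_px = pixel_size_nm / 1000.0
    out: list[CellRecord] = []
    for det, mask, n in zip(dets, masks, counts):
        center_um = (det.X * um_per_px, det.Y * um_per_px)
        if mask is None or n is None:
            out.append(
                CellRecord(
                    detection=det,
                    n_processes=None,
                    status=None,
                    physical_center_um=center_um,
                    unsegmentable=True,
                )
            )
        else:
            status = classify(n)
            det.C = status
            out.append(
                CellRecord(detection=det, n_processes=n, status=status, physical_center_um=center_um)
            )
    return out


def read_records(path) -> list[CellRecord]:
    frame = pd.read_csv(path)
    out = []
    for r in frame.itertuples(index=False):
        unseg = r.status == "unsegmentable"
        det = Detection(X=float(r.X), Y=float(r.Y), W=float(r.W), H=float(r.H), p=float(r.p),
                        C=None if unseg else str(r.status))
        out.append(
            CellRecord(
                detection=det,
                n_processes=None if unseg else int(r.n_processes),
                status=None if unseg else str(r.status),
                physical_center_um=(float(r.cx_um), float(r.cy_um)),
                ghost_suspect=bool(r.ghost_suspect),
                unsegmentable=unseg,
            )
        )
    return out
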