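"""Single-pass grid detector for osteocyte-like objects.

The detection contract mirrors the single-shot grid detectors used for this
kind of screening: the input is resized onto a 448 x 448 canvas, the canvas
is divided into an S x S grid, each grid cell proposes at most one candidate
box, every detection carries exactly five numbers (X, Y, W, H, p), and
overlapping boxes are resolved by greedy non-max suppression with a 0.5
confidence floor.

The default backend is deterministic: normalized cross-correlation against a
bank of elliptical soma templates (orientations x scales).  The NCC score is
mapped linearly onto [0, 1] to produce the confidence p.  A learned detector
can be plugged in by providing any callable with the same signature as
:func:`detect`; nothing downstream depends on the backend.

The module also carries the training-set plumbing used when a learned
backend is trained: grid augmentation of annotated patches (rotation, scale,
contrast, translation) with exact count accounting, and a leakage-free
train/test split by source annotation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.feature import match_template
from skimage.filters import gaussian
from skimage.transform import rescale, resize, rotate

from .geometry import Panorama
from .phantom import CELL_BOX_PX, GroundTruthCell

__all__ = [
    "DetectorConfig",
    "Detection",
    "AugmentationSpec",
    "Annotation",
    "AugmentedExample",
    "preprocess",
    "detect",
    "detect_panorama",
    "nms",
    "box_iou",
    "augment",
    "materialize_example",
    "split",
    "evaluate",
    "DetectionMetrics",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the grid detector and its NCC backend.

    ``confidence_floor`` is the post-NMS keep threshold (keep p > floor);
    ``display_floor`` is the stricter threshold used only when rendering
    pins.  ``box_px`` is the nominal whole-cell box side in source pixels.
    """

    input_side_px: int = 448
    grid_S: int = 7
    confidence_floor: float = 0.5
    display_floor: float = 0.7
    nms_iou: float = 0.5
    box_px: float = float(CELL_BOX_PX)
    soma_axes_px: tuple[float, float] = (20.0, 12.0)
    orientations_deg: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    template_scales: tuple[float, ...] = (1.0,)
    score_map_range: tuple[float, float] = (0.2, 0.9)
    background_level: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_floor <= self.display_floor <= 1.0):
            raise ValueError("need 0 <= confidence_floor <= display_floor <= 1")
        if self.grid_S < 1:
            raise ValueError("grid_S must be >= 1")
        if self.input_side_px < 1:
            raise ValueError("input_side_px must be >= 1")


@dataclass
class Detection:
    """One detected object: exactly five numeric predictions plus a class.

    (X, Y) is the box centre and (W, H) its extent, all in the source image
    frame; p in [0, 1] is the detection confidence; C is the viability class,
    unset until classification.
    """

    X: float
    Y: float
    W: float
    H: float
    p: float
    C: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("confidence p must lie in [0, 1]")
        if self.W <= 0 or self.H <= 0:
            raise ValueError("box extents must be positive")


@dataclass(frozen=True)
class CanvasTransform:
    """Affine mapping source -> canvas: canvas = source * scale + offset."""

    scale: float
    offset_x: float
    offset_y: float

    def to_canvas(self, x: float, y: float) -> tuple[float, float]:
        return x * self.scale + self.offset_x, y * self.scale + self.offset_y

    def to_source(self, x: float, y: float) -> tuple[float, float]:
        return (x - self.offset_x) / self.scale, (y - self.offset_y) / self.scale


def preprocess(image: np.ndarray, cfg: DetectorConfig) -> tuple[np.ndarray, CanvasTransform]:
    """Aspect-preserving resize onto a square letterboxed canvas.

    The canvas side is ``cfg.input_side_px``; unfilled margins take the
    background level.  The returned transform maps source coordinates onto
    the canvas (and back via ``to_source``).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot preprocess an empty image")
    h, w = image.shape[:2]
    side = cfg.input_side_px
    scale = side / max(h, w)
    nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    if (nh, nw) == (h, w):
        content = image.astype(np.float64)
        scale = 1.0
    else:
        content = resize(
            image.astype(np.float64), (nh, nw), order=1, anti_aliasing=scale < 1, preserve_range=True
        )
    canvas = np.full((side, side), cfg.background_level, dtype=np.float64)
    oy = (side - content.shape[0]) // 2
    ox = (side - content.shape[1]) // 2
    canvas[oy : oy + content.shape[0], ox : ox + content.shape[1]] = content
    return canvas, CanvasTransform(scale=scale, offset_x=float(ox), offset_y=float(oy))


def _soma_template(axes_px: tuple[float, float], orientation_deg: float) -> np.ndarray:
    """Dark-ellipse-on-light matched filter, lightly smoothed."""
    a = axes_px[0] / 2.0
    b = axes_px[1] / 2.0
    side = int(math.ceil(2 * max(a, b))) + 9
    side |= 1
    c = side // 2
    t = np.full((side, side), 1.0)
    rr, cc = draw_ellipse(c, c, b, a, shape=t.shape, rotation=-math.radians(orientation_deg))
    t[rr, cc] = 0.0
    return gaussian(t, sigma=1.0)


def _response_map(image: np.ndarray, cfg: DetectorConfig, scale: float = 1.0) -> np.ndarray:
    """Max NCC response over the template bank, same shape as ``image``."""
    img = np.asarray(image, dtype=np.float64)
    best = np.full(img.shape, -1.0)
    for s, o in itertools.product(cfg.template_scales, cfg.orientations_deg):
        axes = (cfg.soma_axes_px[0] * s * scale, cfg.soma_axes_px[1] * s * scale)
        if min(axes) < 3:
            continue
        tmpl = _soma_template(axes, o)
        if tmpl.shape[0] > min(img.shape):
            continue
        resp = match_template(
            img, tmpl, pad_input=True, mode="constant", constant_values=cfg.background_level
        )
        np.maximum(best, resp, out=best)
    return best


def _score_to_p(score: np.ndarray | float, cfg: DetectorConfig):
    lo, hi = cfg.score_map_range
    return np.clip((score - lo) / (hi - lo), 0.0, 1.0)


def _grid_candidates(
    response: np.ndarray,
    x0: int,
    y0: int,
    w: int,
    h: int,
    cfg: DetectorConfig,
    box_side: float,
) -> list[Detection]:
    """One candidate per grid cell: the peak response inside the cell."""
    out: list[Detection] = []
    xb = np.linspace(x0, x0 + w, cfg.grid_S + 1).astype(int)
    yb = np.linspace(y0, y0 + h, cfg.grid_S + 1).astype(int)
    for gy in range(cfg.grid_S):
        for gx in range(cfg.grid_S):
            sub = response[yb[gy] : yb[gy + 1], xb[gx] : xb[gx + 1]]
            if sub.size == 0:
                continue
            flat = int(np.argmax(sub))
            ry, rx = divmod(flat, sub.shape[1])
            score = float(sub[ry, rx])
            p = float(_score_to_p(score, cfg))
            if p <= 0.0:
                continue
            out.append(
                Detection(
                    X=float(xb[gx] + rx),
                    Y=float(yb[gy] + ry),
                    W=box_side,
                    H=box_side,
                    p=p,
                )
            )
    return out


def box_iou(a: Detection, b: Detection) -> float:
    """Intersection-over-union of two centre-format boxes."""
    ax0, ax1 = a.X - a.W / 2, a.X + a.W / 2
    ay0, ay1 = a.Y - a.H / 2, a.Y + a.H / 2
    bx0, bx1 = b.X - b.W / 2, b.X + b.W / 2
    by0, by1 = b.Y - b.H / 2, b.Y + b.H / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a.W * a.H + b.W * b.H - inter
    if union <= 0:
        return 0.0
    return min(1.0, max(0.0, inter / union))


def nms(dets: Sequence[Detection], cfg: Optional[DetectorConfig] = None) -> list[Detection]:
    """Greedy non-max suppression, then the confidence floor.

    Boxes are visited in descending confidence (ties broken by (X, Y)); a box
    is suppressed if its IoU with an already kept box exceeds ``nms_iou``.
    Kept boxes with p <= ``confidence_floor`` are dropped afterwards, so the
    floor never changes which boxes suppress which.
    """
    cfg = cfg or DetectorConfig()
    order = sorted(dets, key=lambda d: (-d.p, d.X, d.Y))
    kept: list[Detection] = []
    for d in order:
        if all(box_iou(d, k) <= cfg.nms_iou for k in kept):
            kept.append(d)
    return [d for d in kept if d.p > cfg.confidence_floor]


def detect(image: np.ndarray, cfg: Optional[DetectorConfig] = None) -> list[Detection]:
    """Run the single-pass grid detector on one image.

    Preprocesses onto the square canvas, computes the NCC response of the
    template bank (templates scaled with the canvas), proposes one candidate
    per grid cell, suppresses overlaps, applies the confidence floor, and
    returns detections in the source frame.
    """
    cfg = cfg or DetectorConfig()
    canvas, tform = preprocess(image, cfg)
    response = _response_map(canvas, cfg, scale=tform.scale)
    side = cfg.input_side_px
    cands = _grid_candidates(response, 0, 0, side, side, cfg, box_side=cfg.box_px * tform.scale)
    kept = nms(cands, cfg)
    out = []
    for d in kept:
        sx, sy = tform.to_source(d.X, d.Y)
        out.append(Detection(X=sx, Y=sy, W=d.W / tform.scale, H=d.H / tform.scale, p=d.p, C=d.C))
    return out


def detect_panorama(
    pano: Panorama | np.ndarray,
    cfg: Optional[DetectorConfig] = None,
    stride: Optional[int] = None,
) -> list[Detection]:
    """Detect over a large panorama with overlapping canvas-sized windows.

    The NCC response is computed once over the whole image (NCC normalization
    is local to the template footprint, so this matches per-window responses
    away from borders); the S x S grid-candidate rule is then applied inside
    each window and duplicates from overlapping windows are removed by one
    global NMS pass.
    """
    cfg = cfg or DetectorConfig()
    img = pano.pixels if isinstance(pano, Panorama) else np.asarray(pano)
    h, w = img.shape[:2]
    side = cfg.input_side_px
    if h <= side and w <= side:
        return detect(img, cfg)
    stride = stride or side // 2
    response = _response_map(img.astype(np.float64), cfg, scale=1.0)

    def _origins(extent: int) -> list[int]:
        if extent <= side:
            return [0]
        n = math.ceil((extent - side) / stride) + 1
        return sorted({min(i * stride, extent - side) for i in range(n)})

    cands: list[Detection] = []
    for oy in _origins(h):
        for ox in _origins(w):
            ww = min(side, w - ox)
            wh = min(side, h - oy)
            cands.extend(_grid_candidates(response, ox, oy, ww, wh, cfg, box_side=cfg.box_px))
    return nms(cands, cfg)


# ---------------------------------------------------------------------------
# Training-set plumbing: augmentation grid and leakage-free splitting.
# ---------------------------------------------------------------------------


def _default_scales() -> tuple[float, ...]:
    # 53-point 1% scale grid centred on identity (0.74 .. 1.26).
    return tuple(round(0.74 + 0.01 * i, 2) for i in range(53))


@dataclass(frozen=True)
class AugmentationSpec:
    """Deterministic transform grid applied to every annotation.

    The grid is the Cartesian product of the four lists; the identity
    transform (rotation 0, scale 1, contrast 1, shift (0, 0)) is required to
    be a member.  The default grid holds 30 rotations x 53 scales x 1 x 1 =
    1,590 transforms, so 629 annotations expand to 1,000,110 examples.
    """

    rotations_deg: tuple[float, ...] = tuple(float(r) for r in range(0, 360, 12))
    scales: tuple[float, ...] = field(default_factory=_default_scales)
    contrasts: tuple[float, ...] = (1.0,)
    translations_px: tuple[tuple[int, int], ...] = ((0, 0),)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if any(c <= 0 for c in self.contrasts):
            raise ValueError("contrast gains must be positive")
        if not (
            0.0 in self.rotations_deg
            and 1.0 in self.scales
            and 1.0 in self.contrasts
            and (0, 0) in self.translations_px
        ):
            raise ValueError("the identity transform must be a member of the grid")

    @property
    def per_example_count(self) -> int:
        return (
            len(self.rotations_deg)
            * len(self.scales)
            * len(self.contrasts)
            * len(self.translations_px)
        )


@dataclass(frozen=True)
class Annotation:
    """One manually annotated cell patch with its viability label."""

    id: int
    label: str
    patch: Optional[np.ndarray] = None


@dataclass(frozen=True)
class AugmentedExample:
    """A transform-parameter record; images are materialized on demand."""

    source_id: int
    label: str
    rotation_deg: float
    scale: float
    contrast: float
    translation_px: tuple[int, int]


def augment(annotations: Sequence[Annotation], spec: Optional[AugmentationSpec] = None) -> list[AugmentedExample]:
    """Expand annotations over the transform grid.

    Returns exactly ``len(annotations) * spec.per_example_count`` parameter
    records, each traceable to its source annotation; labels are invariant
    under the transforms.  Images are not materialized here (see
    :func:`materialize_example`), so million-example grids stay cheap.
    """
    spec = spec or AugmentationSpec()
    if len(annotations) == 0:
        raise ValueError("augment requires at least one annotation")
    return [
        AugmentedExample(
            source_id=a.id,
            label=a.label,
            rotation_deg=r,
            scale=s,
            contrast=c,
            translation_px=t,
        )
        for a in annotations
        for r in spec.rotations_deg
        for s in spec.scales
        for c in spec.contrasts
        for t in spec.translations_px
    ]


def materialize_example(
    annotation: Annotation, example: AugmentedExample, background: float = 200.0
) -> np.ndarray:
    """Apply one transform record to its source patch."""
    if annotation.id != example.source_id:
        raise ValueError("example does not belong to this annotation")
    if annotation.patch is None:
        raise ValueError("annotation carries no pixel data")
    img = annotation.patch.astype(np.float64)
    if example.scale != 1.0:
        img = rescale(img, example.scale, order=1, anti_aliasing=example.scale < 1, preserve_range=True)
    if example.rotation_deg != 0.0:
        img = rotate(img, example.rotation_deg, resize=False, preserve_range=True, cval=background)
    dx, dy = example.translation_px
    if (dx, dy) != (0, 0):
        img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
    if example.contrast != 1.0:
        img = background + (img - background) * example.contrast
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def split(
    examples: Sequence[AugmentedExample],
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[AugmentedExample], list[AugmentedExample]]:
    """Split by source annotation, not by example.

    All augmentations of one annotation land on the same side, so no test
    example is a transform of a training example.  The number of training
    sources is ``round(train_fraction * n_sources)``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    sources = sorted({e.source_id for e in examples})
    if len(sources) < 2:
        raise ValueError("split requires at least two source annotations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sources))
    n_train = int(round(train_fraction * len(sources)))
    train_ids = {sources[i] for i in perm[:n_train]}
    train = [e for e in examples if e.source_id in train_ids]
    test = [e for e in examples if e.source_id not in train_ids]
    return train, test


@dataclass
class DetectionMetrics:
    """Greedy IoU matching of detections against ground truth."""

    precision: float
    recall: float
    accuracy: float
    n_truth: int
    n_detections: int
    n_matched: int
    n_correct_class: int
    n_ghost_hits: int


def evaluate(
    dets: Sequence[Detection],
    truth: Sequence[GroundTruthCell],
    iou_floor: float = 0.5,
    ghost_tolerant: bool = False,
) -> DetectionMetrics:
    """Score detections against phantom ground truth.

    Matching is one-to-one and greedy by descending IoU (pairs below
    ``iou_floor`` never match).  Accuracy is joint detection + classification
    over non-ghost truth: matched cells whose predicted class equals the true
    status, divided by the non-ghost truth count.  Ghost lacunae are excluded
    from that denominator; a detection matched to a ghost counts against
    precision unless ``ghost_tolerant``.
    """
    truth_dets = [
        Detection(X=t.bbox[0], Y=t.bbox[1], W=t.bbox[2], H=t.bbox[3], p=1.0, C=t.status)
        for t in truth
    ]
    pairs = []
    for di, d in enumerate(dets):
        for ti, td in enumerate(truth_dets):
            iou = box_iou(d, td)
            if iou >= iou_floor:
                pairs.append((iou, di, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_d: dict[int, int] = {}
    matched_t: set[int] = set()
    for _, di, ti in pairs:
        if di in matched_d or ti in matched_t:
            continue
        matched_d[di] = ti
        matched_t.add(ti)

    non_ghost = [i for i, t in enumerate(truth) if t.status != "ghost"]
    n_truth = len(non_ghost)
    ghost_hits = sum(1 for ti in matched_t if truth[ti].status == "ghost")
    matched_non_ghost = [di for di, ti in matched_d.items() if truth[ti].status != "ghost"]
    n_correct = sum(1 for di in matched_non_ghost if dets[di].C == truth[matched_d[di]].status)

    tp = len(matched_non_ghost) + (ghost_hits if ghost_tolerant else 0)
    precision = tp / len(dets) if dets else 0.0
    recall = len(matched_non_ghost) / n_truth if n_truth else 0.0
    accuracy = n_correct / n_truth if n_truth else 0.0
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        n_truth=n_truth,
        n_detections=len(dets),
        n_matched=len(matched_non_ghost),
        n_correct_class=n_correct,
        n_ghost_hits=ghost_hits,
    )
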