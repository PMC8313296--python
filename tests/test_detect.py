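"""Grid detector contract: preprocessing, NMS, augmentation, evaluation."""

import numpy as np
import pytest

from osteoatlas.detect import (
    Annotation,
    AugmentationSpec,
    AugmentedExample,
    Detection,
    DetectorConfig,
    augment,
    box_iou,
    detect,
    detect_panorama,
    evaluate,
    materialize_example,
    nms,
    preprocess,
    split,
)
from osteoatlas.geometry import downscale_for_detection
from osteoatlas.phantom import GroundTruthCell, PhantomSpec, generate_phantom_panorama, render_cell

CFG = DetectorConfig()


# ---------------------------------------------------------------- preprocess
def test_preprocess_identity_on_canvas_sized_input(rng):
    img = rng.integers(0, 255, (448, 448)).astype(np.uint8)
    canvas, t = preprocess(img, CFG)
    assert canvas.shape == (448, 448)
    assert t.scale == 1.0 and (t.offset_x, t.offset_y) == (0.0, 0.0)
    np.testing.assert_allclose(canvas, img)


def test_preprocess_downscale_maps_back(rng):
    img = rng.integers(0, 255, (896, 896)).astype(np.uint8)
    _, t = preprocess(img, CFG)
    assert t.scale == pytest.approx(0.5)
    assert t.to_source(100, 100) == pytest.approx((200, 200))


def test_preprocess_letterbox_offset(rng):
    img = rng.integers(0, 255, (448, 896)).astype(np.uint8)
    canvas, t = preprocess(img, CFG)
    assert t.scale == pytest.approx(0.5)
    assert t.offset_y == 112 and t.offset_x == 0
    # letterbox bands filled with background
    assert np.all(canvas[:112] == CFG.background_level)


def test_preprocess_rejects_empty():
    with pytest.raises(ValueError):
        preprocess(np.empty((0, 0)), CFG)


# ----------------------------------------------------------------------- NMS
def _det(x, y, p, w=10.0, h=10.0):
    return Detection(X=x, Y=y, W=w, H=h, p=p)


def test_nms_keeps_highest_of_identical_boxes():
    kept = nms([_det(5, 5, 0.9), _det(5, 5, 0.6)], CFG)
    assert len(kept) == 1 and kept[0].p == 0.9


def test_nms_floor_drops_low_confidence():
    assert nms([_det(5, 5, 0.4)], CFG) == []


def test_nms_keeps_disjoint_boxes():
    kept = nms([_det(0, 0, 0.8), _det(100, 100, 0.7)], CFG)
    assert len(kept) == 2


def _reference_nms(dets, iou_thr, floor):
    """Independent greedy suppression: repeated linear max scans."""
    remaining = list(dets)
    kept = []
    while remaining:
        best = min(remaining, key=lambda d: (-d.p, d.X, d.Y))
        kept.append(best)
        remaining = [d for d in remaining if d is not best and box_iou(d, best) <= iou_thr]
    return [d for d in kept if d.p > floor]


def test_nms_matches_reference_on_random_sets(rng):
    """Greedy NMS equals an independent reference over 200 random box sets."""
    for _ in range(200):
        n = int(rng.integers(0, 13))
        dets = [
            _det(
                float(rng.uniform(0, 50)),
                float(rng.uniform(0, 50)),
                float(np.round(rng.uniform(0, 1), 3)),
                w=float(rng.uniform(5, 20)),
                h=float(rng.uniform(5, 20)),
            )
            for _ in range(n)
        ]
        ours = nms(dets, CFG)
        ref = _reference_nms(dets, CFG.nms_iou, CFG.confidence_floor)
        assert [(d.X, d.Y, d.p) for d in ours] == [(d.X, d.Y, d.p) for d in ref]


# -------------------------------------------------------------------- detect
def test_detect_blank_canvas_is_empty():
    blank = np.full((448, 448), 200, dtype=np.uint8)
    assert detect(blank, CFG) == []


def test_detect_localizes_single_soma():
    spec = PhantomSpec(noise_sd=0.0)
    patch = render_cell("viable", 4, orientation=0.7, spec=spec)
    img = np.full((448, 448), 200, dtype=np.uint8)
    cy, cx = 215, 190
    s = patch.shape[0]
    img[cy - s // 2 : cy + s // 2 + 1, cx - s // 2 : cx + s // 2 + 1] = patch
    dets = detect(img, CFG)
    assert len(dets) == 1
    assert abs(dets[0].X - cx) <= 3 and abs(dets[0].Y - cy) <= 3


def test_detect_recall_on_sparse_phantom(small_geom):
    """20 well-separated cells at default noise: recall >= 0.9 at IoU 0.5."""
    spec = PhantomSpec(n_cells=20, seed=11, ghost_fraction=0.0)
    pano, cells = generate_phantom_panorama(spec, small_geom)
    dets = detect_panorama(pano, CFG)
    m = evaluate(dets, cells)
    assert m.recall >= 0.9


def test_detect_translation_covariance():
    """Shifting a noise-free field shifts every detection by the same amount."""
    spec = PhantomSpec(noise_sd=0.0)
    patch = render_cell("viable", 5, orientation=0.2, spec=spec)
    s = patch.shape[0]

    def field(offset):
        img = np.full((448, 448), 200, dtype=np.uint8)
        for cy, cx in [(120 + offset[0], 110 + offset[1]), (300 + offset[0], 310 + offset[1])]:
            img[cy - s // 2 : cy + s // 2 + 1, cx - s // 2 : cx + s // 2 + 1] = patch
        return img

    base = sorted([(d.X, d.Y) for d in detect(field((0, 0)), CFG)])
    shifted = sorted([(d.X, d.Y) for d in detect(field((9, 17)), CFG)])
    assert len(base) == len(shifted) == 2
    for (x0, y0), (x1, y1) in zip(base, shifted):
        assert abs((x1 - x0) - 17) <= 1 and abs((y1 - y0) - 9) <= 1


def test_confidence_monotone_under_noise(small_geom):
    """More additive noise never raises the mean detection confidence."""
    means = []
    for sd in (4.0, 8.0, 16.0):
        spec = PhantomSpec(n_cells=15, seed=23, noise_sd=sd, ghost_fraction=0.0)
        pano, _ = generate_phantom_panorama(spec, small_geom)
        dets = detect_panorama(pano, CFG)
        assert dets
        means.append(np.mean([d.p for d in dets]))
    assert means[0] >= means[1] >= means[2]


def test_detection_five_prediction_contract():
    with pytest.raises(ValueError):
        Detection(X=0, Y=0, W=10, H=10, p=1.5)
    with pytest.raises(ValueError):
        Detection(X=0, Y=0, W=0, H=10, p=0.5)


# ------------------------------------------------------------------- augment
def test_augment_default_grid_reaches_a_million():
    spec = AugmentationSpec()
    assert spec.per_example_count == 1_590
    annotations = [Annotation(id=i, label="viable") for i in range(629)]
    examples = augment(annotations, spec)
    assert len(examples) == 629 * 1_590 == 1_000_110
    assert len(examples) >= 10**6


def test_augment_identity_only_reproduces_input(rng):
    patch = rng.integers(0, 255, (32, 32)).astype(np.uint8)
    ann = Annotation(id=0, label="pyknotic", patch=patch)
    spec = AugmentationSpec(rotations_deg=(0.0,), scales=(1.0,), contrasts=(1.0,), translations_px=((0, 0),))
    (ex,) = augment([ann], spec)
    np.testing.assert_array_equal(materialize_example(ann, ex), patch)


def test_augment_product_law_and_traceability():
    spec = AugmentationSpec(
        rotations_deg=(0.0, 90.0), scales=(1.0, 1.1), contrasts=(1.0,), translations_px=((0, 0),)
    )
    anns = [Annotation(id=7, label="viable"), Annotation(id=9, label="pyknotic")]
    examples = augment(anns, spec)
    assert len(examples) == 2 * 4
    assert {e.source_id for e in examples} == {7, 9}
    # labels invariant under transforms
    assert all(e.label == ("viable" if e.source_id == 7 else "pyknotic") for e in examples)


def test_augment_rejects_degenerate_transforms():
    with pytest.raises(ValueError):
        AugmentationSpec(scales=(1.0, 0.0))
    with pytest.raises(ValueError):
        AugmentationSpec(rotations_deg=(12.0,))  # identity must be a member
    with pytest.raises(ValueError):
        augment([], AugmentationSpec())


# --------------------------------------------------------------------- split
def _examples(n_sources, per=4):
    spec = AugmentationSpec(
        rotations_deg=tuple(np.linspace(0, 348, per)), scales=(1.0,), contrasts=(1.0,),
        translations_px=((0, 0),),
    )
    return augment([Annotation(id=i, label="viable") for i in range(n_sources)], spec)


def test_split_is_75_25_by_source():
    examples = _examples(100)
    train, test = split(examples, 0.75, seed=0)
    assert len({e.source_id for e in train}) == 75
    assert len({e.source_id for e in test}) == 25


def test_split_deterministic_and_partitions():
    examples = _examples(40)
    t1 = split(examples, 0.75, seed=5)
    t2 = split(examples, 0.75, seed=5)
    assert t1 == t2
    train, test = t1
    assert len(train) + len(test) == len(examples)
    assert {e.source_id for e in train}.isdisjoint({e.source_id for e in test})
    # no augmented leakage: each source entirely on one side
    assert set(map(id, train)).isdisjoint(map(id, test))


def test_split_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        split(_examples(1), 0.75, seed=0)
    with pytest.raises(ValueError):
        split(_examples(10), 1.0, seed=0)


# ------------------------------------------------------------------ evaluate
def _truth(x, y, status, n=4, cid=0):
    if status == "pyknotic":
        n = 1
    if status == "ghost":
        n = 0
    return GroundTruthCell(id=cid, center=(x, y), bbox=(x, y, 96.0, 96.0), n_processes=n, status=status)


def test_evaluate_perfect_detections():
    truth = [_truth(100, 100, "viable", cid=0), _truth(300, 300, "pyknotic", cid=1)]
    dets = [
        Detection(X=100, Y=100, W=96, H=96, p=0.9, C="viable"),
        Detection(X=300, Y=300, W=96, H=96, p=0.9, C="pyknotic"),
    ]
    m = evaluate(dets, truth)
    assert m.accuracy == 1.0 and m.precision == 1.0 and m.recall == 1.0


def test_evaluate_empty_detections():
    m = evaluate([], [_truth(10, 10, "viable")])
    assert m.recall == 0.0 and m.accuracy == 0.0


def test_evaluate_ghosts_excluded_from_accuracy():
    truth = [_truth(100, 100, "viable", cid=0), _truth(300, 300, "ghost", cid=1)]
    dets = [
        Detection(X=100, Y=100, W=96, H=96, p=0.9, C="viable"),
        Detection(X=300, Y=300, W=96, H=96, p=0.9, C="viable"),
    ]
    m = evaluate(dets, truth)
    assert m.n_truth == 1 and m.accuracy == 1.0
    assert m.n_ghost_hits == 1
    assert m.precision == 0.5  # ghost hit is a detection error...
    assert evaluate(dets, truth, ghost_tolerant=True).precision == 1.0  # ...unless tolerated
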