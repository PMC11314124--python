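"""Architecture assembly: parameter accounting, feature-map shape
contracts, box decoding and non-maximum suppression."""

import numpy as np
import pytest

from lemonsurf.arch import (ConfigurationError, Detection, ModelVariant,
                            build_model, count_parameters, decode_predictions,
                            iou_matrix, letterbox, nms)
from lemonsurf.blocks import C2f
from lemonsurf.nn import ConvBlock
from lemonsurf.nn import tensor as T


def test_single_conv_block_closed_form_count():
    # 3x3 conv, in=3, out=16, no bias, plus batch-norm scale and shift
    block = ConvBlock(3, 16, 3)
    assert block.num_parameters() == 3 * 16 * 9 + 2 * 16 == 464


def test_exactly_eight_variants_and_flag_roundtrip(variant_counts):
    assert len(variant_counts) == 8
    assert len(set(variant_counts.values())) == 8


def test_parameter_count_invariant_to_input_size_and_batch():
    a = build_model(ModelVariant(num_classes=2, input_size=640), seed=0)
    b = build_model(ModelVariant(num_classes=2, input_size=320), seed=1)
    assert count_parameters(a) == count_parameters(b)


def test_sod_variant_has_fewer_parameters_than_baseline(variant_counts):
    assert variant_counts[(False, True, False)] < variant_counts[(False, False, False)]


def test_parameter_deltas_are_nearly_additive(variant_counts):
    base = variant_counts[(False, False, False)]
    full = variant_counts[(True, True, True)]
    d_sac = variant_counts[(True, False, False)] - base
    d_sod = variant_counts[(False, True, False)] - base
    d_cbam = variant_counts[(False, False, True)] - base
    assert abs((full - base) - (d_sac + d_sod + d_cbam)) < 0.05e6


def test_invalid_configurations_rejected():
    with pytest.raises(ConfigurationError):
        ModelVariant(num_classes=0)
    with pytest.raises(ConfigurationError):
        ModelVariant(width_multiple=-1.0)
    with pytest.raises(ConfigurationError):
        ModelVariant(input_size=600)           # not divisible by 32
    with pytest.raises(ConfigurationError):
        ModelVariant(use_sod=True, input_size=352)   # needs divisibility by 64


def test_variant_yaml_roundtrip(tmp_path):
    v = ModelVariant(use_sac=True, use_cbam=True, sac_rate=4)
    v.to_yaml(tmp_path / "v.yaml")
    assert ModelVariant.from_yaml(tmp_path / "v.yaml") == v


@pytest.mark.parametrize("use_sod,size,expect", [
    (True, 320, {"P2": 80, "P3": 40, "P4": 20, "P5": 10}),
    (False, 320, {"P3": 40, "P4": 20, "P5": 10}),
])
def test_feature_map_grids(use_sod, size, expect):
    v = ModelVariant(use_sod=use_sod, num_classes=2, input_size=size)
    m = build_model(v, seed=0)
    m.eval()
    x = np.zeros((2, 3, size, size), dtype=np.float32)
    with T.no_grad():
        feats = m.forward_features(x)
    assert set(feats) == set(expect)
    for lv, g in expect.items():
        assert feats[lv].shape == (2, m.layout.channels[lv], g, g)


def test_forward_rejects_non_divisible_input(baseline_model):
    with pytest.raises(ValueError):
        baseline_model.forward_features(np.zeros((1, 3, 100, 100), np.float32))


def test_forward_is_deterministic_for_fixed_seed():
    v = ModelVariant(num_classes=2, input_size=320)
    x = np.random.default_rng(7).random((1, 3, 320, 320), dtype=np.float32)
    outs = []
    for _ in range(2):
        m = build_model(v, seed=11)
        m.eval()
        with T.no_grad():
            feats = m.forward_features(x)
        outs.append({k: f.numpy().copy() for k, f in feats.items()})
    for k in outs[0]:
        assert np.array_equal(outs[0][k], outs[1][k])


# -- decoding / NMS ---------------------------------------------------------

def _fake_level(boxes_conf, grid, stride, nc=2, reg_max=16):
    """Head-output tensors encoding the given (cell, class, conf, dist) list."""
    box = np.zeros((1, 4 * reg_max, grid, grid), np.float32)
    cls = np.full((1, nc, grid, grid), -20.0, np.float32)
    for (gy, gx), cid, conf, dist in boxes_conf:
        logit = np.log(conf / (1 - conf))
        cls[0, cid, gy, gx] = logit
        for e, d in enumerate(dist):      # saturate DFL bins at integer d
            box[0, e * reg_max + d, gy, gx] = 30.0
    return T.Tensor(box), T.Tensor(cls)


def test_nms_suppresses_duplicate_keeps_disjoint():
    boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10], [50, 50, 60, 60]], float)
    scores = np.array([0.9, 0.8, 0.7])
    keep = nms(boxes, scores, 0.5)
    assert keep == [0, 2]


def test_nms_chain_does_not_propagate_suppression():
    a = np.array([0.0, 0, 10, 10])
    b = np.array([2.5, 0, 12.5, 10])
    c = np.array([5.0, 0, 15, 10])
    boxes = np.stack([a, b, c])
    assert np.isclose(iou_matrix(boxes, boxes)[0, 1], 0.6)
    assert np.isclose(iou_matrix(boxes, boxes)[1, 2], 0.6)
    assert iou_matrix(boxes, boxes)[0, 2] < 0.5
    keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.5)
    assert keep == [0, 2]


def test_decode_thresholds_and_coordinates():
    # one cell at (4,4) on an 8x8 stride-8 grid: distances 2,2,2,2 cells
    raw = [_fake_level([((4, 4), 1, 0.9, (2, 2, 2, 2))], grid=8, stride=8)]
    dets = decode_predictions(raw, strides=(8,), shapes=[(8, 8)],
                              conf_threshold=0.25, iou_threshold=0.7)
    assert len(dets) == 1 and len(dets[0]) == 1
    d = dets[0][0]
    assert d.class_id == 1
    assert d.confidence == pytest.approx(0.9, abs=1e-3)
    centre = (4 + 0.5) * 8
    assert d.box == pytest.approx((centre - 16, centre - 16,
                                   centre + 16, centre + 16), abs=1e-2)


def test_decode_confidence_floor_and_empty():
    raw = [_fake_level([((1, 1), 0, 0.2, (1, 1, 1, 1))], grid=8, stride=8)]
    dets = decode_predictions(raw, (8,), [(8, 8)], conf_threshold=0.25,
                              iou_threshold=0.7)
    assert dets[0] == []
    assert decode_predictions([], (8,), [], 0.25, 0.7) == []


def test_decoded_boxes_stay_inside_canvas(full_model):
    x = np.random.default_rng(3).random((1, 3, 128, 128), dtype=np.float32)
    v = ModelVariant(use_sod=True, num_classes=2, input_size=128)
    m = build_model(v, seed=5)
    from lemonsurf.arch import predict
    dets = predict(m, x, conf_threshold=0.01, iou_threshold=0.7)
    for d in dets[0]:
        x0, y0, x1, y1 = d.box
        assert 0 <= x0 < x1 <= 128 and 0 <= y0 < y1 <= 128


def test_detection_invariants_enforced():
    with pytest.raises(ValueError):
        Detection(0, 0.5, (10, 10, 5, 20))
    with pytest.raises(ValueError):
        Detection(0, 1.5, (0, 0, 5, 5))


def test_letterbox_pads_with_114_and_maps_coordinates():
    img = np.full((100, 200, 3), 50, np.uint8)
    canvas, scale, (dx, dy) = letterbox(img, 64)
    assert canvas.shape == (64, 64, 3)
    assert scale == pytest.approx(64 / 200)
    assert canvas[0, 0, 0] == 114 and canvas[32, 32, 0] == 50
    # source centre maps to canvas centre
    cx = 100 * scale + dx
    cy = 50 * scale + dy
    assert cx == pytest.approx(32, abs=1) and cy == pytest.approx(32, abs=1)
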