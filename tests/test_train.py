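"""Training stack: loss behaviour, assigner sanity, optimizer semantics,
checkpoint/resume determinism and the CLI wiring."""

import numpy as np
import pytest

from lemonsurf.arch import ModelVariant, build_model
from lemonsurf.heads import grid_anchors
from lemonsurf.loss import AssignerConfig, assign_targets, compute_loss
from lemonsurf.nn import AdamW, param_groups_for
from lemonsurf.nn import tensor as T
from lemonsurf.train import (TrainConfig, fit, load_checkpoint,
                             restore_optimizer, save_checkpoint)

SMALL = ModelVariant(num_classes=2, width_multiple=0.125, input_size=64)


def _batch(rng, n=2, size=64):
    return rng.random((n, 3, size, size), dtype=np.float32)


def _gts(boxes_list):
    return [np.asarray(b, dtype=np.float64).reshape(-1, 5) for b in boxes_list]


@pytest.fixture(scope="module")
def small_model():
    return build_model(SMALL, seed=0)


def _loss(model, xb, gts):
    model.train()
    raw = model(xb)
    return compute_loss(raw, gts, model.strides, model.variant.num_classes,
                        reg_max=model.reg_max)


def test_loss_components_finite_and_nonnegative(small_model, rng):
    xb = _batch(rng)
    gts = _gts([[(0, 10, 10, 40, 40)], [(1, 5, 5, 30, 50), (0, 35, 35, 60, 60)]])
    loss, comps = _loss(small_model, xb, gts)
    assert np.isfinite(loss.numpy())
    for k in ("box", "cls", "dfl"):
        assert comps[k] >= 0
    assert comps["num_fg"] > 0


def test_image_without_targets_has_zero_box_loss(small_model, rng):
    xb = _batch(rng, n=1)
    loss, comps = _loss(small_model, xb, _gts([[]]))
    assert comps["box"] == 0.0 and comps["dfl"] == 0.0
    assert comps["cls"] > 0.0          # background logits still penalised


def test_duplicate_identical_targets_assign_without_error(small_model, rng):
    xb = _batch(rng, n=1)
    gts = _gts([[(0, 10, 10, 50, 50), (0, 10, 10, 50, 50)]])
    loss, comps = _loss(small_model, xb, gts)
    assert np.isfinite(comps["total"])


def test_loss_deterministic_across_model_rebuilds(rng):
    xb = _batch(rng)
    gts = _gts([[(0, 10, 10, 40, 40)], [(1, 20, 20, 50, 50)]])
    vals = []
    for _ in range(2):
        m = build_model(SMALL, seed=3)
        _, comps = _loss(m, xb.copy(), gts)
        vals.append(comps["total"])
    assert vals[0] == vals[1]


def test_small_targets_land_on_p2_head():
    """With the stride-4 head active, small boxes (side <= 16 px at 640)
    must be assigned predominantly to P2 cells."""
    v = ModelVariant(use_sod=True, num_classes=2, width_multiple=0.125,
                     input_size=640)
    m = build_model(v, seed=2)
    m.train()
    shapes = [(640 // s,) * 2 for s in m.strides]
    points, stride = grid_anchors(shapes, m.strides)
    a = len(points)
    n_p2 = shapes[0][0] * shapes[0][1]
    rng = np.random.default_rng(0)
    hits = 0
    trials = 10
    for t in range(trials):
        cx, cy = rng.uniform(100, 540, 2)
        side = rng.uniform(10, 16)
        gt = np.array([[0, cx - side / 2, cy - side / 2,
                        cx + side / 2, cy + side / 2]])
        scores = rng.random((1, a, 2)).astype(np.float32) * 0.01
        # random plausible predicted boxes around each anchor
        off = rng.uniform(2, 30, (1, a, 2)).astype(np.float32)
        pred = np.concatenate([points[None] - off, points[None] + off], axis=2)
        fg, _, _, _ = assign_targets(scores, pred, points, [gt], 2,
                                     AssignerConfig())
        idx = np.flatnonzero(fg[0])
        if idx.size and (idx < n_p2).mean() > 0.5:
            hits += 1
    assert hits >= 0.9 * trials


def test_optimizer_step_changes_every_param_with_gradient(small_model, rng):
    xb = _batch(rng)
    gts = _gts([[(0, 10, 10, 40, 40)], [(1, 20, 20, 50, 50)]])
    m = build_model(SMALL, seed=7)
    opt = AdamW(param_groups_for(m), lr=0.001667, momentum=0.9,
                weight_decay=0.0005)
    loss, _ = _loss(m, xb, gts)
    before = {id(p): p.data.copy() for p in m.parameters()}
    opt.zero_grad()
    loss.backward()
    opt.step()
    for p in m.parameters():
        if p.grad is not None and np.any(p.grad != 0):
            assert np.any(p.data != before[id(p)])


def test_zero_learning_rate_leaves_parameters_unchanged(rng):
    m = build_model(SMALL, seed=9)
    opt = AdamW(param_groups_for(m), lr=0.0, weight_decay=0.0005)
    xb = _batch(rng)
    gts = _gts([[(0, 10, 10, 40, 40)], []])
    loss, _ = _loss(m, xb, gts)
    before = {id(p): p.data.copy() for p in m.parameters()}
    opt.zero_grad()
    loss.backward()
    opt.step()
    for p in m.parameters():
        assert np.array_equal(p.data, before[id(p)])


def test_divergence_aborts_with_diagnostic(rng, tmp_path):
    m = build_model(SMALL, seed=1)
    for p in m.parameters():       # corrupt the model to force a huge loss
        p.data[...] += 100.0
    xb = _batch(rng)
    gts = _gts([[(0, 10, 10, 40, 40)], [(1, 20, 20, 50, 50)]])
    cfg = TrainConfig(epochs=1, input_size=64, batch_size=2, seed=0,
                      divergence_threshold=1e-6)
    with pytest.raises(FloatingPointError, match="divergence"):
        fit(m, xb, gts, cfg, out_dir=tmp_path)


def test_checkpoint_roundtrip_and_resume_matches_uninterrupted(rng, tmp_path):
    xb = _batch(rng, n=2)
    gts = _gts([[(0, 10, 10, 40, 40)], [(1, 20, 20, 50, 50)]])
    cfg4 = TrainConfig(epochs=4, input_size=64, batch_size=2, seed=5)
    m_a = build_model(SMALL, seed=5)
    hist_a, _ = fit(m_a, xb, gts, cfg4)

    # same 4-epoch schedule, interrupted after epoch 2
    m_b = build_model(SMALL, seed=5)
    opt_b = AdamW(param_groups_for(m_b), lr=cfg4.lr0, momentum=cfg4.momentum,
                  weight_decay=cfg4.weight_decay)
    fit(m_b, xb, gts, cfg4, optimizer=opt_b, stop_epoch=3)
    save_checkpoint(tmp_path / "ck.npz", m_b, opt_b, epoch=2)

    m_c, meta = load_checkpoint(tmp_path / "ck.npz")
    assert meta["epoch"] == 2
    opt_c = AdamW(param_groups_for(m_c), lr=cfg4.lr0, momentum=cfg4.momentum,
                  weight_decay=cfg4.weight_decay)
    restore_optimizer(opt_c, meta)
    # total_steps must match the uninterrupted schedule
    hist_c, _ = fit(m_c, xb, gts, cfg4, optimizer=opt_c, start_epoch=3)
    assert hist_c[0]["epoch"] == 3
    assert hist_c[0]["loss"] == pytest.approx(hist_a[3]["loss"], abs=1e-3)


def test_history_and_run_artifacts_written(rng, tmp_path):
    xb = _batch(rng, n=2)
    gts = _gts([[(0, 10, 10, 40, 40)], [(1, 20, 20, 50, 50)]])
    cfg = TrainConfig(epochs=2, input_size=64, batch_size=2, seed=0,
                      eval_interval=2)
    m = build_model(SMALL, seed=0)
    hist, best = fit(m, xb, gts, cfg, out_dir=tmp_path)
    assert (tmp_path / "history.csv").exists()
    assert (tmp_path / "last.ckpt.npz").exists()
    assert (tmp_path / "config.yaml").exists()
    assert any("mAP50" in row for row in hist)


class TestCLI:
    def test_params_and_synth_split_pipeline(self, tmp_path, capsys):
        from lemonsurf.cli import main
        assert main(["params", "--cbam"]) == 0
        out = capsys.readouterr().out
        assert "3.08 M" in out

        ds = tmp_path / "ds"
        assert main(["synth", "--n", "6", "--width", "640", "--height", "640",
                     "--seed", "1", "--out", str(ds)]) == 0
        assert main(["split", "--dataset", str(ds), "--k", "3",
                     "--seed", "0", "--out", str(tmp_path / "folds.json")]) == 0
        assert (tmp_path / "folds.json").exists()
        # identical seeds give identical fold files
        assert main(["split", "--dataset", str(ds), "--k", "3",
                     "--seed", "0", "--out", str(tmp_path / "folds2.json")]) == 0
        assert ((tmp_path / "folds.json").read_bytes()
                == (tmp_path / "folds2.json").read_bytes())

    def test_unknown_flag_gives_usage_error(self):
        from lemonsurf.cli import main
        assert main(["params", "--bogus"]) != 0
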