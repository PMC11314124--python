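"""Minimal training loop and fold-wise evaluation driver.

Hyperparameter defaults follow the detector's published recipe: AdamW
(momentum 0.9 -> beta1, beta2 0.999), initial learning rate 0.001667,
decoupled weight decay 0.0005, batch size 8, 200 epochs at 640 px input.
The learning rate decays linearly to 1 % of its initial value over the
run.  No mosaic or colour augmentation; horizontal flip is available
behind a flag.  All randomness flows from ``TrainConfig.seed``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import metrics
from .arch import DetectorNetwork, ModelVariant, build_model, predict
from .loss import compute_loss
from .metrics import GroundTruthBox, evaluate
from .nn import AdamW, linear_lr, param_groups_for
from .nn import tensor as T


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.001667
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 8
    epochs: int = 200
    input_size: int = 640
    seed: int = 0
    lr_final_frac: float = 0.01
    flip_augment: bool = False
    eval_interval: int = 0      # 0: evaluate on the final epoch only
    conf_eval: float = 0.001
    iou_eval: float = 0.7
    divergence_threshold: float = 1e4

    def __post_init__(self):
        for f in ("lr0", "momentum", "weight_decay", "batch_size", "epochs",
                  "input_size"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def evaluate_model(model: DetectorNetwork, images: np.ndarray, gts,
                   conf=0.001, iou=0.7, num_classes=None) -> metrics.EvalReport:
    """mAP evaluation of a model on an [N,3,H,W] batch with pixel gts."""
    nc = num_classes or model.variant.num_classes
    dets = predict(model, images, conf_threshold=conf, iou_threshold=iou)
    gt_objs = [[GroundTruthBox(int(r[0]), tuple(r[1:5])) for r in g]
               for g in gts]
    return evaluate(dets, gt_objs, num_classes=nc)


def save_checkpoint(path, model: DetectorNetwork, optimizer=None, epoch=None):
    """Self-describing checkpoint: weights + the variant that built them."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"variant": asdict(model.variant), "epoch": epoch}
    meta["variant"]["sac_stages"] = list(model.variant.sac_stages)
    if optimizer is not None:
        for gi, group in enumerate(optimizer.groups):
            for pi, p in enumerate(group["params"]):
                k = id(p)
                if k in optimizer._m:
                    payload[f"opt_m/{gi}/{pi}"] = optimizer._m[k]
                    payload[f"opt_v/{gi}/{pi}"] = optimizer._v[k]
        meta["opt_t"] = optimizer.t
    payload["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path, seed: int = 0):
    """Rebuild the network a checkpoint describes and load its weights."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        vd = meta["variant"]
        vd["sac_stages"] = tuple(vd["sac_stages"])
        model = build_model(ModelVariant(**vd), seed=seed)
        sd = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        model.load_state_dict(sd)
        opt_state = {k: z[k] for k in z.files if k.startswith("opt_")}
        meta["_opt_arrays"] = opt_state
    return model, meta


def restore_optimizer(optimizer, meta):
    arrays = meta.get("_opt_arrays", {})
    if not arrays:
        return
    optimizer.t = meta.get("opt_t", 0)
    for gi, group in enumerate(optimizer.groups):
        for pi, p in enumerate(group["params"]):
            mk, vk = f"opt_m/{gi}/{pi}", f"opt_v/{gi}/{pi}"
            if mk in arrays:
                optimizer._m[id(p)] = arrays[mk].copy()
                optimizer._v[id(p)] = arrays[vk].copy()


def fit(model: DetectorNetwork, images: np.ndarray, gts, config: TrainConfig,
        out_dir=None, optimizer=None, start_epoch: int = 0,
        stop_epoch: int | None = None):
    """Train on an in-memory dataset.

    images: [N,3,S,S] float batch in [0,1]; gts: list of [M,5] pixel arrays
    (class, x0, y0, x1, y1).  One epoch sweeps the dataset once in seeded
    shuffled mini-batches.  Returns (history rows, best mAP@50 seen).
    """
    rng = np.random.default_rng(config.seed)
    n_im = images.shape[0]
    steps_per_epoch = max((n_im + config.batch_size - 1) // config.batch_size, 1)
    total_steps = config.epochs * steps_per_epoch
    if optimizer is None:
        optimizer = AdamW(param_groups_for(model), lr=config.lr0,
                          momentum=config.momentum,
                          weight_decay=config.weight_decay)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            import yaml
            d = asdict(config)
            d["variant"] = asdict(model.variant)
            d["variant"]["sac_stages"] = list(model.variant.sac_stages)
            yaml.safe_dump(d, fh)
    history, best_map = [], -1.0
    step = start_epoch * steps_per_epoch
    last_epoch = config.epochs if stop_epoch is None else min(stop_epoch,
                                                              config.epochs)
    for epoch in range(start_epoch, last_epoch):
        model.train()
        order = rng.permutation(n_im)
        epoch_loss, comps_acc = 0.0, {}
        for bs in range(0, n_im, config.batch_size):
            idx = order[bs:bs + config.batch_size]
            xb = images[idx]
            gb = [gts[i] for i in idx]
            if config.flip_augment:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                size = xb.shape[3]
                for k in np.flatnonzero(flip):
                    xb[k] = xb[k, :, :, ::-1]
                    if len(gb[k]):
                        g = gb[k].copy()
                        g[:, 1], g[:, 3] = size - gb[k][:, 3], size - gb[k][:, 1]
                        gb[k] = g
            optimizer.lr = linear_lr(config.lr0, step, total_steps,
                                     config.lr_final_frac)
            raw = model(xb)
            loss, comps = compute_loss(raw, gb, model.strides,
                                       model.variant.num_classes,
                                       reg_max=model.reg_max)
            if comps["total"] > config.divergence_threshold:
                _dump_history(out, history)
                raise FloatingPointError(
                    f"divergence at epoch {epoch}: loss {comps['total']:.3g}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            step += 1
            epoch_loss += comps["total"]
            for k, v in comps.items():
                comps_acc[k] = comps_acc.get(k, 0.0) + v
        row = {"epoch": epoch, "loss": epoch_loss / steps_per_epoch,
               "lr": optimizer.lr,
               **{f"loss_{k}": v / steps_per_epoch for k, v in comps_acc.items()
                  if k != "total"}}
        is_last = epoch == config.epochs - 1
        if (config.eval_interval and (epoch + 1) % config.eval_interval == 0) or is_last:
            rep = evaluate_model(model, images, gts, config.conf_eval,
                                 config.iou_eval)
            row["mAP50"] = rep.map50
            row["mAP50_95"] = rep.map50_95
            if rep.map50 > best_map:
                best_map = rep.map50
                if out:
                    save_checkpoint(out / "best.ckpt.npz", model, optimizer,
                                    epoch)
        history.append(row)
    if out:
        save_checkpoint(out / "last.ckpt.npz", model, optimizer, last_epoch - 1)
        _dump_history(out, history)
    return history, best_map


def _dump_history(out, history):
    if not out or not history:
        return
    keys = sorted({k for row in history for k in row})
    with open(Path(out) / "history.csv", "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=keys)
        wr.writeheader()
        wr.writerows(history)


def crossval(model_factory, fold_batches, config: TrainConfig):
    """Train/evaluate across folds; returns per-fold reports + aggregates.

    fold_batches: list of (train_images, train_gts, val_images, val_gts).
    """
    reports = []
    for fi, (tr_x, tr_g, va_x, va_g) in enumerate(fold_batches):
        model = model_factory(fi)
        fit(model, tr_x, tr_g, config)
        reports.append(evaluate_model(model, va_x, va_g,
                                      config.conf_eval, config.iou_eval))
    agg = {}
    if len(reports) == 5:
        agg = {m: metrics.fold_aggregate([getattr(r, m) for r in reports])
               for m in ("map50", "map50_95", "precision", "recall")}
    return reports, agg
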