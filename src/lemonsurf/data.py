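"""Dataset plumbing: YOLO-format label I/O, target-centred 1024x1024
tiling with label regeneration, and stratified 5-fold split plans.

Conventions: pixel boxes are half-open ``[x_min, x_max)``; label files use
the normalized-centre convention ``class cx cy w h``; all internal math is
0-based.  Class ids: 0 = healthy lemon, 1 = diseased lemon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

CLASS_NAMES = {0: "lemon", 1: "disease"}


class LabelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledImage:
    """One image with normalized YOLO boxes (class, cx, cy, w, h)."""
    path: str
    width: int
    height: int
    boxes: tuple = ()   # of (class_id, cx, cy, w, h)

    def pixel_boxes(self) -> np.ndarray:
        """[N,5] array: class, x_min, y_min, x_max, y_max in pixels."""
        if not self.boxes:
            return np.zeros((0, 5), dtype=np.float64)
        arr = np.asarray(self.boxes, dtype=np.float64)
        cx, cy = arr[:, 1] * self.width, arr[:, 2] * self.height
        w, h = arr[:, 3] * self.width, arr[:, 4] * self.height
        return np.stack([arr[:, 0], cx - w / 2, cy - h / 2,
                         cx + w / 2, cy + h / 2], axis=1)


@dataclass(frozen=True)
class TileRecord:
    """One fixed-size crop with regenerated labels.

    ``origin`` is the crop's top-left pixel in the source image;
    ``edge_flags[i]`` is True when box i was clipped by the tile boundary.
    """
    source: str
    origin: tuple        # (x_off, y_off)
    size: int
    boxes: tuple
    edge_flags: tuple
    source_indices: tuple = ()   # index of each box in the source image


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every image id to exactly one of k validation folds."""
    k: int
    assignment: dict = field(default_factory=dict)

    def fold_of(self, image_id) -> int:
        return self.assignment[image_id]

    def validation_ids(self, fold: int) -> list:
        return sorted(i for i, f in self.assignment.items() if f == fold)

    def training_ids(self, fold: int) -> list:
        return sorted(i for i, f in self.assignment.items() if f != fold)


# -- YOLO label files -------------------------------------------------------

def read_yolo_labels(path, image_size, missing_ok=True) -> LabeledImage:
    """Parse one `<stem>.txt` label file.  image_size: (width, height)."""
    width, height = image_size
    path = Path(path)
    if not path.exists():
        if not missing_ok:
            raise FileNotFoundError(path)
        warnings.warn(f"missing label file {path}; assuming zero boxes")
        return LabeledImage(str(path), width, height, ())
    boxes, problems = [], []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            problems.append(f"line {ln}: expected 5 fields, got {len(parts)}")
            continue
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:])
        except ValueError:
            problems.append(f"line {ln}: non-numeric field")
            continue
        if cid < 0:
            problems.append(f"line {ln}: negative class id")
        eps = 1e-6
        if not (-eps <= cx - w / 2 and cx + w / 2 <= 1 + eps
                and -eps <= cy - h / 2 and cy + h / 2 <= 1 + eps
                and w > 0 and h > 0):
            problems.append(f"line {ln}: box outside [0,1] or empty")
        boxes.append((cid, cx, cy, w, h))
    if problems:
        raise LabelValidationError(f"{path}: " + "; ".join(problems))
    return LabeledImage(str(path), width, height, tuple(boxes))


def write_yolo_labels(image: LabeledImage, path):
    lines = [f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
             for c, cx, cy, w, h in image.boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_manifest(path, train_dir, val_dir, names=None):
    names = names or CLASS_NAMES
    with open(path, "w") as fh:
        yaml.safe_dump({"train": str(train_dir), "val": str(val_dir),
                        "names": {int(k): v for k, v in names.items()}}, fh)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# -- tiling -----------------------------------------------------------------

def _clip_box_to_window(px_box, x0, y0, tile):
    """Clip a pixel box to the window; returns (clipped box or None,
    visible_fraction, clipped_flag)."""
    _, bx0, by0, bx1, by1 = px_box
    cx0, cy0 = max(bx0, x0), max(by0, y0)
    cx1, cy1 = min(bx1, x0 + tile), min(by1, y0 + tile)
    area = max(bx1 - bx0, 0) * max(by1 - by0, 0)
    vis_area = max(cx1 - cx0, 0) * max(cy1 - cy0, 0)
    if vis_area <= 0 or area <= 0:
        return None, 0.0, True
    clipped = not (cx0 == bx0 and cy0 == by0 and cx1 == bx1 and cy1 == by1)
    return (cx0, cy0, cx1, cy1), vis_area / area, clipped


def tile_image(src: LabeledImage, tile: int = 1024,
               min_visibility: float = 0.3) -> list:
    """Target-centred fixed-size crops with regenerated labels.

    Windows are centred on each target's centroid and clamped to the image
    bounds; windows whose anchor targets would duplicate an existing window
    (same clamped origin) are merged.  Images smaller than the tile in
    either dimension pass through untiled.  Boxes with visible fraction
    below ``min_visibility`` are dropped from a tile; boxes cut by a tile
    edge keep their class and are edge-flagged.
    """
    px = src.pixel_boxes()
    if src.width < tile or src.height < tile:
        flags = tuple(False for _ in src.boxes)
        return [TileRecord(src.path, (0, 0), tile, src.boxes, flags,
                           tuple(range(len(src.boxes))))]
    origins = []
    for row in px:
        cx, cy = (row[1] + row[3]) / 2, (row[2] + row[4]) / 2
        x0 = int(round(min(max(cx - tile / 2, 0), src.width - tile)))
        y0 = int(round(min(max(cy - tile / 2, 0), src.height - tile)))
        if (x0, y0) not in origins:
            origins.append((x0, y0))
    records = []
    for x0, y0 in origins:
        boxes, flags, idxs = [], [], []
        for bi, row in enumerate(px):
            clipped_box, vis, clipped = _clip_box_to_window(row, x0, y0, tile)
            if clipped_box is None or vis < min_visibility:
                continue
            bx0, by0, bx1, by1 = clipped_box
            cx = ((bx0 + bx1) / 2 - x0) / tile
            cy = ((by0 + by1) / 2 - y0) / tile
            bw, bh = (bx1 - bx0) / tile, (by1 - by0) / tile
            boxes.append((int(row[0]), cx, cy, bw, bh))
            flags.append(clipped)
            idxs.append(bi)
        records.append(TileRecord(src.path, (x0, y0), tile, tuple(boxes),
                                  tuple(flags), tuple(idxs)))
    return records


def tile_to_source_boxes(rec: TileRecord) -> np.ndarray:
    """De-normalize tile boxes and add the origin: [N,5] class+xyxy pixels."""
    if not rec.boxes:
        return np.zeros((0, 5), dtype=np.float64)
    arr = np.asarray(rec.boxes, dtype=np.float64)
    x_off, y_off = rec.origin
    cx, cy = arr[:, 1] * rec.size + x_off, arr[:, 2] * rec.size + y_off
    w, h = arr[:, 3] * rec.size, arr[:, 4] * rec.size
    return np.stack([arr[:, 0], cx - w / 2, cy - h / 2,
                     cx + w / 2, cy + h / 2], axis=1)


def write_tile_sidecar(rec: TileRecord, path):
    with open(path, "w") as fh:
        json.dump({"source": rec.source, "x_off": rec.origin[0],
                   "y_off": rec.origin[1], "size": rec.size,
                   "edge_flags": list(rec.edge_flags)}, fh)


# -- folds ------------------------------------------------------------------

def make_folds(images, k: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic stratified k-fold plan.

    ``images``: mapping image id -> LabeledImage (or iterable of
    LabeledImage, keyed by path).  Stratified by presence of the diseased
    class so each fold sees both classes; fold sizes differ by at most 1.
    """
    if not isinstance(images, dict):
        images = {im.path: im for im in images}
    n = len(images)
    if k > n:
        raise ValueError(f"cannot split {n} images into {k} folds")
    rng = np.random.default_rng(seed)
    has_disease = {i: any(b[0] == 1 for b in im.boxes) for i, im in images.items()}
    strata = [sorted(i for i in images if has_disease[i]),
              sorted(i for i in images if not has_disease[i])]
    # round-robin over shuffled strata; rotate the starting fold between
    # strata so combined fold sizes stay within 1 of each other
    assignment = {}
    offset = 0
    for group in strata:
        perm = rng.permutation(len(group))
        for pos, gi in enumerate(perm):
            assignment[group[gi]] = (pos + offset) % k
        offset += len(group)
    plan = FoldPlan(k, assignment)
    sizes = [len(plan.validation_ids(f)) for f in range(k)]
    assert max(sizes) - min(sizes) <= 1, sizes
    return plan


def fold_instance_table(images: dict, plan: FoldPlan) -> list:
    """Per-fold class-instance bookkeeping (training/validation rows)."""
    rows = []
    for f in range(plan.k):
        for part, ids in (("train", plan.training_ids(f)),
                          ("val", plan.validation_ids(f))):
            lemon = sum(sum(1 for b in images[i].boxes if b[0] == 0) for i in ids)
            disease = sum(sum(1 for b in images[i].boxes if b[0] == 1) for i in ids)
            rows.append({"fold": f, "part": part, "lemon": lemon,
                         "disease": disease, "total": lemon + disease})
    return rows


def save_fold_plan(plan: FoldPlan, path):
    with open(path, "w") as fh:
        json.dump({"k": plan.k, "assignment": plan.assignment}, fh, indent=0)


def load_fold_plan(path) -> FoldPlan:
    with open(path) as fh:
        d = json.load(fh)
    return FoldPlan(d["k"], dict(d["assignment"]))
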