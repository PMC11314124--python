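"""Synthetic orchard scenes with YOLO ground truth.

Stands in for field photographs of lemon trees: each scene is a foliage-
textured canvas carrying 1-6 roughly elliptical fruit targets of two
classes (0 = healthy, 1 = diseased; diseased fruit carry dark lesion
blobs), optional leaf-like occluders partially covering targets, and a
global illumination gain.  Fruit pixels live in a distinctive yellow hue
band that never occurs in the background, so ground truth can be verified
independently by colour masking (`recover_boxes_by_color`).

Ground-truth boxes tightly bound the *visible* (un-occluded) extent of
each fruit; targets that end up more than 95 % occluded are resampled.
All randomness flows from ``SceneSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .data import CLASS_NAMES, LabeledImage, write_manifest, write_yolo_labels

# fruit colours are the only yellows in a scene (high R, high G, low B)
FRUIT_RGB = np.array([215, 200, 40], dtype=np.float32)
DISEASED_FRUIT_RGB = np.array([200, 170, 45], dtype=np.float32)
LESION_RGB = np.array([92, 58, 25], dtype=np.float32)
LEAF_RGB = np.array([40, 95, 35], dtype=np.float32)


@dataclass(frozen=True)
class SceneSpec:
    """Generation parameters for one scene (defaults emulate the field
    dataset: 1-6 targets per image, ~14 % diseased instances, occasional
    leaf occlusion and lighting variation)."""
    width: int = 1024
    height: int = 1024
    n_targets: int | None = None       # None: draw uniformly from 1..6
    max_targets: int = 6
    fraction_diseased: float = 0.143   # diseased share of instances
    occlusion_probability: float = 0.3
    illumination_range: tuple = (0.65, 1.25)
    target_size_range: tuple = (0.05, 0.18)  # fruit radius / min(canvas)
    lesion_count_range: tuple = (1, 6)
    lesion_area_range: tuple = (0.05, 0.30)  # lesion / fruit area
    seed: int = 0

    def __post_init__(self):
        if not (640 <= min(self.width, self.height)
                and max(self.width, self.height) <= 3000):
            raise ValueError("canvas size must lie in 640..3000 px")
        if self.n_targets is not None and not 1 <= self.n_targets <= 6:
            raise ValueError("n_targets must lie in 1..6")


def _ellipse_mask(h, w, cx, cy, rx, ry, angle, yy, xx):
    ca, sa = np.cos(angle), np.sin(angle)
    dx, dy = xx - cx, yy - cy
    u = (dx * ca + dy * sa) / rx
    v = (-dx * sa + dy * ca) / ry
    return u * u + v * v <= 1.0


def _foliage_background(rng, h, w):
    """Smooth low-frequency green/brown mottle (no yellow hues)."""
    small = rng.random((h // 32 + 2, w // 32 + 2, 3), dtype=np.float32)
    ys = np.linspace(0, small.shape[0] - 1.001, h)
    xs = np.linspace(0, small.shape[1] - 1.001, w)
    y0, x0 = ys.astype(int), xs.astype(int)
    fy, fx = (ys - y0)[:, None, None], (xs - x0)[None, :, None]
    a = small[y0][:, x0]
    b = small[y0][:, x0 + 1]
    c = small[y0 + 1][:, x0]
    d = small[y0 + 1][:, x0 + 1]
    t = a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx + c * fy * (1 - fx) + d * fy * fx
    base = np.array([[35, 70, 30], [70, 90, 45], [55, 45, 30]], np.float32)
    img = t @ base
    return np.clip(img, 0, 255)


def generate_scene(spec: SceneSpec):
    """Render one scene.  Returns (image uint8 HWC RGB, LabeledImage)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = _foliage_background(rng, h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)

    n = spec.n_targets or int(rng.integers(1, spec.max_targets + 1))
    rmin = spec.target_size_range[0] * min(h, w)
    rmax = spec.target_size_range[1] * min(h, w)
    boxes = []
    placed = []      # fruit ellipse bounds, to limit fruit-on-fruit overlap
    for _ in range(n):
        for _attempt in range(20):
            rx = float(rng.uniform(rmin, rmax))
            ry = rx * float(rng.uniform(0.8, 1.1))
            cx = float(rng.uniform(rx, w - rx))
            cy = float(rng.uniform(ry, h - ry))
            # fruits never touch: keeps every target separable in the render
            cand = (cx - rx, cy - ry, cx + rx, cy + ry)
            if any(_boxes_intersect(cand, p, margin=5.0) for p in placed):
                continue
            ang = float(rng.uniform(0, np.pi))
            diseased = rng.random() < spec.fraction_diseased
            fruit = _ellipse_mask(h, w, cx, cy, rx, ry, ang, yy, xx)

            colour = DISEASED_FRUIT_RGB if diseased else FRUIT_RGB
            jitter = rng.normal(0, 6, 3).astype(np.float32)
            # radial shading keeps the fruit looking curved
            rr = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
            shade = np.clip(1.05 - 0.35 * rr, 0.55, 1.05)
            layer = img.copy()
            layer[fruit] = np.clip((colour + jitter)[None, :] *
                                   shade[fruit][:, None], 0, 255)
            if diseased:
                n_les = int(rng.integers(spec.lesion_count_range[0],
                                         spec.lesion_count_range[1] + 1))
                fruit_area = float(fruit.sum())
                for _ in range(n_les):
                    frac = rng.uniform(*spec.lesion_area_range) / n_les
                    lr = max(np.sqrt(frac * fruit_area / np.pi), 2.0)
                    lcx = cx + rng.uniform(-0.6, 0.6) * rx
                    lcy = cy + rng.uniform(-0.6, 0.6) * ry
                    lesion = _ellipse_mask(h, w, lcx, lcy, lr,
                                           lr * rng.uniform(0.6, 1.0),
                                           rng.uniform(0, np.pi), yy, xx)
                    lesion &= fruit
                    layer[lesion] = LESION_RGB + rng.normal(0, 4, 3)

            visible = fruit.copy()
            if rng.random() < spec.occlusion_probability:
                ocx = cx + rng.uniform(-0.8, 0.8) * rx
                ocy = cy + rng.uniform(-0.8, 0.8) * ry
                occ = _ellipse_mask(h, w, ocx, ocy,
                                    rx * rng.uniform(0.5, 1.2),
                                    ry * rng.uniform(0.25, 0.6),
                                    rng.uniform(0, np.pi), yy, xx)
                layer[occ] = LEAF_RGB + rng.normal(0, 5, 3)
                visible &= ~occ
            vis_frac = visible.sum() / max(fruit.sum(), 1)
            if vis_frac < 0.05:
                continue    # >95 % occluded: resample this target
            img = layer
            placed.append(cand)
            ys, xs = np.nonzero(visible)
            x0, x1 = xs.min(), xs.max() + 1
            y0, y1 = ys.min(), ys.max() + 1
            boxes.append((int(diseased),
                          float((x0 + x1) / 2 / w), float((y0 + y1) / 2 / h),
                          float((x1 - x0) / w), float((y1 - y0) / h)))
            break

    gain = rng.uniform(*spec.illumination_range)
    grad = 1.0 + 0.12 * ((yy / h) - 0.5) * rng.choice([-1.0, 1.0])
    img = np.clip(img * gain * grad[..., None], 0, 255).astype(np.uint8)
    labeled = LabeledImage(path="", width=w, height=h, boxes=tuple(boxes))
    return img, labeled


def _boxes_intersect(a, b, margin=0.0):
    return (a[0] - margin < b[2] and b[0] < a[2] + margin
            and a[1] - margin < b[3] and b[1] < a[3] + margin)


def recover_boxes_by_color(image: np.ndarray, min_area: int = 60) -> list:
    """Independent ground-truth check: connected components of the fruit
    colour mask (yellow rind or red-brown lesion; both rules are invariant
    to the scene's illumination gain), returned as xyxy pixel boxes."""
    img = image.astype(np.float32)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    yellow = (r > 80) & (g > 70) & (b < 0.6 * np.minimum(r, g)) & (r + g > 180)
    lesion = (r > 1.4 * g) & (r < 2.0 * g) & (b < 0.65 * g) & (r > 30)
    mask = yellow | lesion
    lbl = _label_components(mask)
    out = []
    for k in range(1, lbl.max() + 1):
        ys, xs = np.nonzero(lbl == k)
        if ys.size < min_area:
            continue
        out.append((float(xs.min()), float(ys.min()),
                    float(xs.max() + 1), float(ys.max() + 1)))
    return out


def _label_components(mask: np.ndarray) -> np.ndarray:
    """4-connected component labelling (iterative flood fill)."""
    lbl = np.zeros(mask.shape, dtype=np.int32)
    cur = 0
    for sy, sx in zip(*np.nonzero(mask & (lbl == 0))):
        if lbl[sy, sx]:
            continue
        cur += 1
        stack = [(sy, sx)]
        lbl[sy, sx] = cur
        while stack:
            y, x = stack.pop()
            for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                        and mask[ny, nx] and not lbl[ny, nx]):
                    lbl[ny, nx] = cur
                    stack.append((ny, nx))
    return lbl


def generate_dataset(n_images: int, spec: SceneSpec, out_dir,
                     overwrite: bool = False):
    """Write `n_images` scenes + YOLO labels + manifest under out_dir."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty")
    img_dir, lbl_dir = out / "images", out / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    records = {}
    for i in range(n_images):
        sub = replace(spec, seed=int(np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(i,)).generate_state(1)[0] % 2**31))
        img, labeled = generate_scene(sub)
        stem = f"scene_{i:04d}"
        Image.fromarray(img).save(img_dir / f"{stem}.png")
        labeled = LabeledImage(str(img_dir / f"{stem}.png"), labeled.width,
                               labeled.height, labeled.boxes)
        write_yolo_labels(labeled, lbl_dir / f"{stem}.txt")
        records[stem] = labeled
    manifest = out / "manifest.yaml"
    write_manifest(manifest, img_dir, img_dir, CLASS_NAMES)
    return manifest, records


def scenes_as_batch(specs, size: int):
    """Render scenes and letterbox them into one [N,3,size,size] float batch.

    Returns (batch in [0,1], list of per-image pixel gt arrays [M,5]
    (class,xyxy) in canvas coordinates)."""
    from .arch import letterbox
    batch, gts = [], []
    for spec in specs:
        img, labeled = generate_scene(spec)
        canvas, scale, (dx, dy) = letterbox(img, size)
        batch.append(canvas.astype(np.float32).transpose(2, 0, 1) / 255.0)
        px = labeled.pixel_boxes()
        if len(px):
            px = px.copy()
            px[:, 1::2] = px[:, 1::2] * scale + dx
            px[:, 2::2] = px[:, 2::2] * scale + dy
        gts.append(px)
    return np.stack(batch), gts
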