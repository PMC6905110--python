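"""Seeded synthetic field scenes with dot ground truth.

Emulates the statistical structure of in-field wheat-spike imagery: many
elongated, mutually occluding objects clustered into row-like patches on a
textured canopy background, with per-scene illumination jitter and optional
defocus blur. The generator is deliberately not photo-realistic — it exists
so the counting pipeline (targets, training, merging, evaluation) can be
exercised end to end with exact ground truth and no external data.

Objects are anisotropic Gaussian-profile ellipses (length 15-60 px, aspect
2-5, uniform orientation) composited back to front; the annotation dot of
each object is its centroid. Object centers follow a Thomas-style cluster
process: Poisson parents, offspring assigned multinomially and scattered
isotropically around their parent, conditioned on the per-image total count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

from .errors import ValidationError
from .targets import DotAnnotation

__all__ = ["SceneConfig", "Scene", "generate_scene", "generate_dataset",
           "load_dataset", "scenes_for_benchmark"]


@dataclass(frozen=True)
class SceneConfig:
    """Generative configuration; identical config + seed give identical scenes."""

    image_hw: Tuple[int, int] = (912, 1216)
    count_range: Tuple[int, int] = (0, 1462)
    length_range: Tuple[float, float] = (15.0, 60.0)
    aspect_range: Tuple[float, float] = (2.0, 5.0)
    mean_offspring: float = 8.0          # objects per cluster parent
    cluster_sigma: float = 40.0          # isotropic offspring scatter, px
    profile_sharpness: float = 3.0       # 1 = soft Gaussian blob, >=2 = solid body
    gain_range: Tuple[float, float] = (0.7, 1.3)
    gamma_range: Tuple[float, float] = (0.8, 1.25)
    blur_sigma_range: Tuple[float, float] = (0.0, 3.0)
    background_scale: int = 32           # px per background texture cell
    border_margin: float = 0.0           # keep all dots >= this far from borders
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        h, w = self.image_hw
        cmin, cmax = self.count_range
        if h < 8 or w < 8:
            raise ValidationError(f"canvas {h}x{w} too small")
        if cmin < 0 or cmax < cmin:
            raise ValidationError(f"bad count_range {self.count_range}")
        if cmax > (h * w) // 64:
            raise ValidationError(
                f"count_range max {cmax} infeasible for a {h}x{w} canvas")
        if 2 * self.border_margin >= min(h, w):
            raise ValidationError("border_margin leaves no room for dots")


@dataclass(frozen=True)
class Scene:
    image: np.ndarray        # (H, W, 3) uint8
    dots: DotAnnotation
    config: SceneConfig
    seed: int


def _sample_centers(cfg: SceneConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Thomas-style cluster process conditioned on exactly n points in-canvas."""
    h, w = cfg.image_hw
    m = cfg.border_margin
    if n == 0:
        return np.empty((0, 2))
    n_parents = max(1, int(rng.poisson(n / cfg.mean_offspring)))
    parents = np.column_stack([
        rng.uniform(m, w - m, n_parents),
        rng.uniform(m, h - m, n_parents),
    ])
    assign = rng.integers(0, n_parents, n)
    pts = parents[assign] + rng.normal(0.0, cfg.cluster_sigma, (n, 2))
    # reflect out-of-bounds offspring back into the admissible region
    lo = np.array([m, m])
    hi = np.array([w - m, h - m]) - 1e-6
    span = hi - lo
    pts = lo + np.abs((pts - lo) % (2 * span) - span)
    return pts


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_hw
    cell = cfg.background_scale
    gh, gw = h // cell + 2, w // cell + 2
    base = np.array([0.22, 0.30, 0.12])  # muted canopy green-brown
    coarse = base + rng.normal(0.0, 0.06, (gh, gw, 3))
    fine = zoom(coarse, (h / gh, w / gw, 1), order=1)[:h, :w]
    fine += rng.normal(0.0, 0.015, fine.shape)
    return np.clip(fine, 0.0, 1.0)


def generate_scene(config: SceneConfig, seed: Optional[int] = None) -> Scene:
    """Render one scene; the dot list is exactly the rendered object centroids."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValidationError("a seed is required (config.seed or argument)")
    rng = np.random.default_rng(seed)
    h, w = config.image_hw
    n = int(rng.integers(config.count_range[0], config.count_range[1] + 1))
    centers = _sample_centers(config, n, rng)
    img = _background(config, rng)

    lengths = rng.uniform(*config.length_range, n)
    aspects = rng.uniform(*config.aspect_range, n)
    thetas = rng.uniform(0.0, np.pi, n)
    # wheat-spike straw tones, jittered per object
    colors = np.clip(
        np.array([0.78, 0.72, 0.38]) + rng.normal(0.0, 0.07, (n, 3)), 0.0, 1.0)

    for k in range(n):  # back-to-front alpha compositing
        cx, cy = centers[k]
        L, a, th = lengths[k], aspects[k], thetas[k]
        su, sv = L / 4.0, (L / a) / 4.0  # Gaussian radii along/across the axis
        r = int(np.ceil(2.5 * su)) + 1
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        ys = np.arange(y0, y1) - cy
        xs = np.arange(x0, x1) - cx
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        u = np.cos(th) * xx + np.sin(th) * yy
        v = -np.sin(th) * xx + np.cos(th) * yy
        # super-Gaussian: flat-topped solid body with a soft edge; sharpness 1
        # degenerates to a smooth Gaussian blob
        rr = (u / su) ** 2 + (v / sv) ** 2
        alpha = np.exp(-0.5 * rr ** config.profile_sharpness)
        alpha = np.where(alpha < 0.05, 0.0, alpha)
        img[y0:y1, x0:x1] = (alpha[..., None] * colors[k]
                             + (1.0 - alpha[..., None]) * img[y0:y1, x0:x1])

    gain = rng.uniform(*config.gain_range)
    gamma = rng.uniform(*config.gamma_range)
    img = np.clip(gain * np.power(np.clip(img, 0.0, 1.0), gamma), 0.0, 1.0)
    blur = rng.uniform(*config.blur_sigma_range)
    if blur > 0.05:
        for c in range(3):
            img[..., c] = gaussian_filter(img[..., c], blur)
    image = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    dots = DotAnnotation(centers, (h, w))
    return Scene(image, dots, config, int(seed))


# --------------------------------------------------------------------------
# Dataset generation on disk
# --------------------------------------------------------------------------

_SPLITS = ("train", "val", "test")


def _write_annotation_csv(path: Path, name: str, dots: DotAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("image,x,y\n")
        for x, y in dots.points:
            fh.write(f"{name},{x:.4f},{y:.4f}\n")


def generate_dataset(config: SceneConfig, n_train: int, n_val: int, n_test: int,
                     seed: int, outdir, overwrite: bool = False) -> dict:
    """Write PNG images, CSV annotations and a JSON manifest for three splits.

    Per-image seeds are drawn from a generator seeded with ``seed``, one
    disjoint block per split, so splits never share a scene.
    """
    if min(n_train, n_val, n_test) < 1:
        raise ValidationError("each split needs at least one image")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise ValidationError(
            f"output directory {outdir} exists and is not empty "
            "(pass overwrite to replace)")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    counts = {"train": n_train, "val": n_val, "test": n_test}
    manifest = {
        "seed": int(seed),
        "config": dataclasses.asdict(config),
        "splits": {},
    }
    for split in _SPLITS:
        entries = []
        for i in range(counts[split]):
            sseed = int(rng.integers(0, 2 ** 31))
            scene = generate_scene(config, sseed)
            name = f"{split}_{i:04d}"
            img_path = outdir / f"{name}.png"
            ann_path = outdir / f"{name}.csv"
            Image.fromarray(scene.image).save(img_path)
            _write_annotation_csv(ann_path, name, scene.dots)
            entries.append({
                "image": img_path.name,
                "annotation": ann_path.name,
                "seed": sseed,
                "count": len(scene.dots),
            })
        manifest["splits"][split] = entries
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_dataset(outdir) -> dict:
    """Load a generated dataset back as {split: [(image, dots), ...]}."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    out = {}
    for split, entries in manifest["splits"].items():
        pairs = []
        for e in entries:
            img = np.asarray(Image.open(outdir / e["image"]).convert("RGB"))
            pts = np.loadtxt(outdir / e["annotation"], delimiter=",",
                             skiprows=1, usecols=(1, 2), ndmin=2)
            pairs.append((img, DotAnnotation(pts, img.shape[:2])))
        out[split] = pairs
    return out


def scenes_for_benchmark(config: SceneConfig, n: int, seed: int) -> List[Scene]:
    """In-memory list of scenes (no disk round trip) for tests and benchmarks."""
    rng = np.random.default_rng(seed)
    return [generate_scene(config, int(rng.integers(0, 2 ** 31))) for _ in range(n)]
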