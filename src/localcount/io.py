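"""File formats: dot annotations, array grids, model checkpoints, overlays.

Annotations travel as CSV (``image,x,y`` header, one row per dot) or JSON
(``{"image": ..., "points": [[x, y], ...]}``). Density maps and count grids
are stored as compressed ``.npz`` with a JSON sidecar carrying the
window/stride/pad metadata. A checkpoint is a single ``.npz`` bundling the
weight arrays with a JSON-encoded header (variant name, architecture spec,
normalization means, geometry).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from . import arch, netcore
from .errors import ValidationError
from .targets import DotAnnotation, LocalCountMap

__all__ = [
    "read_annotations_csv",
    "write_annotations_csv",
    "read_annotations_json",
    "write_annotations_json",
    "save_grid",
    "load_grid",
    "save_checkpoint",
    "load_checkpoint",
    "save_overlay",
    "load_image",
]


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


# ---------------------------------------------------------------- annotations

def read_annotations_csv(path, image_hw: Tuple[int, int],
                         image: Optional[str] = None) -> DotAnnotation:
    df = pd.read_csv(path)
    missing = {"image", "x", "y"} - set(df.columns)
    if missing:
        raise ValidationError(f"annotation CSV missing columns: {sorted(missing)}")
    if image is not None:
        df = df[df["image"] == image]
    return DotAnnotation(df[["x", "y"]].to_numpy(dtype=float), image_hw)


def write_annotations_csv(path, image: str, dots: DotAnnotation) -> None:
    pd.DataFrame({
        "image": image,
        "x": dots.points[:, 0],
        "y": dots.points[:, 1],
    }).to_csv(path, index=False)


def read_annotations_json(path, image_hw: Tuple[int, int]) -> DotAnnotation:
    with open(path) as fh:
        d = json.load(fh)
    if "points" not in d:
        raise ValidationError("annotation JSON must contain a 'points' list")
    return DotAnnotation(np.asarray(d["points"], dtype=float).reshape(-1, 2),
                         image_hw)


def write_annotations_json(path, image: str, dots: DotAnnotation) -> None:
    with open(path, "w") as fh:
        json.dump({"image": image, "points": dots.points.tolist()}, fh)


# ----------------------------------------------------------------- array grids

def save_grid(path, values: np.ndarray, meta: Dict) -> None:
    path = Path(path)
    np.savez_compressed(path, values=values)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_grid(path) -> Tuple[np.ndarray, Dict]:
    path = Path(path)
    values = np.load(path)["values"]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, meta


def save_local_count_map(path, lcm: LocalCountMap) -> None:
    save_grid(path, lcm.values, {
        "window": lcm.window, "stride": lcm.stride,
        "origin_offset": lcm.origin_offset, "image_hw": list(lcm.image_hw),
    })


# ----------------------------------------------------------------- checkpoints

def save_checkpoint(path, model: "netcore.Model") -> None:
    header = {
        "variant": model.variant.name,
        "spec": arch.spec_to_dict(model.variant.spec),
        "means": model.means.tolist(),
    }
    arrays = model.net.state_dict()
    np.savez_compressed(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> "netcore.Model":
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        state = {k: z[k] for k in z.files if k != "__header__"}
    model = netcore.build_model(header["variant"], seed=0)
    model.net.load_state_dict(state)
    model.means[...] = np.asarray(header["means"], dtype=np.float32)
    return model


# -------------------------------------------------------------------- overlays

def save_overlay(path, image: np.ndarray, count_map: np.ndarray,
                 alpha: float = 0.55, cmap: str = "jet") -> None:
    """False-color count-map overlay on the source image, written as PNG."""
    import matplotlib

    m = np.asarray(count_map, dtype=np.float64)
    vmax = m.max() if m.max() > 0 else 1.0
    colored = matplotlib.colormaps[cmap](m / vmax)[..., :3]
    base = np.asarray(image, dtype=np.float64) / 255.0
    out = (1 - alpha) * base + alpha * colored
    Image.fromarray(np.clip(out * 255, 0, 255).astype(np.uint8)).save(path)
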