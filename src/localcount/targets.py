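"""Regression targets for local-count learning.

Dot annotations (one sub-pixel point per object) are first smoothed into a
density map — a sum of unit-mass Gaussian kernels, so the map's integral is
the object count — and the density map is then integrated over a lattice of
fixed windows to produce the local-count grid the networks regress.

Conventions: coordinates are 0-based pixel centers with x = column and
y = row; windows are half-open ``[a, a + window)``. Each Gaussian kernel is
truncated and then renormalized to unit mass, so dots near the border still
contribute exactly one object to the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = [
    "DotAnnotation",
    "DensityMap",
    "LocalCountMap",
    "density_from_dots",
    "local_counts",
]


@dataclass(frozen=True)
class DotAnnotation:
    """Point annotations: ``points`` is an (N, 2) float array of (x, y)."""

    points: np.ndarray
    image_hw: Tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        h, w = self.image_hw
        if len(pts):
            x, y = pts[:, 0], pts[:, 1]
            bad = (x < 0) | (x >= w) | (y < 0) | (y >= h)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"dot {i} at ({x[i]:.2f}, {y[i]:.2f}) outside "
                    f"[0, {w}) x [0, {h})")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DensityMap:
    """H x W non-negative grid whose integral equals the dot count."""

    values: np.ndarray
    sigma: float

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class LocalCountMap:
    """Window-integrated counts on a stride lattice.

    Cell (i, j) integrates the density over the half-open ``window`` x
    ``window`` square starting at ``(stride*i + origin_offset,
    stride*j + origin_offset)`` in unpadded image coordinates (area outside
    the image contributes zero). ``origin_offset`` is negative when the
    window extends past the image border (e.g. the full-receptive-field
    target), zero for the canonical central-window target.
    """

    values: np.ndarray
    window: int
    stride: int
    origin_offset: int
    image_hw: Tuple[int, int]

    @property
    def grid_hw(self) -> Tuple[int, int]:
        return self.values.shape


def density_from_dots(dots: DotAnnotation, sigma: float = 4.0,
                      truncate: float = 4.0) -> DensityMap:
    """Sum of per-dot unit-mass truncated Gaussians evaluated at pixel centers.

    Each kernel is clipped to the image and renormalized to unit mass, so the
    map integral equals ``len(dots)`` regardless of boundary clipping.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    h, w = dots.image_hw
    values = np.zeros((h, w), dtype=np.float64)
    r = int(np.ceil(truncate * sigma))
    for x, y in dots.points:
        cx, cy = int(np.floor(x)), int(np.floor(y))
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        xs = np.arange(x0, x1, dtype=np.float64) - x
        ys = np.arange(y0, y1, dtype=np.float64) - y
        kern = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
        mass = kern.sum()
        if mass <= 0:  # pragma: no cover - unreachable for r >= 1
            continue
        values[y0:y1, x0:x1] += kern / mass
    return DensityMap(values, float(sigma))


def _integral_image(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=s[1:, 1:])
    return s


def local_counts(density: DensityMap, window: int = 64, stride: int = 16,
                 pad: int = 15, context: int = 15,
                 image_hw: Optional[Tuple[int, int]] = None) -> LocalCountMap:
    """Integrate the density over the window lattice of a counting network.

    The lattice is defined by the network geometry: grid cell (i, j)
    corresponds to a receptive field of extent ``window + 2*context`` placed
    at ``stride*(i, j) - pad`` on the zero-padded canvas, and the regression
    target is the count inside the central ``window`` square of that field,
    which starts at ``stride*i + (context - pad)`` in image coordinates.
    Canonical geometry (window 64, stride 16, pad 15, context 15) aligns the
    target grid exactly with the network's output grid; the
    full-receptive-field target uses window 94, context 0.

    Computed with a summed-area table, so each entry is an exact windowed sum.
    """
    if window < 1 or stride < 1 or pad < 0 or context < 0:
        raise ValidationError(
            f"invalid geometry window={window} stride={stride} pad={pad} "
            f"context={context}")
    h, w = density.values.shape
    if image_hw is not None and tuple(image_hw) != (h, w):
        raise GeometryError(
            f"density map is {h}x{w} but target geometry expects "
            f"{image_hw[0]}x{image_hw[1]}")
    extent = window + 2 * context
    gh = (h + 2 * pad - extent) // stride + 1
    gw = (w + 2 * pad - extent) // stride + 1
    if gh < 1 or gw < 1:
        raise GeometryError(
            f"image {h}x{w} too small for window {window} + context "
            f"{context} at pad {pad}")
    offset = context - pad
    # margin so every window, even those overhanging the border, stays in-canvas
    m = max(0, -offset)
    canvas = np.zeros((h + 2 * m, w + 2 * m), dtype=np.float64)
    canvas[m:m + h, m:m + w] = density.values
    sat = _integral_image(canvas)
    i = np.arange(gh) * stride + offset + m
    j = np.arange(gw) * stride + offset + m
    y0, y1 = i, np.minimum(i + window, canvas.shape[0])
    x0, x1 = j, np.minimum(j + window, canvas.shape[1])
    vals = (sat[np.ix_(y1, x1)] - sat[np.ix_(y0, x1)]
            - sat[np.ix_(y1, x0)] + sat[np.ix_(y0, x0)])
    vals = np.maximum(vals, 0.0)  # guard against cumsum round-off
    return LocalCountMap(vals, window, stride, offset, (h, w))
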