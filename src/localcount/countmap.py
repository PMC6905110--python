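"""Merge overlapping local counts into a normalized full-resolution count map.

A fully convolutional counting network emits one local count per stride step;
adjacent windows overlap, so the raw grid cannot simply be summed. Each
window's count is first redistributed uniformly over its pixel footprint
(count / window**2 per pixel, footprints clipped to the image), and every
pixel is then divided by its coverage multiplicity — the number of windows
covering it, computed after clipping so border pixels are not under-weighted.
The integral of the resulting map is the image-level count estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import CoverageError, GeometryError

__all__ = ["RawCountGrid", "NormalizedCountMap", "merge_normalize", "image_count"]


@dataclass(frozen=True)
class RawCountGrid:
    """Per-window local counts from a counting network.

    Window (i, j) covers the half-open square of side ``window`` starting at
    ``(stride*i + origin_offset, stride*j + origin_offset)`` in image
    coordinates; parts outside the image are clipped.
    """

    values: np.ndarray
    window: int = 64
    stride: int = 16
    origin_offset: int = 0
    image_hw: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2:
            raise GeometryError(f"count grid must be 2-D, got shape {self.values.shape}")
        h, w = self.image_hw
        if h < 1 or w < 1:
            raise GeometryError(f"image_hw must be positive, got {self.image_hw}")


@dataclass(frozen=True)
class NormalizedCountMap:
    """Per-pixel count map on the original canvas; its integral is the count."""

    values: np.ndarray
    image_hw: Tuple[int, int]


def _footprints(grid: RawCountGrid):
    h, w = grid.image_hw
    gh, gw = grid.values.shape
    s, win, off = grid.stride, grid.window, grid.origin_offset
    y0 = np.clip(np.arange(gh) * s + off, 0, h)
    y1 = np.clip(np.arange(gh) * s + off + win, 0, h)
    x0 = np.clip(np.arange(gw) * s + off, 0, w)
    x1 = np.clip(np.arange(gw) * s + off + win, 0, w)
    return y0, y1, x0, x1


def merge_normalize(grid: RawCountGrid) -> NormalizedCountMap:
    """Uniform redistribution over window footprints + coverage division.

    Separable along rows and columns: the deposit and the coverage are both
    outer products of 1-D interval indicators, so the accumulation runs on
    1-D difference arrays instead of per-window 2-D slices.
    """
    h, w = grid.image_hw
    gh, gw = grid.values.shape
    y0, y1, x0, x1 = _footprints(grid)
    if np.any(y1 <= y0) or np.any(x1 <= x0):
        raise GeometryError("a window footprint is entirely outside the image")

    # coverage multiplicity via 1-D interval stabs (after clipping)
    def cover_1d(a0, a1, n):
        d = np.zeros(n + 1, dtype=np.float64)
        np.add.at(d, a0, 1.0)
        np.add.at(d, a1, -1.0)
        return np.cumsum(d[:n])

    cov = np.outer(cover_1d(y0, y1, h), cover_1d(x0, x1, w))
    if np.any(cov == 0):
        raise CoverageError(
            "pixels with zero window coverage; image size is not compatible "
            "with the window/stride lattice")

    # deposits via a 2-D difference array: four corner scatters + cumsums;
    # each count spreads at c/window^2 per pixel, so a window overhanging the
    # border deposits only its in-canvas share — part of the aggregation
    # convention (only lattices with negative offsets are affected)
    dens = grid.values / float(grid.window * grid.window)
    d = np.zeros((h + 1, w + 1), dtype=np.float64)
    yy0, yy1 = np.repeat(y0, gw), np.repeat(y1, gw)
    xx0, xx1 = np.tile(x0, gh), np.tile(x1, gh)
    v = dens.ravel()
    np.add.at(d, (yy0, xx0), v)
    np.add.at(d, (yy0, xx1), -v)
    np.add.at(d, (yy1, xx0), -v)
    np.add.at(d, (yy1, xx1), v)
    acc = np.cumsum(np.cumsum(d, axis=0), axis=1)[:h, :w]
    return NormalizedCountMap(acc / cov, (h, w))


def image_count(cmap: NormalizedCountMap) -> float:
    """Integrate the normalized count map: the image-level count estimate."""
    return float(cmap.values.sum())
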