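"""Deterministic raster tiling with overlap, and probability stitching.

A :class:`TileGrid` decomposes an H x W raster into fixed-size windows
advancing by ``stride = floor(tile * (1 - overlap))``, with a final row and
column of tiles anchored flush to the bottom/right edge so coverage is
total.  Windows are 0-based, half-open ``(row, col, h, w)``, enumerated
row-major.

Stitching averages per-class probabilities over all tiles covering a pixel,
renormalises, and takes the argmax; ties break toward the lower class ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TileGrid", "make_grid", "stitch"]

N_CLASSES = 5


@dataclass
class TileGrid:
    height: int
    width: int
    tile: tuple[int, int]
    overlap: float
    windows: list[tuple[int, int, int, int]]

    def __len__(self) -> int:
        return len(self.windows)

    def to_dict(self) -> dict:
        return {
            "height": self.height,
            "width": self.width,
            "tile": list(self.tile),
            "overlap": self.overlap,
            "windows": [list(w) for w in self.windows],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TileGrid":
        return cls(
            height=int(d["height"]),
            width=int(d["width"]),
            tile=tuple(d["tile"]),
            overlap=float(d["overlap"]),
            windows=[tuple(w) for w in d["windows"]],
        )


def _origins(extent: int, tile: int, stride: int) -> list[int]:
    starts = list(range(0, extent - tile + 1, stride))
    if starts[-1] + tile < extent:
        starts.append(extent - tile)  # flush-edge anchor
    return starts


def make_grid(h: int, w: int, tile: int | tuple[int, int], overlap: float = 0.0) -> TileGrid:
    """Enumerate tile windows covering an h x w raster.

    ``tile`` is a side length or (tile_h, tile_w); ``overlap`` is the
    fractional overlap between successive tiles, in [0, 1).
    """
    th, tw = (tile, tile) if np.isscalar(tile) else tile
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap must be in [0, 1); got {overlap}")
    if th > h or tw > w:
        raise ValueError(f"tile {th}x{tw} larger than raster {h}x{w}")
    stride_r = max(1, int(np.floor(th * (1.0 - overlap))))
    stride_c = max(1, int(np.floor(tw * (1.0 - overlap))))
    windows = [
        (r, c, th, tw)
        for r in _origins(h, th, stride_r)
        for c in _origins(w, tw, stride_c)
    ]
    return TileGrid(height=h, width=w, tile=(th, tw), overlap=overlap, windows=windows)


def stitch(
    tiles: list[tuple[tuple[int, int, int, int], np.ndarray]],
    grid: TileGrid,
    n_classes: int = N_CLASSES,
) -> tuple[np.ndarray, np.ndarray]:
    """Blend per-tile class-probability stacks into one full-raster map.

    ``tiles`` pairs each window with a (n_classes, h, w) probability array.
    Returns ``(hard, soft)``: hard integer labels 1..n_classes and the
    blended (n_classes, H, W) probability stack.  Raises if any grid pixel
    is left uncovered.
    """
    acc = np.zeros((n_classes, grid.height, grid.width))
    cnt = np.zeros((grid.height, grid.width))
    for (r, c, h, w), probs in tiles:
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape != (n_classes, h, w):
            raise ValueError(
                f"tile at {(r, c)} has probability shape {probs.shape}, "
                f"expected {(n_classes, h, w)}"
            )
        acc[:, r : r + h, c : c + w] += probs
        cnt[r : r + h, c : c + w] += 1.0
    if (cnt == 0).any():
        gaps = np.argwhere(cnt == 0)
        raise ValueError(
            f"{len(gaps)} pixels uncovered by tiles; first gaps (row, col): "
            f"{[tuple(g) for g in gaps[:5]]}"
        )
    soft = acc / cnt
    total = soft.sum(axis=0)
    nz = total > 0
    soft[:, nz] /= total[nz]
    # argmax returns the first maximal index -> ties break to the lower class ID
    hard = np.argmax(soft, axis=0).astype(np.int64) + 1
    return hard, soft
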