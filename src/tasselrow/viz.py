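"""Overlay rendering and per-frame record output.

Colour scheme of the overlays: white crop-row detection lines, pink
navigation line, optional blue manual reference; ROI boxes are colour-coded
by status (green feature, yellow sparse-corrected, red deviated, gray
empty).  Records are JSON lines, one object per frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage.draw import line as draw_line

from .line_fitting import DetectionResult, Line
from .roi_tracker import RoiChain, RoiStatus

__all__ = ["draw_overlay", "write_records"]

_STATUS_COLORS = {
    RoiStatus.FEATURE: (0, 200, 0),
    RoiStatus.SPARSE_CORRECTED: (230, 200, 0),
    RoiStatus.DEVIATED: (220, 30, 30),
    RoiStatus.EMPTY: (128, 128, 128),
}


def _draw_infinite_line(canvas: np.ndarray, line: Line, color: tuple[int, int, int]) -> None:
    h = canvas.shape[0]
    y0, y1 = 0, h - 1
    x0, x1 = int(round(line.x_at(y0))), int(round(line.x_at(y1)))
    rr, cc = draw_line(y0, x0, y1, x1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[keep], cc[keep]] = color


def _draw_box(canvas: np.ndarray, r0: int, r1: int, c0: int, c1: int, color) -> None:
    h, w = canvas.shape[:2]
    r0, r1 = max(0, r0), min(h - 1, r1 - 1)
    c0, c1 = max(0, c0), min(w - 1, c1 - 1)
    if r0 > r1 or c0 > c1:
        return
    canvas[r0, c0 : c1 + 1] = color
    canvas[r1, c0 : c1 + 1] = color
    canvas[r0 : r1 + 1, c0] = color
    canvas[r0 : r1 + 1, c1] = color


def draw_overlay(
    img: np.ndarray,
    result: DetectionResult | None = None,
    chains: tuple[RoiChain, RoiChain] | None = None,
    reference: Line | None = None,
) -> np.ndarray:
    """Render detection output on top of a frame (RGB uint8)."""
    img = np.asarray(img)
    canvas = (
        np.repeat(img[..., None], 3, axis=2).astype(np.uint8)
        if img.ndim == 2
        else img.astype(np.uint8).copy()
    )
    if chains is not None:
        for chain in chains:
            for box, status in chain.rois:
                r0, r1, c0, c1 = box.clipped(canvas.shape[:2])
                _draw_box(canvas, r0, r1, c0, c1, _STATUS_COLORS[status])
    if result is not None:
        _draw_infinite_line(canvas, result.left, (255, 255, 255))
        _draw_infinite_line(canvas, result.right, (255, 255, 255))
        _draw_infinite_line(canvas, result.navigation, (255, 105, 180))
        for pts in result.points.values():
            for p in pts:
                r, c = int(round(p.y)), int(round(p.x))
                if 0 <= r < canvas.shape[0] and 0 <= c < canvas.shape[1]:
                    canvas[r, c] = (0, 120, 255)
    if reference is not None:
        _draw_infinite_line(canvas, reference, (0, 0, 255))
    return canvas


def write_records(records: list[dict], path: str | Path) -> None:
    """Append-free JSON-lines dump of per-frame records."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, default=float) + "\n")
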