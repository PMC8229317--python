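"""Edge extraction: from a trunk mask to the pixel span N.

The device measures along a single transverse mark line (one image row,
the operator's breast-height line).  Among the maximal runs of
trunk-labelled pixels on that row the run containing the image's centre
column is selected — the operator centres the target trunk — falling
back to the run nearest the centre (wider run wins a distance tie, then
leftmost).  The span convention is inclusive: ``N = right - left + 1``,
counting the trunk pixels themselves; the synthetic scene generator uses
the identical convention so the geometry inverse closes.

``refine_edges`` mirrors the device's manual "Refine" mode, replacing
one or both detected edges with operator-supplied columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Literal, Optional, Tuple

import numpy as np

from .mask import SegmentationMask

__all__ = [
    "EdgePair",
    "NoTrunkDetectedError",
    "extract_edges",
    "refine_edges",
    "trunk_fraction",
    "annotate_scene",
]


class NoTrunkDetectedError(ValueError):
    """No trunk pixel on the measurement row — nothing to measure."""


@dataclass(frozen=True)
class EdgePair:
    """Left/right trunk edge columns on a measurement row (inclusive)."""

    row: int
    left: int
    right: int
    image_width: int
    source: Literal["auto", "refined"] = "auto"

    def __post_init__(self) -> None:
        if not (0 <= self.left <= self.right < self.image_width):
            raise ValueError(
                f"require 0 <= left <= right < width, got "
                f"left={self.left}, right={self.right}, width={self.image_width}"
            )

    @property
    def pixel_span(self) -> int:
        return self.right - self.left + 1


def _runs(row_labels: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of 1s as inclusive (start, stop) column pairs."""
    padded = np.concatenate([[0], row_labels.astype(np.int8), [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def extract_edges(mask: SegmentationMask, row: Optional[int] = None) -> EdgePair:
    """Detect the trunk edges on one row of a segmentation mask.

    ``row`` defaults to the vertical centre (the transverse mark line).
    """
    h, w = mask.shape
    if row is None:
        row = h // 2
    if not (0 <= row < h):
        raise ValueError(f"row {row} outside image of height {h}")
    runs = _runs(mask.labels[row])
    if not runs:
        raise NoTrunkDetectedError(f"no trunk pixel on row {row}")
    centre = w // 2
    containing = [r for r in runs if r[0] <= centre <= r[1]]
    if containing:
        left, right = containing[0]
    else:
        def distance(run: Tuple[int, int]) -> int:
            lo, hi = run
            return min(abs(lo - centre), abs(hi - centre))

        # nearest endpoint to centre; ties -> wider run; then leftmost
        best = min(runs, key=lambda r: (distance(r), -(r[1] - r[0]), r[0]))
        left, right = best
    return EdgePair(row=row, left=left, right=right, image_width=w, source="auto")


def refine_edges(
    pair: EdgePair,
    new_left: Optional[int] = None,
    new_right: Optional[int] = None,
) -> EdgePair:
    """Apply manual edge overrides (the GUI's refine lines).

    Returns a pair with ``source='refined'``; if the overrides cross
    (left > right) they are swapped with a warning.
    """
    left = pair.left if new_left is None else new_left
    right = pair.right if new_right is None else new_right
    for name, col in (("new_left", left), ("new_right", right)):
        if not (0 <= col < pair.image_width):
            raise ValueError(
                f"{name}={col} outside image of width {pair.image_width}"
            )
    if left > right:
        warnings.warn(
            f"refined edges cross (left={left} > right={right}); swapping",
            stacklevel=2,
        )
        left, right = right, left
    return replace(pair, left=left, right=right, source="refined")


def trunk_fraction(pair: EdgePair, image_width: Optional[int] = None) -> float:
    """Percentage of the image width occupied by the trunk span."""
    w = pair.image_width if image_width is None else image_width
    if w < 1:
        raise ValueError("image width must be >= 1")
    return 100.0 * pair.pixel_span / w


def annotate_scene(
    image: np.ndarray,
    pair: EdgePair,
    path,
    refine_columns: Optional[Tuple[int, int]] = None,
) -> None:
    """Write a debug PNG: red edge points on the measurement row, the
    transverse and central vertical mark lines in white, and optional
    blue refine lines."""
    from PIL import Image

    img = (np.clip(np.asarray(image, dtype=np.float64), 0, 1) * 255).astype(np.uint8)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=2)
    h, w, _ = img.shape
    img[pair.row, :, :] = np.maximum(img[pair.row, :, :], 160)
    img[:, w // 2, :] = np.maximum(img[:, w // 2, :], 160)
    if refine_columns is not None:
        for col in refine_columns:
            img[:, col] = (40, 40, 255)
    r0, r1 = max(pair.row - 2, 0), min(pair.row + 3, h)
    for col in (pair.left, pair.right):
        c0, c1 = max(col - 2, 0), min(col + 3, w)
        img[r0:r1, c0:c1] = (255, 0, 0)
    Image.fromarray(img).save(path)
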