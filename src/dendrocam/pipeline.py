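"""End-to-end measurement: image + range -> segmentation -> edges -> DBH."""

from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .edges import EdgePair, extract_edges, refine_edges, trunk_fraction
from .geometry import CameraIntrinsics, TrunkObservation, diameter_from_span
from .mask import SegmentationMask
from .nn.network import TrunkSegmenter
from .records import MeasurementRecord

__all__ = ["measure", "load_image", "measure_scene_with_oracle_mask"]

log = logging.getLogger("dendrocam")


def load_image(path: Union[str, Path]) -> np.ndarray:
    """Read a JPEG/PNG into float RGB in [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    return arr


def measure(
    image: Union[str, Path, np.ndarray],
    distance_mm: float,
    intrinsics: CameraIntrinsics,
    model: Optional[TrunkSegmenter] = None,
    mask: Optional[SegmentationMask] = None,
    row: Optional[int] = None,
    refine: Optional[Tuple[Optional[int], Optional[int]]] = None,
    timestamp: Optional[datetime] = None,
    longitude: Optional[float] = None,
    latitude: Optional[float] = None,
) -> Tuple[MeasurementRecord, EdgePair]:
    """Run the full measurement pipeline on one shot.

    Either a trained ``model`` or a precomputed ``mask`` (the oracle-mask
    bypass used for testing the geometric stages in isolation) must be
    supplied.  ``refine`` optionally overrides the detected (left, right)
    edge columns, mirroring the device's manual refine mode.
    """
    image_ref: Optional[str] = None
    if isinstance(image, (str, Path)):
        image_ref = str(image)
        image_arr = load_image(image)
    else:
        image_arr = np.asarray(image, dtype=np.float32)

    if mask is None:
        if model is None:
            raise ValueError("either a trained model or a mask must be provided")
        mask = model.predict_mask(image_arr)
    if mask.shape != image_arr.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image_arr.shape[:2]}"
        )

    pair = extract_edges(mask, row=row)
    if refine is not None and (refine[0] is not None or refine[1] is not None):
        pair = refine_edges(pair, new_left=refine[0], new_right=refine[1])

    obs = TrunkObservation(
        distance_mm=distance_mm, pixel_span=pair.pixel_span, image_path=image_ref
    )
    est = diameter_from_span(obs, intrinsics)
    log.info(
        "span N=%d px (row %d, %s), trunk fraction %.1f%%, D=%.0f mm, "
        "f_x=%.2f px -> DBH=%.2f mm",
        pair.pixel_span,
        pair.row,
        pair.source,
        trunk_fraction(pair),
        distance_mm,
        intrinsics.fx,
        est.diameter_mm,
    )
    rec = MeasurementRecord(
        timestamp=timestamp or datetime.now().replace(microsecond=0),
        dbh_mm=est.diameter_mm,
        distance_mm=distance_mm,
        longitude=longitude,
        latitude=latitude,
        image_ref=image_ref,
    )
    return rec, pair


def measure_scene_with_oracle_mask(scene, row: Optional[int] = None) -> float:
    """Measured diameter (mm) of a synthetic scene using its ground-truth
    mask — isolates edge-extraction + geometry from segmentation."""
    pair = extract_edges(scene.mask, row=row)
    obs = TrunkObservation(
        distance_mm=scene.spec.distance_mm, pixel_span=pair.pixel_span
    )
    return diameter_from_span(obs, scene.spec.intrinsics).diameter_mm
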