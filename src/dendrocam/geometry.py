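"""Pinhole-optics model linking trunk diameter, range and pixel span.

A camera at horizontal distance ``D`` (mm, measured to the *front surface*
of the trunk at the ranging point) images a trunk of semidiameter ``R``
(mm).  The trunk's half-width projects onto the sensor as

    L / f = R / (R + D)                       (thin-lens similar triangles)

where ``f`` is the focal length.  With pixel size ``mu`` the projection
covers ``N = 2 L / mu`` pixels, and introducing the normalized focal
length ``f_x = f / mu`` (focal length in pixel units) the semidiameter is
recovered from an observed span as

    R = D * N / (2 * f_x - N).

All lengths are carried in millimetres internally; pixel size is accepted
in micrometres and converted at the boundary.  The pixel span ``N`` is
real-valued here — quantization to whole pixels happens only in edge
extraction — which keeps the forward and inverse maps exactly mutually
inverse and testable to floating-point precision.

The rangefinder origin and the camera optical centre are assumed
co-located: ``D`` is the surface range, so ``R + D`` is the distance to
the trunk axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "TrunkObservation",
    "DiameterEstimate",
    "GeometryError",
    "DegenerateGeometryError",
    "normalized_focal_length",
    "diameter_from_span",
    "span_from_diameter",
    "project_halfwidth",
    "load_intrinsics",
]

#: µm per mm
_UM_PER_MM = 1000.0

#: relative tolerance for cross-checking redundant intrinsics
_CONSISTENCY_RTOL = 1e-6


class GeometryError(ValueError):
    """Invalid parameter for the imaging model."""


class DegenerateGeometryError(GeometryError):
    """The observed span is geometrically impossible (trunk fills or
    overfills the field of view, ``N >= 2 f_x``)."""


def normalized_focal_length(focal_length_mm: float, pixel_size_um: float) -> float:
    """Focal length expressed in pixel units, ``f_x = f / mu``.

    Parameters
    ----------
    focal_length_mm
        Lens focal length in millimetres.
    pixel_size_um
        Sensor pixel pitch in micrometres.

    Returns
    -------
    float
        Dimensionless pixel count ``f_x``.

    Examples
    --------
    >>> round(normalized_focal_length(16.0, 3.7), 4)
    4324.3243
    """
    if not (focal_length_mm > 0 and pixel_size_um > 0):
        raise GeometryError(
            f"focal length and pixel size must be positive, got "
            f"{focal_length_mm} mm, {pixel_size_um} um"
        )
    return focal_length_mm * _UM_PER_MM / pixel_size_um


@dataclass(frozen=True)
class CameraIntrinsics:
    """Calibrated scale of the imaging model.

    Any two of (focal length, pixel size, normalized focal length) define
    the third; when all three are supplied they must agree to a relative
    tolerance of 1e-6.
    """

    focal_length_mm: Optional[float] = None
    pixel_size_um: Optional[float] = None
    fx: Optional[float] = None

    def __post_init__(self) -> None:
        f, mu, fx = self.focal_length_mm, self.pixel_size_um, self.fx
        given = [v is not None for v in (f, mu, fx)]
        for name, v in (("focal_length_mm", f), ("pixel_size_um", mu), ("fx", fx)):
            if v is not None and not v > 0:
                raise GeometryError(f"{name} must be strictly positive, got {v}")
        if sum(given) < 2:
            raise GeometryError(
                "need at least two of focal_length_mm, pixel_size_um, fx"
            )
        if f is not None and mu is not None:
            derived = normalized_focal_length(f, mu)
            if fx is None:
                object.__setattr__(self, "fx", derived)
            elif abs(fx - derived) > _CONSISTENCY_RTOL * derived:
                raise GeometryError(
                    f"inconsistent intrinsics: fx={fx} but f/mu={derived}"
                )
        elif fx is not None and mu is not None:
            object.__setattr__(self, "focal_length_mm", fx * mu / _UM_PER_MM)
        elif fx is not None and f is not None:
            object.__setattr__(self, "pixel_size_um", f * _UM_PER_MM / fx)

    def scaled(self, factor: float) -> "CameraIntrinsics":
        """Intrinsics of the same optics binned/downscaled by ``factor``
        (e.g. ``factor=8`` models 8x pixel binning: f_x drops 8-fold)."""
        if not factor > 0:
            raise GeometryError(f"scale factor must be positive, got {factor}")
        return CameraIntrinsics(
            focal_length_mm=self.focal_length_mm,
            pixel_size_um=self.pixel_size_um * factor,
        )


#: The reference camera used throughout the examples and benchmarks:
#: a 16 mm lens over a 3.7 um-pitch sensor, f_x = 4324.3243 px.
REFERENCE_CAMERA = CameraIntrinsics(focal_length_mm=16.0, pixel_size_um=3.7)


@dataclass(frozen=True)
class TrunkObservation:
    """One shot: surface range ``D`` (mm) and pixel span ``N``."""

    distance_mm: float
    pixel_span: float
    image_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.distance_mm > 0:
            raise GeometryError(f"distance must be positive, got {self.distance_mm}")
        if not self.pixel_span > 0:
            raise GeometryError(f"pixel span must be positive, got {self.pixel_span}")


@dataclass(frozen=True)
class DiameterEstimate:
    """Recovered semidiameter R and diameter DBH = 2R, in mm."""

    semidiameter_mm: float

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.semidiameter_mm


def diameter_from_span(
    obs: TrunkObservation, cam: CameraIntrinsics
) -> DiameterEstimate:
    """Invert the projection: ``R = D N / (2 f_x - N)``.

    Raises
    ------
    DegenerateGeometryError
        If ``N >= 2 f_x`` (the trunk would fill or overfill the field).
    """
    fx = cam.fx
    denom = 2.0 * fx - obs.pixel_span
    if denom <= 0:
        raise DegenerateGeometryError(
            f"pixel span N={obs.pixel_span} >= 2 f_x = {2 * fx}: "
            "trunk fills or overfills the field of view"
        )
    r = obs.distance_mm * obs.pixel_span / denom
    return DiameterEstimate(semidiameter_mm=r)


def span_from_diameter(
    semidiameter_mm: float, distance_mm: float, cam: CameraIntrinsics
) -> float:
    """Forward projection: real-valued span ``N = 2 f_x R / (R + D)``.

    Exact inverse of :func:`diameter_from_span`; no rounding is applied.
    """
    if not semidiameter_mm > 0:
        raise GeometryError(f"semidiameter must be positive, got {semidiameter_mm}")
    if not distance_mm > 0:
        raise GeometryError(f"distance must be positive, got {distance_mm}")
    return 2.0 * cam.fx * semidiameter_mm / (semidiameter_mm + distance_mm)


def project_halfwidth(
    semidiameter_mm: float, distance_mm: float, cam: CameraIntrinsics
) -> float:
    """Half-width of the trunk's image on the sensor, ``L = f R / (R + D)``,
    in micrometres.  Satisfies ``2 L / mu == span_from_diameter``."""
    if not semidiameter_mm > 0:
        raise GeometryError(f"semidiameter must be positive, got {semidiameter_mm}")
    if not distance_mm > 0:
        raise GeometryError(f"distance must be positive, got {distance_mm}")
    l_mm = cam.focal_length_mm * semidiameter_mm / (semidiameter_mm + distance_mm)
    return l_mm * _UM_PER_MM


def load_intrinsics(path: Union[str, Path]) -> CameraIntrinsics:
    """Load an intrinsics config block from YAML or JSON.

    Recognised keys: ``focal_length_mm``, ``pixel_size_um``, optional ``fx``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise GeometryError(f"intrinsics config {path} is not a mapping")
    unknown = set(data) - {"focal_length_mm", "pixel_size_um", "fx"}
    if unknown:
        raise GeometryError(f"unknown intrinsics keys in {path}: {sorted(unknown)}")
    return CameraIntrinsics(**data)
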