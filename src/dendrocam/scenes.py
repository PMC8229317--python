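"""Synthetic single-trunk forest scenes with exact ground truth.

Real training photographs for the trunk segmenter are not redistributable,
so this module renders procedurally textured stand-ins whose geometry is
*exact* by construction: the trunk is a vertical band centred on the
image's centre column whose real-valued width comes from the pinhole
forward projection ``span_from_diameter``; the rasterised mask width is
``round(true_span)`` in the default hard-edge mode, so running edge
extraction on the ground-truth mask and inverting the geometry recovers
the true diameter up to integer pixel quantization and nothing else.

Variability emulates the failure modes of field imagery: four bark styles
(uniform, striped, mottled, shaggy), background clutter (plain /
out-of-focus background trunks / foliage), optional sun spots straddling
a trunk edge, and a global illumination gain.

Three canned suites are provided:

* :func:`generate_dataset` — a randomized training/test pool with trunks
  occupying 10-90 % of the frame width;
* :func:`cylinder_benchmark` — six reference cylinders of 50-300 mm
  diameter imaged ten times each at 2, 2.5 and 3 m (180 scenes), the
  desk-scale analogue of a machined-cylinder accuracy experiment;
* :func:`viewing_frame_sweep` — scenes at prescribed trunk/frame
  fractions, for analysing measurement error versus framing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union
import warnings

import numpy as np
import pandas as pd

from .geometry import (
    CameraIntrinsics,
    GeometryError,
    REFERENCE_CAMERA,
    TrunkObservation,
    diameter_from_span,
    span_from_diameter,
)
from .mask import SegmentationMask

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "SceneInfeasibleError",
    "generate_scene",
    "generate_dataset",
    "cylinder_benchmark",
    "viewing_frame_sweep",
    "write_scene",
    "CYLINDER_DIAMETERS_MM",
    "CYLINDER_DISTANCES_MM",
    "CYLINDER_REPLICATES",
]

#: Reference cylinder diameters (mm) and ranges (mm) of the benchmark design.
CYLINDER_DIAMETERS_MM = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
CYLINDER_DISTANCES_MM = (2000.0, 2500.0, 3000.0)
CYLINDER_REPLICATES = 10

BARK_STYLES = ("uniform", "striped", "mottled", "shaggy")
BACKGROUND_STYLES = ("plain", "cluttered-trunks", "foliage")


class SceneInfeasibleError(ValueError):
    """The requested geometry does not fit in the image frame."""


@dataclass(frozen=True)
class SceneSpec:
    """Full recipe for one rendered scene (deterministic given ``seed``)."""

    true_diameter_mm: float
    distance_mm: float
    intrinsics: CameraIntrinsics = REFERENCE_CAMERA
    image_size: Tuple[int, int] = (128, 128)
    bark_style: str = "mottled"
    background_style: str = "plain"
    sun_spots: bool = False
    illumination: float = 1.0
    seed: int = 0
    hard_edges: bool = True

    def __post_init__(self) -> None:
        if self.bark_style not in BARK_STYLES:
            raise ValueError(f"bark_style must be one of {BARK_STYLES}")
        if self.background_style not in BACKGROUND_STYLES:
            raise ValueError(f"background_style must be one of {BACKGROUND_STYLES}")
        if not self.true_diameter_mm > 0 or not self.distance_mm > 0:
            raise ValueError("diameter and distance must be positive")
        if self.illumination <= 0:
            raise ValueError("illumination gain must be positive")

    @property
    def true_span(self) -> float:
        """Real-valued forward-projected pixel span."""
        return span_from_diameter(
            self.true_diameter_mm / 2.0, self.distance_mm, self.intrinsics
        )


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene plus its exact ground truth."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    mask: SegmentationMask
    true_span: float
    true_diameter_mm: float
    spec: SceneSpec


# --------------------------------------------------------------- texture kit


def _value_noise(
    rng: np.random.Generator, shape: Tuple[int, int], cell: int
) -> np.ndarray:
    """Smooth value noise in [0, 1]: coarse random grid, bilinear upsample."""
    h, w = shape
    gh, gw = max(h // cell, 1) + 2, max(w // cell, 1) + 2
    grid = rng.random((gh, gw))
    ys = np.linspace(0, gh - 1.001, h)
    xs = np.linspace(0, gw - 1.001, w)
    y0 = ys.astype(int)
    x0 = xs.astype(int)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    a = grid[y0][:, x0]
    b = grid[y0][:, x0 + 1]
    c = grid[y0 + 1][:, x0]
    d = grid[y0 + 1][:, x0 + 1]
    return a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx + c * fy * (1 - fx) + d * fy * fx


def _bark_texture(
    rng: np.random.Generator, shape: Tuple[int, int], style: str
) -> np.ndarray:
    """Greyscale bark modulation in [0, 1] (mean ~0.5)."""
    h, w = shape
    if style == "uniform":
        tex = 0.5 + 0.03 * (rng.random((h, w)) - 0.5)
    elif style == "striped":
        cols = np.arange(w)
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.25, 0.8)
        stripes = 0.5 + 0.25 * np.sin(freq * cols + phase)
        tex = stripes[None, :] + 0.15 * (_value_noise(rng, shape, 6) - 0.5)
    elif style == "mottled":
        tex = _value_noise(rng, shape, 8)
        tex = 0.5 + 0.35 * (tex - 0.5) + 0.05 * (rng.random((h, w)) - 0.5)
    elif style == "shaggy":
        streaks = _value_noise(rng, (h, max(w // 3, 4)), 3)
        idx = np.minimum(
            (np.arange(w) / 3).astype(int), streaks.shape[1] - 1
        )
        tex = streaks[:, idx]
        tex = 0.5 + 0.4 * (tex - 0.5) + 0.08 * (rng.random((h, w)) - 0.5)
    else:  # pragma: no cover - guarded by SceneSpec
        raise ValueError(style)
    return np.clip(tex, 0.0, 1.0)


def _background(
    rng: np.random.Generator, shape: Tuple[int, int], style: str
) -> np.ndarray:
    """RGB background in [0, 1]; bright relative to bark."""
    h, w = shape
    if style == "plain":
        base = rng.uniform(0.65, 0.9)
        tint = rng.uniform(-0.05, 0.05, size=3)
        img = np.clip(base + tint, 0, 1) * np.ones((h, w, 3))
        img += 0.04 * (_value_noise(rng, shape, 16) - 0.5)[:, :, None]
    elif style == "cluttered-trunks":
        img = _background(rng, shape, "plain")
        # hazy distant trunks: lighter, washed-out vertical bands
        for _ in range(rng.integers(2, 5)):
            width = int(rng.uniform(0.03, 0.12) * w)
            left = int(rng.uniform(0, w - width))
            shade = rng.uniform(0.45, 0.62)
            band = shade + 0.06 * (
                _value_noise(rng, (h, width), 6) - 0.5
            )
            img[:, left : left + width, :] = band[:, :, None] * np.array(
                [1.0, 0.95, 0.9]
            )
    elif style == "foliage":
        img = np.empty((h, w, 3))
        noise = _value_noise(rng, shape, 5)
        img[:, :, 0] = 0.35 + 0.25 * noise
        img[:, :, 1] = 0.55 + 0.3 * _value_noise(rng, shape, 5)
        img[:, :, 2] = 0.3 + 0.2 * noise
    else:  # pragma: no cover
        raise ValueError(style)
    return np.clip(img, 0.0, 1.0)


# ------------------------------------------------------------------- renderer


def _band_columns(width: int, span_px: int) -> Tuple[int, int]:
    """Inclusive (left, right) of a span_px-wide band containing the
    centre column ``width // 2``."""
    centre = width // 2
    left = centre - span_px // 2
    return left, left + span_px - 1


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene from its spec (deterministic given ``spec.seed``)."""
    h, w = spec.image_size
    true_span = spec.true_span
    if true_span >= w:
        raise SceneInfeasibleError(
            f"forward span {true_span:.1f} px does not fit image width {w}"
        )
    rng = np.random.default_rng(spec.seed)

    img = _background(rng, (h, w), spec.background_style)

    # bark colour: dark brown/grey, clearly below background luminance
    base = rng.uniform(0.12, 0.38)
    bark_rgb = np.clip(
        np.array([base * 1.15, base, base * 0.8]) + rng.uniform(-0.03, 0.03, 3),
        0.02,
        0.55,
    )
    tex = _bark_texture(rng, (h, w), spec.bark_style)

    span_px = int(round(true_span))
    if span_px < 1:
        raise SceneInfeasibleError(f"span {true_span:.3f} px rounds below 1 pixel")
    left, right = _band_columns(w, span_px)
    if left < 0 or right >= w:
        raise SceneInfeasibleError("trunk band exceeds the image frame")

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[:, left : right + 1] = 1

    if spec.hard_edges:
        trunk_rgb = bark_rgb[None, None, :] * (0.6 + 0.8 * tex[:, :, None])
        img = np.where(mask[:, :, None] == 1, trunk_rgb, img)
    else:
        # anti-aliased: fractional coverage at the two edge columns
        cov = np.zeros(w)
        lo = w // 2 - true_span / 2.0
        hi = lo + true_span
        for col in range(max(int(np.floor(lo)), 0), min(int(np.ceil(hi)), w)):
            cov[col] = max(0.0, min(col + 1.0, hi) - max(float(col), lo))
        trunk_rgb = bark_rgb[None, None, :] * (0.6 + 0.8 * tex[:, :, None])
        img = cov[None, :, None] * trunk_rgb + (1 - cov[None, :, None]) * img
        mask = (cov >= 0.5).astype(np.uint8)[None, :].repeat(h, axis=0)

    # mild edge shading so the trunk reads as a cylinder
    cols = np.arange(w)
    inside = (cols >= left) & (cols <= right)
    if span_px >= 3:
        rel = np.zeros(w)
        rel[inside] = (cols[inside] - (left + right) / 2.0) / max(span_px / 2.0, 1)
        shade = 1.0 - 0.25 * rel**2
        img[:, inside, :] *= shade[inside][None, :, None]

    if spec.sun_spots:
        # bright blotches straddling a trunk edge — the classic failure mode
        for edge_col in rng.permutation([left, right])[: rng.integers(1, 3)]:
            cy = rng.uniform(0.2, 0.8) * h
            ry = rng.uniform(0.05, 0.18) * h
            rx = rng.uniform(0.02, 0.08) * w
            yy, xx = np.mgrid[0:h, 0:w]
            blob = ((yy - cy) / ry) ** 2 + ((xx - edge_col) / rx) ** 2 <= 1.0
            img[blob] = np.clip(img[blob] + rng.uniform(0.45, 0.7), 0, 1)

    img = np.clip(img * spec.illumination, 0.0, 1.0).astype(np.float32)

    # geometry self-check: inverse of the forward model recovers the truth
    est = diameter_from_span(
        TrunkObservation(distance_mm=spec.distance_mm, pixel_span=true_span),
        spec.intrinsics,
    )
    if abs(est.diameter_mm - spec.true_diameter_mm) > 1e-9 * spec.true_diameter_mm:
        raise AssertionError("forward/inverse geometry inconsistency")

    return SyntheticScene(
        image=img,
        mask=SegmentationMask(labels=mask),
        true_span=true_span,
        true_diameter_mm=spec.true_diameter_mm,
        spec=spec,
    )


# --------------------------------------------------------------------- suites


def _derive_seed(base: int, index: int) -> int:
    return int((base * 100003 + 7919 * index + 1) % (2**31 - 1))


def generate_dataset(
    n: int,
    seed: int = 0,
    intrinsics: Optional[CameraIntrinsics] = None,
    image_size: Tuple[int, int] = (128, 128),
    diameter_range_mm: Tuple[float, float] = (60.0, 400.0),
    fraction_range: Tuple[float, float] = (0.10, 0.90),
    sun_spot_probability: float = 0.3,
    manifest_csv: Optional[Union[str, Path]] = None,
) -> List[SyntheticScene]:
    """A randomized pool of ground-truthed scenes.

    Trunk diameters are drawn uniformly and the camera range is solved so
    the trunk occupies a uniformly drawn fraction of the frame width
    (10-90 % by default).  Bark style, background, sun spots and
    illumination are randomized per scene.  Optionally writes a manifest
    CSV of every scene's ground truth.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        warnings.warn("generate_dataset called with n=0: empty dataset")
        return []
    if intrinsics is None:
        # reference optics binned so trunks at field ranges fit the frame
        intrinsics = REFERENCE_CAMERA.scaled(8)
    rng = np.random.default_rng(seed)
    h, w = image_size
    scenes: List[SyntheticScene] = []
    rows = []
    for i in range(n):
        diameter = rng.uniform(*diameter_range_mm)
        frac = rng.uniform(*fraction_range)
        span = frac * w
        distance = _distance_for_span(diameter / 2.0, span, intrinsics)
        spec = SceneSpec(
            true_diameter_mm=diameter,
            distance_mm=distance,
            intrinsics=intrinsics,
            image_size=image_size,
            bark_style=BARK_STYLES[rng.integers(len(BARK_STYLES))],
            background_style=BACKGROUND_STYLES[rng.integers(len(BACKGROUND_STYLES))],
            sun_spots=bool(rng.random() < sun_spot_probability),
            illumination=float(rng.uniform(0.7, 1.2)),
            seed=_derive_seed(seed, i),
        )
        scene = generate_scene(spec)
        scenes.append(scene)
        rows.append(_manifest_row(i, scene))
    if manifest_csv is not None:
        pd.DataFrame(rows).to_csv(manifest_csv, index=False)
    return scenes


def _manifest_row(index: int, scene: SyntheticScene) -> dict:
    s = scene.spec
    return {
        "index": index,
        "true_diameter_mm": s.true_diameter_mm,
        "distance_mm": s.distance_mm,
        "true_span_px": scene.true_span,
        "bark_style": s.bark_style,
        "background_style": s.background_style,
        "sun_spots": s.sun_spots,
        "illumination": s.illumination,
        "seed": s.seed,
        "height": s.image_size[0],
        "width": s.image_size[1],
    }


def cylinder_benchmark(
    intrinsics: CameraIntrinsics = REFERENCE_CAMERA,
    image_size: Tuple[int, int] = (128, 1024),
    replicates: int = CYLINDER_REPLICATES,
    seed: int = 0,
    range_noise_cv: float = 0.0,
) -> List[SyntheticScene]:
    """The standard-cylinder accuracy suite: six known diameters
    (50-300 mm), each imaged ``replicates`` times at 2, 2.5 and 3 m.

    Replicates share identical geometry and differ in texture and
    illumination jitter (machined cylinders: plain background, no sun
    spots).  Scenes are rendered at the full sensor pixel pitch as a
    wide strip around the measurement line, so the thinnest cylinder at
    the longest range still spans ~71 px and quantization stays well
    below 1 %.  ``range_noise_cv`` > 0 optionally perturbs the *recorded*
    range with multiplicative Gaussian noise of that coefficient of
    variation, emulating rangefinder error; default is noise-free.
    """
    scenes: List[SyntheticScene] = []
    rng = np.random.default_rng(seed)
    i = 0
    for diameter in CYLINDER_DIAMETERS_MM:
        for distance in CYLINDER_DISTANCES_MM:
            for _rep in range(replicates):
                actual_distance = distance
                if range_noise_cv > 0:
                    actual_distance = distance * float(
                        1.0 + range_noise_cv * rng.standard_normal()
                    )
                spec = SceneSpec(
                    true_diameter_mm=diameter,
                    distance_mm=actual_distance,
                    intrinsics=intrinsics,
                    image_size=image_size,
                    bark_style="uniform" if i % 2 == 0 else "mottled",
                    background_style="plain",
                    sun_spots=False,
                    illumination=float(rng.uniform(0.8, 1.15)),
                    seed=_derive_seed(seed, i),
                )
                scenes.append(generate_scene(spec))
                i += 1
    return scenes


def _distance_for_span(
    semidiameter_mm: float, span_px: float, intrinsics: CameraIntrinsics
) -> float:
    """Solve N = 2 f_x R / (R + D) for D."""
    fx = intrinsics.fx
    if span_px <= 0 or span_px >= 2 * fx:
        raise SceneInfeasibleError(
            f"span {span_px} px unreachable with f_x = {fx}"
        )
    return semidiameter_mm * (2.0 * fx - span_px) / span_px


def viewing_frame_sweep(
    intrinsics: CameraIntrinsics,
    fractions: Sequence[float],
    diameter_mm: float = 200.0,
    image_size: Tuple[int, int] = (128, 128),
    seed: int = 0,
    **scene_kwargs,
) -> List[SyntheticScene]:
    """Scenes whose trunk occupies prescribed percentages of the frame
    width, obtained by solving the range for each requested fraction.
    Larger fractions come from shorter ranges (fixed diameter)."""
    h, w = image_size
    scenes = []
    for i, frac in enumerate(fractions):
        if not (0 < frac < 100):
            raise SceneInfeasibleError(
                f"trunk fraction must be in (0, 100) %, got {frac}"
            )
        span = frac / 100.0 * w
        distance = _distance_for_span(diameter_mm / 2.0, span, intrinsics)
        spec = SceneSpec(
            true_diameter_mm=diameter_mm,
            distance_mm=distance,
            intrinsics=intrinsics,
            image_size=image_size,
            seed=_derive_seed(seed, i),
            **scene_kwargs,
        )
        scenes.append(generate_scene(spec))
    return scenes


# --------------------------------------------------------------------- output


def write_scene(scene: SyntheticScene, directory: Union[str, Path], stem: str) -> None:
    """Write image PNG + mask PNG + ground-truth JSON for one scene."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray((scene.image * 255).astype(np.uint8)).save(
        directory / f"{stem}.png"
    )
    Image.fromarray(scene.mask.labels * 255).save(directory / f"{stem}_mask.png")
    truth = _manifest_row(0, scene)
    truth.pop("index")
    (directory / f"{stem}.json").write_text(json.dumps(truth, indent=2))
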