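import numpy as np
import pytest

import dendrocam as dc


@pytest.fixture(scope="session")
def ref_cam():
    """The reference optics: 16 mm lens, 3.7 um pixels, f_x = 4324.3243."""
    return dc.REFERENCE_CAMERA


@pytest.fixture(scope="session")
def binned_cam():
    """Reference optics binned 8x so trunks fit small test frames."""
    return dc.REFERENCE_CAMERA.scaled(8)


@pytest.fixture(scope="session")
def simple_scene(binned_cam):
    """A trivially separable scene: uniform dark trunk on a plain bright
    background, 64x64."""
    return dc.generate_scene(
        dc.SceneSpec(
            true_diameter_mm=100.0,
            distance_mm=2000.0,
            intrinsics=binned_cam,
            image_size=(64, 64),
            bark_style="uniform",
            background_style="plain",
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def textured_scenes(binned_cam):
    """A handful of varied 64x64 scenes for oracle-mask pipeline tests."""
    rng = np.random.default_rng(7)
    scenes = []
    for i, (style, bg) in enumerate(
        [
            ("mottled", "plain"),
            ("striped", "cluttered-trunks"),
            ("shaggy", "foliage"),
            ("uniform", "plain"),
        ]
    ):
        scenes.append(
            dc.generate_scene(
                dc.SceneSpec(
                    true_diameter_mm=float(rng.uniform(60, 220)),
                    distance_mm=float(rng.uniform(2000, 3500)),
                    intrinsics=binned_cam,
                    image_size=(64, 64),
                    bark_style=style,
                    background_style=bg,
                    sun_spots=(i == 1),
                    seed=100 + i,
                )
            )
        )
    return scenes
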