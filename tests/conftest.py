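import numpy as np
import pytest

import sceneprompt as sp
from sceneprompt.synthetic_scene import OrganSpec, Period, SceneSchedule


@pytest.fixture(scope="session")
def cost_model():
    return dict(sp.DEFAULT_COST_MODEL)


@pytest.fixture(scope="session")
def surgery_dataset_100():
    """100-frame default surgical stress schedule at the full ToF grid."""
    schedule = sp.default_surgery_schedule(seed=3, n_frames=100)
    return sp.generate(schedule)


@pytest.fixture(scope="session")
def static_dataset_100():
    """100 static frames, zero boundary deformation: gt masks identical."""
    schedule = SceneSchedule(
        n_frames=100,
        periods=(Period(0, 100, ("static",)),),
        organ=OrganSpec(base_deform=0.0),
        seed=2,
    )
    return sp.generate(schedule)


def tiny_schedule(seed=0, n_frames=30, kinds=("static",), **organ_kw):
    """Small-raster schedule for cheap per-test generation."""
    organ_kw.setdefault("center", (40.0, 36.0))
    organ_kw.setdefault("radii", (24.0, 19.0))
    return SceneSchedule(
        n_frames=n_frames,
        periods=(Period(0, n_frames, kinds),),
        organ=OrganSpec(**organ_kw),
        resolution=(72, 80),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_static_dataset():
    return sp.generate(tiny_schedule(seed=1, n_frames=30, base_deform=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
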