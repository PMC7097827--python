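import numpy as np
import pytest

from cervia import synthetic
from cervia.registration import ClockSlice


@pytest.fixture(scope="session")
def demo_scene():
    """One seeded scene with a CIN2+ sector, a CIN1 sector, and an os tilt."""
    spec = synthetic.SceneSpec(
        abnormal_sectors=frozenset({3}),
        cin1_sectors=frozenset({7}),
        os_angle_deg=25.0,
        seed=5,
    )
    pre, post, fid, truth = synthetic.generate_scene(spec)
    return spec, pre, post, fid, truth


@pytest.fixture(scope="session")
def demo_record(demo_scene):
    spec, pre, post, fid, truth = demo_scene
    return synthetic.PatientRecord("P001", spec, pre, post, fid, truth)


@pytest.fixture(scope="session")
def demo_pair_slices(demo_record):
    from cervia.workbench import process_pair

    return process_pair(demo_record)


def make_slice(pre, post, mask, sector=1, label="UNKNOWN", patient_id="T"):
    """Build a ClockSlice directly from arrays (test helper)."""
    return ClockSlice(
        patient_id=patient_id,
        sector=sector,
        pre=np.asarray(pre),
        post=np.asarray(post),
        mask=np.asarray(mask, dtype=bool),
        label=label,
    )


def constant_image(shape, rgb):
    img = np.zeros((*shape, 3), dtype=np.uint8)
    img[:] = rgb
    return img
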