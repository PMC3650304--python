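import numpy as np
import pytest

from preycap import synthgen, vidproc


@pytest.fixture(scope="session")
def scene():
    return synthgen.SceneParams()


@pytest.fixture(scope="session")
def background(scene):
    return synthgen._background(scene).astype(np.uint8)


# head center at a half-integer pixel row (127.5 px): the rasterized body is
# then symmetric about its midline, which makes the straight-pose fixture
# free of chord-parity quantization
STRAIGHT_CENTER_MM = (4.2, 4.2075)


@pytest.fixture(scope="session")
def straight_truth():
    params = synthgen.GeneratorParams(delta_theta_true=0.0, osc_amp=0.0, seed=0)
    _, truth = synthgen.gen_bout_kinematics(params,
                                            head_center_mm=STRAIGHT_CENTER_MM)
    return truth


@pytest.fixture(scope="session")
def straight_binary(straight_truth, scene, background):
    stack = synthgen.render_frames(straight_truth, scene)
    binary, valid = vidproc.preprocess_free(stack[:1], background)
    assert valid[0]
    return binary[0]


@pytest.fixture(scope="session")
def bout30():
    """A rendered 30-degree turning bout with truth, binary stack and poses."""
    scene = synthgen.SceneParams()
    bg = synthgen._background(scene).astype(np.uint8)
    params = synthgen.GeneratorParams(delta_theta_true=30.0, seed=3)
    _, truth = synthgen.gen_bout_kinematics(params, head_center_mm=(4.2, 4.2))
    stack = synthgen.render_frames(truth, scene)
    binary, valid = vidproc.preprocess_free(stack, bg)
    poses = vidproc.track_stack(binary, valid)
    return truth, binary, poses
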