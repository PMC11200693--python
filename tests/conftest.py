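import numpy as np
import pytest

from skewgait.pose_io import N_JOINTS, PoseFrame, PoseSequence
from skewgait.synthetic_gait import WalkerParams, generate_walk


def make_frame(frame_index, fps, coords, confidence=0.9):
    """Build a PoseFrame from a list of (joint_id, x, y) triples.

    Unlisted joints get confidence 0.
    """
    kp = np.zeros((N_JOINTS, 3))
    for joint_id, x, y in coords:
        kp[joint_id] = (x, y, confidence)
    return PoseFrame(frame_index=frame_index, timestamp=frame_index / fps, keypoints=kp)


def make_sequence(frame_coords, fps=30.0, **kwargs):
    """Build a PoseSequence from per-frame lists of (joint_id, x, y) triples."""
    frames = [make_frame(i, fps, coords) for i, coords in enumerate(frame_coords)]
    return PoseSequence(frames=frames, fps=fps, **kwargs)


@pytest.fixture(scope="session")
def straight_walk():
    """Noise-free, dropout-free straight walk away from the camera."""
    params = WalkerParams(skew_deg=0.0, noise_sd_px=0.0, dropout_rate=0.0, seed=1)
    return generate_walk(params, "away", "straight")


@pytest.fixture(scope="session")
def toward_walk():
    params = WalkerParams(skew_deg=0.0, noise_sd_px=0.0, dropout_rate=0.0, seed=1)
    return generate_walk(params, "toward", "straight")


@pytest.fixture(scope="session")
def noisy_walk():
    params = WalkerParams(skew_deg=0.5, noise_sd_px=1.5, dropout_rate=0.05, seed=42)
    return generate_walk(params, "away", "skew_left")
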