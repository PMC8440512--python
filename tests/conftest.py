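import numpy as np
import pytest

from animakin import AnimationRecording, WordCategory


def make_recording(
    red_xy,
    blue_xy=None,
    red_rot=None,
    blue_rot=None,
    frame_rate_hz=133.0,
    canvas=(1920, 1080),
    word=WordCategory.FOLLOWING,
    animation_id="test",
    animator_id="tester",
):
    """Build a valid recording from raw position arrays."""
    red_xy = np.asarray(red_xy, dtype=float)
    n = len(red_xy)
    if blue_xy is None:
        blue_xy = red_xy + 5.0
    blue_xy = np.asarray(blue_xy, dtype=float)
    zeros = np.zeros(n)
    return AnimationRecording(
        animation_id=animation_id,
        animator_id=animator_id,
        word=word,
        frame_rate_hz=frame_rate_hz,
        canvas_px=canvas,
        t=np.arange(n) / frame_rate_hz,
        red_xy=red_xy,
        red_rot=zeros if red_rot is None else np.asarray(red_rot, dtype=float),
        blue_xy=blue_xy,
        blue_rot=zeros if blue_rot is None else np.asarray(blue_rot, dtype=float),
    )


def circle_xy(n, radius_px, center=(960.0, 540.0), cycles=2.0, phase=0.0):
    ang = phase + 2 * np.pi * cycles * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius_px * np.cos(ang), center[1] + radius_px * np.sin(ang)]
    )


@pytest.fixture
def circle_recording():
    return make_recording(circle_xy(2000, 300.0))
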