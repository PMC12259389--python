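import numpy as np
import pytest

from gibbonpam import (
    GRAY_PROFILE,
    AudioSegment,
    LabeledClip,
    RenderSpec,
    SoundscapeSpec,
    synth_call,
    synth_soundscape,
)

RATE = 16000


@pytest.fixture(scope="session")
def render():
    return RenderSpec()


@pytest.fixture(scope="session")
def soundscape60():
    """60-s pink-noise soundscape with three well-separated calls at 10 dB."""
    spec = SoundscapeSpec(
        duration_s=60.0,
        sample_rate_hz=RATE,
        call_placements=[(8.0, GRAY_PROFILE, 10.0), (25.0, GRAY_PROFILE, 10.0), (45.0, GRAY_PROFILE, 10.0)],
        seed=11,
    )
    return synth_soundscape(spec)


def make_separable_clips(n, rate=RATE, duration_s=12.0, seed0=0):
    """n clips alternating tonal gray-gibbon calls and digital silence."""
    clips = []
    for i in range(n):
        if i % 2 == 0:
            seg = synth_call(GRAY_PROFILE, duration_s, rate, seed=seed0 + i)
            label = "gibbon"
        else:
            seg = AudioSegment(np.zeros(int(duration_s * rate)), rate)
            label = "noise"
        clips.append(LabeledClip(seg, label, "window", f"site{i % 4}", 0.0))
    return clips


@pytest.fixture(scope="session")
def separable_clips():
    return make_separable_clips(60)
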