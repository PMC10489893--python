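import numpy as np
import pytest

from virtualgate import Frame, FrameStream


def rgb_frame(pixels, t=0, index=0):
    """Frame from a nested list / array of RGB triples."""
    return Frame(pixels=np.asarray(pixels, dtype=np.uint8), capture_time=t, index=index)


def uniform_frame(h, w, color, t=0, index=0):
    px = np.empty((h, w, 3), dtype=np.uint8)
    px[:] = color
    return Frame(pixels=px, capture_time=t, index=index)


def random_frame(rng, h, w, t=0, index=0, gray=False):
    shape = (h, w) if gray else (h, w, 3)
    return Frame(
        pixels=rng.integers(0, 256, size=shape, dtype=np.uint8),
        capture_time=t,
        index=index,
    )


def stream_from_frames(frames, fps=25.0):
    return FrameStream(frames=list(frames), nominal_fps=fps)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
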