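import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from redetect.slide_io import ChannelSpec, FrameGrid, SlideImage, tile_slide


def make_slide(pixels: np.ndarray, frame_width: int, frame_height: int,
               n_frames: int) -> SlideImage:
    """Wrap a (4, H, W) float array in a normalized SlideImage."""
    grid = FrameGrid(frame_width, frame_height, n_frames)
    return SlideImage(ChannelSpec(), grid, np.asarray(pixels, np.float32),
                      normalized=True)


def random_slide(rng: np.random.Generator, frame_width: int = 96,
                 frame_height: int = 64, n_frames: int = 2,
                 level: float = 0.1) -> SlideImage:
    grid = FrameGrid(frame_width, frame_height, n_frames)
    h, w = grid.mosaic_shape
    px = rng.uniform(0, level, size=(4, h, w)).astype(np.float32)
    return SlideImage(ChannelSpec(), grid, px, normalized=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_tiling(rng):
    """A 2-frame, 96x64 slide: 3x2 tiles per frame, 12 tiles total."""
    slide = random_slide(rng)
    return tile_slide(slide)
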