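import pytest

from ccmea.synthetic import FramePhantomSpec


@pytest.fixture(scope="session")
def small_spec() -> FramePhantomSpec:
    """64x64 phantom spec: enough resolution for every photometric rule,
    cheap enough to render hundreds of frames in a test run."""
    return FramePhantomSpec(image_height=64, image_width=64, seed=0)
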