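import numpy as np
import pytest

from standcount.segmentation import segment_image
from standcount.synthetic_field import FieldSpec, easy_spec, generate, stage_presets


@pytest.fixture(scope="session")
def stage2_plot():
    """Default stage-2 synthetic plot (~400 plants) with truth."""
    return generate(stage_presets(2), seed=7)


@pytest.fixture(scope="session")
def small_plot():
    """A reduced 4-row plot for fast pipeline tests."""
    spec = FieldSpec(plot_width_m=0.9, plot_height_m=1.0, n_rows=4)
    return generate(spec, seed=11)


@pytest.fixture(scope="session")
def small_segmented(small_plot):
    img, _ = small_plot
    return segment_image(img)


@pytest.fixture(scope="session")
def easy_plot():
    """Weed-free, well-separated plot of 50 single plants."""
    return generate(easy_spec(50), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
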