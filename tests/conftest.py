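import numpy as np
import pytest

from relcolors.synthetic import SyntheticSpec, generate_image

# vivid, well-separated mode colors that survive CIELAB relevance filtering
VIVID_PALETTE = np.array(
    [
        [200, 40, 40],
        [40, 170, 60],
        [50, 60, 200],
        [220, 200, 50],
        [150, 60, 170],
        [60, 190, 190],
    ]
)


@pytest.fixture
def four_mode_spec() -> SyntheticSpec:
    """Noise-free striped image with 4 modes at exactly representable weights."""
    return SyntheticSpec(
        n_true=4,
        palette_true=VIVID_PALETTE[:4],
        proportions=np.array([0.5, 0.25, 0.125, 0.125]),
        noise_sigma=0.0,
        layout="stripes",
        width=64,
        height=64,
        seed=11,
    )


@pytest.fixture
def four_mode_image(four_mode_spec):
    return generate_image(four_mode_spec)


@pytest.fixture
def noisy_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_true=5,
        palette_true=VIVID_PALETTE[:5],
        proportions=np.full(5, 0.2),
        noise_sigma=6.0,
        layout="voronoi",
        width=64,
        height=64,
        seed=7,
    )


@pytest.fixture
def noisy_image(noisy_spec):
    return generate_image(noisy_spec)
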