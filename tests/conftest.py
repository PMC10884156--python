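import numpy as np
import pytest

from lgequant import LabelMap, PhantomSpec, SliceStack, generate_phantom


@pytest.fixture(scope="session")
def default_subject():
    """One default phantom subject (scar-positive, noisy) shared read-only."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def noiseless_subject():
    """Noiseless scar-positive phantom for exact-value checks."""
    return generate_phantom(
        PhantomSpec(noise_sigma=0.0, intensity_scar=300.0, edge_softness_px=0.0, seed=0)
    )


@pytest.fixture
def small_stack():
    """Tiny deterministic stack + all-true mask for arithmetic checks."""
    rng = np.random.default_rng(7)
    data = rng.uniform(0, 100, size=(4, 16, 16))
    geom = dict(pixel_spacing_mm=1.5, slice_thickness_mm=8.0, slice_gap_mm=2.0)
    stack = SliceStack(data, **geom)
    mask = LabelMap(np.ones(data.shape, dtype=bool), **geom)
    return stack, mask
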