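import numpy as np
import pytest

from polarmap.mueller import MuellerImage
from polarmap.synthetic import canonical_mueller, generate_phantom, liver6_classes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_physical_mueller(rng, n=1, depol_max=0.95):
    """Random physical matrices: depolarizer . retarder . diattenuator.

    The depolarizer diagonal is sampled inside the Cloude-physical region
    (a >= b >= c >= a + b - 1), so every product is physically realizable.
    """
    a = rng.uniform(0.3, depol_max, n)
    b = rng.uniform(0.3, a)
    c = rng.uniform(np.maximum(0.05, a + b - 1.0), b)
    delta = rng.uniform(0, np.pi - 0.1, n)
    theta = rng.uniform(0, np.pi, n)
    d = rng.uniform(0, 0.6, n)
    M = (
        canonical_mueller("depolarizer", a=a, b=b, c=c)
        @ canonical_mueller("linear_retarder", delta=delta, theta=theta)
        @ canonical_mueller("diattenuator", d=d, theta=theta)
    )
    return M[0] if n == 1 else M


def image_from_stack(M, roi_id="test", **kwargs):
    """Wrap an (H, W, 4, 4) stack as a MuellerImage."""
    return MuellerImage(elements=M, roi_id=roi_id, **kwargs)


@pytest.fixture
def small_phantom():
    """48 x 48 default 6-class phantom with mild noise."""
    return generate_phantom(
        liver6_classes(), height=48, width=48, blob_scale_px=8,
        noise_sd=0.005, seed=7, roi_id="ph0", patient_id="pa", group="g",
    )


@pytest.fixture
def identity_image():
    el = np.tile(np.eye(4), (10, 12, 1, 1))
    return MuellerImage(elements=el, roi_id="ident")
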