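import numpy as np
import pytest

from maizegap.synthetic import FieldSpec, generate_field


@pytest.fixture(scope="session")
def clean_field():
    """A weed-free, noise-free 2x10 field with 3 interior dropouts."""
    spec = FieldSpec(n_rows=2, plants_per_row=10, missing_prob=0.2, seed=7)
    image, truth = generate_field(spec)
    assert truth.n_missing == 3  # fixture sanity
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
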