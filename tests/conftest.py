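import numpy as np
import pytest

from dataclasses import replace

from smallseg.phantom import (PhantomSpec, generate_phantom,
                              generate_toy_canonical, sample_lesion_spec)


@pytest.fixture(scope="session")
def small_tumor_case():
    """One clinical-style phantom with a single small lesion."""
    spec = PhantomSpec(in_plane_size=128, n_slices=48, seed=7)
    lesion = sample_lesion_spec(np.random.default_rng(7), "small", spec)
    return generate_phantom(replace(spec, lesions=[lesion]))


@pytest.fixture(scope="session")
def normal_case():
    return generate_phantom(PhantomSpec(in_plane_size=128, n_slices=47, seed=11))


@pytest.fixture(scope="session")
def toy_cases():
    """Six desk-scale canonical cases with small lesions (32^3)."""
    return [generate_toy_canonical((32, 32, 32), "small", seed=100 + i,
                                   source_id=f"s{i}") for i in range(6)]
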