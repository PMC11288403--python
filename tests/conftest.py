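import numpy as np
import pytest

import spottune3d as st
from spottune3d.backbones import build_agent, build_main_backbone
from spottune3d.sampling import Sample


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient nested-availability cohort of 24³ phantoms."""
    spec = st.CohortSpec.small(n_total=12, n_dti=10, n_dsc=8,
                               shape=(24, 24, 24), effect_size=0.5,
                               noise_sd=0.1, seed=7)
    return st.generate_cohort(spec)


@pytest.fixture()
def tiny_backbone():
    """Reduced 4-block basic backbone for desk-scale structural tests."""
    return build_main_backbone(1, (1, 1, 1, 1), "basic", base_width=4, seed=0)


@pytest.fixture()
def tiny_agent(tiny_backbone):
    return build_agent(1, tiny_backbone.block_count, base_width=2, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_samples(n_pos, n_neg, shape=(8, 8, 8), seed=0, augmented=False):
    """Random in-[0,1] training samples with the requested class counts."""
    r = np.random.default_rng(seed)
    out = []
    for i in range(n_pos + n_neg):
        out.append(Sample(volume=r.random(shape),
                          label=1 if i < n_pos else 0,
                          patient_id=f"P{i:03d}", augmented=augmented))
    return out
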