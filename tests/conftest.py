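import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from mammoseq import synthetic as syn


@pytest.fixture(scope="session")
def texture_roi():
    """One rendered 512x512 parenchyma-surrogate patch."""
    return syn.render_texture(syn.TextureParams(), (512, 512), rng=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-case feature-level cohort with the default drift."""
    return syn.generate_feature_sequences(
        syn.CohortSpec(n_cases=40, prevalence=0.5, seed=5), dim=12
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
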