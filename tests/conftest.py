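import numpy as np
import pandas as pd
import pytest

from nanosorb.pmf import PMFProfile
from nanosorb.synthetic import GeneratorConfig, generate_descriptor_table, generate_endpoints


def make_profile(z, g, normalized=False, phase="aqueous"):
    return PMFProfile(
        adsorbate_id="test",
        phase=phase,
        adsorbent_id="BP",
        z_grid=np.asarray(z, dtype=float),
        g_values=np.asarray(g, dtype=float),
        normalized=normalized,
    )


@pytest.fixture
def canonical_grid():
    """The canonical 3–15 Å grid at 0.05 Å spacing (241 points)."""
    return np.linspace(3.0, 15.0, 241)


@pytest.fixture
def flat_profile(canonical_grid):
    return make_profile(canonical_grid, np.zeros_like(canonical_grid), normalized=True)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-condition synthetic cohort (41 compounds)."""
    config = GeneratorConfig()
    table = generate_descriptor_table(config, seed=11)
    return generate_endpoints(table, config, seed=12)


@pytest.fixture(scope="session")
def small_table():
    """A 20-compound synthetic table for brute-force oracle checks."""
    config = GeneratorConfig(n_compounds=20)
    table = generate_descriptor_table(config, seed=5)
    return generate_endpoints(table, config, seed=6).table
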