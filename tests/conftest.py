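import numpy as np
import pytest

from nichephylo.containers import Chronogram, EnvStack, OccurrenceSet
from nichephylo.enm_maxent import ModelSettings
from nichephylo.synthetic_data import TrueNiche, generate_env_stack


@pytest.fixture(scope="session")
def small_env() -> EnvStack:
    """A 20x20, 2-layer autocorrelated landscape (5 km cells)."""
    return generate_env_stack(
        2, (20, 20), corr_length_km=15.0, inter_layer_corr=0.3, cell_size_km=5.0, seed=3
    )


@pytest.fixture(scope="session")
def fast_settings() -> ModelSettings:
    """Model settings tuned for many repeated fits in randomization tests."""
    return ModelSettings(max_iter=60, tol=1e-5, background_n=400)


@pytest.fixture
def balanced_quartet() -> Chronogram:
    return Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def wide_niche() -> TrueNiche:
    return TrueNiche([0.5, 0.0], [1.0, 1.0])


def masked_single_cell_env() -> EnvStack:
    """A 5x5 grid with every cell masked except (2, 3)."""
    mask = np.ones((5, 5), dtype=bool)
    mask[2, 3] = False
    data = np.arange(25, dtype=float).reshape(1, 5, 5)
    return EnvStack(["env1"], data, cell_size_km=1.0, nodata_mask=mask)
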