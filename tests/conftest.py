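import numpy as np
import pytest

from twinpgs import simulate


@pytest.fixture(scope="session")
def small_study():
    """Moderate study with all channels at defaults, item-level data included."""
    cfg = simulate.SimConfig(n_families=400, n_snps=150, seed=42)
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def dz_study():
    """DZ-only study under random mating in a homogeneous population."""
    cfg = simulate.SimConfig(
        n_families=2000, n_snps=300, prop_mz=0.0, rho_mate=0.0,
        fst=0.0, n_subpops=1, seed=7,
    )
    return simulate.simulate_study(cfg, items=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
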