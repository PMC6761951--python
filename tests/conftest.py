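import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from zwdose.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A reusable mid-size simulated study with the default planted structure."""
    cfg = SimConfig(n_autosomal_genes=2000, n_z_genes=200, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """No dosage effect, no sex bias: a fully exchangeable dataset."""
    cfg = SimConfig(
        n_autosomal_genes=2000,
        n_z_genes=200,
        seed=8,
        d_z_male=1.0,
        d_z_female=1.0,
        sexbias_fraction_per_stage=(0.0, 0.0, 0.0),
    )
    return simulate(cfg)
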