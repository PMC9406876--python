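"""Shared fixtures: synthetic samples reused across test modules.

Session-scoped so the heavier simulations run once. Seeds are fixed;
nothing here reads external data.
"""

import numpy as np
import pytest

from senescan import GateConfig, calibrate_morphology, default_spec, simulate_events


@pytest.fixture(scope="session")
def huvec_prolif():
    """Proliferating HUVEC-like sample, n=20000 (printed-mean calibration)."""
    return simulate_events(default_spec("HUVEC", "proliferating", seed=11), 20000)


@pytest.fixture(scope="session")
def huvec_sen():
    """Senescent HUVEC-like sample, n=20000."""
    return simulate_events(default_spec("HUVEC", "senescent", seed=12), 20000)


@pytest.fixture(scope="session")
def huvec_pair_small():
    """Smaller paired samples (n=5000 each) for classifier workflows."""
    prolif = simulate_events(default_spec("HUVEC", "proliferating", seed=21), 5000)
    sen = simulate_events(default_spec("HUVEC", "senescent", seed=22), 5000)
    return prolif, sen


@pytest.fixture(scope="session")
def calibrated_gate(huvec_prolif):
    """Extended-gate config with morphology minima from true prolif singles."""
    df = huvec_prolif.table.data
    singles = df[df["true_structure"] == "single"]
    return calibrate_morphology(GateConfig(), singles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
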