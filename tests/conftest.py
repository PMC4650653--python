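"""Shared fixtures: the study-condition simulations, built once per session."""

import numpy as np
import pytest

from longread_audit import synthetic_data as sd


@pytest.fixture(scope="session")
def error_sim():
    """24× over 2 Mb with per-base error rates 0.01%/0.02%/0.10%."""
    return sd.run_simulation(sd.error_profile_scenario(seed=11))


@pytest.fixture(scope="session")
def insertion_sim():
    """50 injected insertions of 9–2000 bp, 12×, error-free reads."""
    return sd.run_simulation(sd.insertion_scenario(seed=5))


@pytest.fixture(scope="session")
def tandem_sim():
    """2 kb and 300 bp TGATA clusters plus interspersed repeats, 24×."""
    return sd.run_simulation(sd.tandem_scenario(seed=3))


@pytest.fixture(scope="session")
def collapsed_sim():
    """Collapsed 7.2 kb unit with 20 donor copies, 24×."""
    return sd.run_simulation(sd.collapsed_scenario(seed=9))


@pytest.fixture(scope="session")
def null_sim():
    """Zero error rates, zero injected variants, one blocked cluster."""
    return sd.run_simulation(sd.null_scenario(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
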