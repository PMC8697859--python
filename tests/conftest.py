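"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from spectroml import SynthConfig, generate
from spectroml.elements import get_element_table


@pytest.fixture(scope="session")
def element_table():
    return get_element_table()


@pytest.fixture(scope="session")
def tiny_dataset():
    """40-molecule smooth-surface dataset (standard noise levels)."""
    ds, truth = generate(SynthConfig(n_molecules=40, seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def smooth_dataset():
    """250-molecule smooth-surface dataset at the default study conditions."""
    ds, truth = generate(SynthConfig(n_molecules=250, seed=7))
    return ds, truth


@pytest.fixture(scope="session")
def noiseless_badger_dataset():
    """Exactly rule-constant dataset (no noise) for constancy diagnostics."""
    ds, truth = generate(
        SynthConfig(
            n_molecules=60, seed=5, truth="badger_exact",
            noise_Re=0.0, noise_we=0.0, noise_D0=0.0,
        )
    )
    return ds, truth
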