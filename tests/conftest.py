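"""Shared fixtures.

The designed library is expensive (a seeded optimization run), so it is built
once per session and shared by the designer, circuit and acceptance tests.
"""

from __future__ import annotations

import warnings

import pytest

from swtkit import DesignConstraints, EnergyModel, design_library

LIBRARY_SEED = 11
LIBRARY_SIZE = 3


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    return EnergyModel.default()


@pytest.fixture(scope="session")
def constraints() -> DesignConstraints:
    return DesignConstraints(rng_seed=LIBRARY_SEED)


@pytest.fixture(scope="session")
def library(constraints, model):
    """A designed 3-member orthogonal library (deterministic, seed 1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return design_library(LIBRARY_SIZE, constraints, model)
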