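"""Shared fixtures: study waters, seed populations, reference profiles."""

import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from aragsim import (
    ARTIFICIAL_SEAWATER,
    NATURAL_SEAWATER,
    ConstantsSet,
    ExperimentConfig,
    SeedPopulation,
    simulate_profile,
)

#: The three experimental (pH_NBS, DIC μmol/kg) set points and printed Ω means.
CONDITIONS = [(8.337, 3000.0, 6.9), (8.445, 4000.0, 11.3), (8.564, 5500.0, 19.2)]


@pytest.fixture(scope="session")
def constants25():
    return ConstantsSet.from_conditions(25.0, 35.0)


@pytest.fixture(scope="session")
def waters():
    return {"natural": NATURAL_SEAWATER, "artificial": ARTIFICIAL_SEAWATER}


def water_at(water, pH, dic):
    """A study water re-equilibrated to an experimental set point."""
    return dataclasses.replace(water, pH_NBS=pH, DIC=dic, TA=None)


@pytest.fixture(scope="session")
def seed_200mg():
    return SeedPopulation.from_mass_ssa(0.2)


@pytest.fixture(scope="session")
def seed_400mg():
    return SeedPopulation.from_mass_ssa(0.4)


@pytest.fixture(scope="session")
def profile_400mg_617(seed_400mg):
    """Reference noiseless run: 400 mg seed, 617 μmol m⁻² h⁻¹, 5 mL target."""
    return simulate_profile(ExperimentConfig(seed=seed_400mg, rate=617.0))
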