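"""Shared fixtures: reference model and the trajectory panel.

Trajectories are session-scoped because the acceptance checks and several
unit tests read different quantities off the same simulations.
"""

import pytest

from pipnet.model import InhibitorEvent, apply_genotype
from pipnet.simulate import Protocol, simulate, steady_state
from pipnet.synth import GENOTYPES, reference_parameterization


@pytest.fixture(scope="session")
def reference_model():
    return reference_parameterization()


@pytest.fixture(scope="session")
def genotype_models(reference_model):
    return {name: apply_genotype(reference_model, geno)
            for name, geno in GENOTYPES.items()}


@pytest.fixture(scope="session")
def steady_states(genotype_models):
    return {name: steady_state(m) for name, m in genotype_models.items()}


@pytest.fixture(scope="session")
def vehicle_trajectories(genotype_models, steady_states):
    proto = Protocol()
    return {name: simulate(m, proto, initial_state=steady_states[name])
            for name, m in genotype_models.items()}


@pytest.fixture(scope="session")
def chase_trajectories(genotype_models, steady_states):
    proto = Protocol(inhibitor=InhibitorEvent(60.0, 0.0))
    return {name: simulate(m, proto, initial_state=steady_states[name])
            for name, m in genotype_models.items()}
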