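import numpy as np
import pytest

from smoltreg import synthio
from smoltreg.synthio import GroundTruth, SimDesign


@pytest.fixture(scope="session")
def design():
    return SimDesign(seed=7)


@pytest.fixture(scope="session")
def annotation(design):
    return synthio.simulate_annotation(design)


@pytest.fixture(scope="session")
def truth(design, annotation):
    t = GroundTruth()
    synthio.plant_expression_truth(design, annotation, t)
    return t


@pytest.fixture(scope="session")
def matrix(design, truth, annotation):
    return synthio.simulate_expression(design, truth, annotation=annotation)


@pytest.fixture(scope="session")
def atac(design, truth, annotation):
    return synthio.simulate_atac(design, truth, annotation,
                                 da_coupled_cluster=3)


@pytest.fixture(scope="session")
def meth(design, truth):
    return synthio.simulate_methylation(design, truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
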