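import numpy as np
import pytest

from neuromotif.morphology import NeuronMorphology, SpaceSpec
from neuromotif.synthetic import GeneratorParams, generate_population
from neuromotif.tree import extract_topological_minor


def make_morphology(points, structure, parents, neuron_id="test"):
    return NeuronMorphology(
        neuron_id=neuron_id,
        points=np.asarray(points, float),
        structure=np.asarray(structure, dtype=object),
        parent_index=np.asarray(parents, int),
        space=SpaceSpec("PIR", 1.0),
    )


@pytest.fixture
def y_tree():
    """Soma at origin, trunk to (0,0,100), two leaves at (+-50, 0, 200)."""
    return make_morphology(
        points=[[0, 0, 0], [0, 0, 100], [-50, 0, 200], [50, 0, 200]],
        structure=["soma", "axon", "axon", "axon"],
        parents=[-1, 0, 1, 1],
        neuron_id="y-tree",
    )


@pytest.fixture(scope="session")
def noiseless_population():
    """Small noiseless synthetic population shared across tests."""
    params = GeneratorParams(noise_um=0.0)
    neurons, atlas, truth = generate_population(25, params, seed=11)
    return neurons, atlas, truth, params


@pytest.fixture(scope="session")
def noiseless_minors(noiseless_population):
    neurons, _atlas, _truth, _params = noiseless_population
    return [extract_topological_minor(m) for m in neurons]
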