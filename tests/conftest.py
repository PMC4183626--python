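import numpy as np
import pytest

from pkaffinity import synthetic
from pkaffinity.synthetic import ContactSpec, EnsembleRecipe


@pytest.fixture(scope="session")
def published_tables():
    return synthetic.published_tables()


@pytest.fixture()
def toy_complex():
    """Small parameterized receptor+ligand with one salt-bridge contact."""
    system, partition = synthetic.make_toy_complex(
        2, 1, [ContactSpec(1, 1, 2.9, receptor_charge=0.8, ligand_charge=-0.8)],
        seed=7,
    )
    return system, partition


@pytest.fixture()
def toy_ensemble(toy_complex):
    system, partition = toy_complex
    pair = synthetic.contact_atom_indices(system)[0]
    recipe = EnsembleRecipe(n_frames=40, sigma=0.15, seed=11,
                            hb_schedule=((pair, 75.0),))
    return synthetic.make_ensemble(system, recipe), system, partition, pair


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
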