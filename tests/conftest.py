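import numpy as np
import pytest

from ddilink.chem_graph import parse_smiles
from ddilink.synthdata import SyntheticSpec, generate_ddi, generate_molecules, generate_pretrain_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """40 parsed synthetic molecules for pretraining-level tests."""
    return [parse_smiles(s) for s in generate_pretrain_corpus(40, seed=11)]


@pytest.fixture(scope="session")
def toy_benchmark():
    """A 40-drug planted-signal dataset: (drugs, network, molecules-with-classes)."""
    spec = SyntheticSpec(n_drugs=40, seed=7)
    mols = generate_molecules(spec)
    network = generate_ddi(mols, spec)
    return [(d, s) for d, s, _ in mols], network, mols


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
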