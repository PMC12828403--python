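import numpy as np
import pytest

from ddpks import synthdata
from ddpks.structio import Atom, AtomicModel, Chain, Residue


@pytest.fixture(scope="session")
def toy_dimer():
    """Small C2-symmetric 3-domain dimer plus its ground-truth metadata."""
    spec = synthdata.SynthDimerSpec([("KS", 60), ("AT", 60), ("DH", 60)], seed=11)
    return synthdata.make_dimer(spec)


@pytest.fixture(scope="session")
def toy_registry(toy_dimer):
    return synthdata.dimer_registry(toy_dimer[1])


def single_atom_model(xyz=(0.0, 0.0, 0.0), name="CA", resname="ALA"):
    return AtomicModel("single", [Chain("A", [Residue(1, resname, [
        Atom(name, "C", np.array(xyz))])])])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
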