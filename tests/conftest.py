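import numpy as np
import pytest

from bmap import synth
from bmap.structures import StructureModel


@pytest.fixture(scope="session")
def truth():
    """Default synthetic bipartite complex (session-cached)."""
    return synth.make_bipartite_truth(seed=1)


@pytest.fixture(scope="session")
def sim_config():
    return synth.SimConfig(seed=1)


def make_model(atoms, model_id=1):
    """Build a StructureModel from (chain, resnum, resname, atom, element, xyz) rows."""
    chains, resnums, resnames, atnames, elements, xyz = zip(*atoms)
    return StructureModel(
        np.array(chains), np.array(resnums, dtype=int), np.array(resnames),
        np.array(atnames), np.array(elements), np.array(xyz, dtype=float),
        model_id,
    )
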