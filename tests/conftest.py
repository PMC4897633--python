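import numpy as np
import pytest

from memanchor import alpha_synuclein_anchor, build_ideal_helix
from memanchor.ensemble import Ensemble
from memanchor.geometry import torsions_to_cartesian


@pytest.fixture(scope="session")
def chain():
    return alpha_synuclein_anchor()


@pytest.fixture(scope="session")
def ideal_helix(chain):
    return build_ideal_helix(chain)


@pytest.fixture(scope="session")
def extended_conf(chain):
    t = np.tile([-180.0, 180.0], (len(chain), 1))
    return torsions_to_cartesian(t, chain)


@pytest.fixture(scope="session")
def helix_ensemble(ideal_helix):
    """Ten identical ideal-helix frames."""
    return Ensemble.from_conformations([ideal_helix] * 10)


@pytest.fixture(scope="session")
def partially_helical(chain):
    from memanchor.synthetic import generate_helical_ensemble
    ens, states = generate_helical_ensemble(chain, 0.7, 400, seed=101)
    return ens, states
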