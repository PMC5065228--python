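import numpy as np
import pytest

from sitescan import synth
from sitescan.structio import Atom, Structure


@pytest.fixture(scope="session")
def small_spec():
    return synth.default_spec(
        seed=11, n_substrates=3, n_nonsubstrates=2, n_poses=5, n_conformations=2
    )


@pytest.fixture(scope="session")
def bundle(small_spec):
    """(Structure, [SiteDefinition]) for a small synthetic helix bundle."""
    return synth.helix_bundle(small_spec)


@pytest.fixture()
def two_atom_structure():
    def build(frames):
        models = []
        for x1, x2 in frames:
            models.append(
                [
                    Atom(serial=1, name="CA", resname="ALA", chain="A", resid=1,
                         xyz=np.asarray(x1, dtype=float), element="C"),
                    Atom(serial=2, name="CA", resname="GLY", chain="A", resid=2,
                         xyz=np.asarray(x2, dtype=float), element="C"),
                ]
            )
        return Structure(models, id="pairtest")

    return build
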