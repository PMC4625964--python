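import numpy as np
import pytest

from mmsie.model_io import Atom, Topology, Trajectory
from mmsie.synthetic_data import HBondDesign, ToyComplexSpec, make_toy_complex


def make_atom(i, **kw):
    defaults = dict(
        serial=i, name=f"X{i}", element="C", residue_index=1,
        residue_name="TOY", chain_id="A",
    )
    defaults.update(kw)
    return Atom(**defaults)


@pytest.fixture
def ion_pair():
    """+1/-1 ion pair at the distance giving exactly -100 kcal/mol."""
    topo, frame = make_toy_complex(ToyComplexSpec(
        n_receptor_residues=1, atoms_per_residue=1, ligand_atoms=1,
        charge_pattern=((1.0,), (-1.0,)),
    ))
    return topo, frame


@pytest.fixture
def small_complex():
    """3-residue/2-atom receptor with a 2-atom ligand, mixed charges."""
    return make_toy_complex(ToyComplexSpec(n_receptor_residues=3))


@pytest.fixture
def hbond_complex():
    """Toy complex with a designed donor-H...acceptor triple (2.83 A, 149.25 deg)."""
    return make_toy_complex(ToyComplexSpec(designed_hbond=HBondDesign()))


@pytest.fixture
def static_traj(small_complex):
    topo, frame = small_complex
    coords = np.repeat(frame[None], 5, axis=0)
    return Trajectory(coords, np.arange(5.0), topo)
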