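import numpy as np
import pytest

from proqa.structure_io import Atom, ProteinModel, Residue, assign_atom_class


def ca_residue(aa: str, index: int, xyz) -> Residue:
    """A residue carrying only its Calpha, for contact-geometry tests."""
    return Residue(aa, index, [Atom("CA", "C", index, np.asarray(xyz, float), 2, False)])


def ca_model(entries, model_id="toy", target_length=None) -> ProteinModel:
    """Model from (aa, index, xyz) triples, Calpha-only."""
    residues = [ca_residue(aa, i, xyz) for aa, i, xyz in entries]
    return ProteinModel(model_id, residues, target_length)


def place_atom(aa, name, index, xyz):
    return Atom(name, name[0], index, np.asarray(xyz, float), assign_atom_class(aa, name), name not in ("N", "CA", "C", "O", "OXT"))


@pytest.fixture(scope="session")
def helix_native():
    from proqa.fixtures import make_native

    return make_native(30, "helix", seed=42)


@pytest.fixture(scope="session")
def two_domain_native():
    from proqa.fixtures import make_native

    return make_native(60, "two_domain", seed=7)


@pytest.fixture(scope="session")
def helix_inputs(helix_native):
    from proqa.fixtures import make_sequence_inputs

    return make_sequence_inputs(helix_native, accuracy=0.9, seed=3)
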