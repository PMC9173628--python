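import numpy as np
import pytest

from evbmech.fixtures import make_active_site_fixture
from evbmech.structure import Atom, Structure


@pytest.fixture(scope="session")
def two_mg_fixture():
    return make_active_site_fixture(seed=1, n_waters=20, variant="two_mg")


@pytest.fixture(scope="session")
def mg_b_fixture():
    return make_active_site_fixture(seed=1, n_waters=20, variant="mg_b")


@pytest.fixture(scope="session")
def reference_fixture():
    return make_active_site_fixture(seed=1, n_waters=20, variant="reference")


def make_structure(spec):
    """Structure from (name, element, resname, resnum, chain, xyz[, q]) rows."""
    atoms = []
    for i, row in enumerate(spec):
        name, element, resname, resnum, chain, xyz = row[:6]
        q = row[6] if len(row) > 6 else None
        atoms.append(Atom(serial=i + 1, name=name, element=element,
                          residue_name=resname, residue_number=resnum,
                          chain_id=chain, position=tuple(map(float, xyz)),
                          partial_charge=q))
    return Structure(atoms, title="test", source="fixture")


@pytest.fixture
def triangle_structure():
    """Two single-atom residues 5 Å apart (3-4-5 triangle) plus a third."""
    return make_structure([
        ("CA", "C", "GLY", 1, "A", (0.0, 0.0, 0.0)),
        ("CA", "C", "GLY", 2, "A", (3.0, 4.0, 0.0)),
        ("CA", "C", "GLY", 3, "B", (6.0, 0.0, 0.0)),
    ])
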