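import numpy as np
import pytest

from thermotriage.structure import Atom, Residue, Structure


def build_structure(residue_specs, structure_id="toy"):
    """Assemble a Structure from compact specs.

    residue_specs: list of (chain, number, aa3, atoms) where atoms is a list
    of (atom_name, element, (x, y, z)).
    """
    residues = []
    serial = 0
    for chain, number, aa3, atoms in residue_specs:
        res = Residue(chain=chain, number=number, icode="", aa3=aa3)
        for name, element, xyz in atoms:
            serial += 1
            res.atoms.append(Atom(
                serial=serial, name=name, element=element,
                residue_ref=(chain, number, ""), coords=np.asarray(xyz, float)))
        residues.append(res)
    return Structure(id=structure_id, residues=residues)


@pytest.fixture
def make_toy_structure():
    return build_structure
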