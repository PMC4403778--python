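from __future__ import annotations

import numpy as np
import pytest

from mtlminer.pdb_io import Atom, Structure
from mtlminer.ligand_extract import LigandInstance


def make_atom(kind="polymer", serial=1, name="CA", resname="ALA", chain="A",
              seq=1, icode="", xyz=(0.0, 0.0, 0.0), element="C", alt=""):
    return Atom(record_kind=kind, serial=serial, name=name, alt_loc=alt,
                residue_name=resname, chain_id=chain, residue_seq=seq,
                insertion_code=icode, x=float(xyz[0]), y=float(xyz[1]),
                z=float(xyz[2]), occupancy=1.0, element=element)


def make_structure(atoms, sid="TEST", method="X-RAY DIFFRACTION",
                   resolution=2.0):
    return Structure(structure_id=sid, experiment_method=method,
                     resolution=resolution, atoms=atoms)


def random_site_structure(rng, n_res, n_lig_atoms=10, box=40.0):
    """Random protein residues (4 atoms each) + a hetero ligand, as a
    Structure and LigandInstance pair for distance tests."""
    atoms = []
    serial = 1
    for r in range(n_res):
        center = rng.uniform(-box, box, size=3)
        for k, name in enumerate(("N", "CA", "C", "O")):
            pos = center + rng.uniform(-1.2, 1.2, size=3)
            atoms.append(make_atom(serial=serial, name=name,
                                   element=name[0], seq=r + 1,
                                   chain="AB"[r % 2], xyz=pos))
            serial += 1
    lig_center = rng.uniform(-box / 3, box / 3, size=3)
    lig_atoms = []
    for k in range(n_lig_atoms):
        pos = lig_center + rng.uniform(-2.5, 2.5, size=3)
        atom = make_atom(kind="hetero", serial=serial, name=f"C{k + 1}",
                         resname="LIG", chain="L", seq=901, xyz=pos)
        lig_atoms.append(atom)
        atoms.append(atom)
        serial += 1
    s = make_structure(atoms)
    lig = LigandInstance(component_id="LIG", chain_id="L", residue_seq=901,
                         insertion_code="", atoms=lig_atoms,
                         heavy_atom_count=n_lig_atoms,
                         source_structure_id="TEST")
    return s, lig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
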