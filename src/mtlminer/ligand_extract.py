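"""Ligand instance identification: hetero-residue grouping, water exclusion
and the strict heavy-atom threshold (>8 by default)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .pdb_io import Atom, Structure, _KNOWN_ELEMENTS

logger = logging.getLogger(__name__)

#: Component codes always treated as water.
WATER_CODES = frozenset({"HOH", "DOD", "WAT"})

#: Common buffer/cryoprotectant components (all <=8 heavy atoms); available
#: as an optional exclusion list but NOT excluded by default.
COMMON_SOLVENT_CODES = frozenset({"GOL", "EDO", "SO4", "PO4", "ACT", "DMS", "PEG"})


@dataclass
class LigandInstance:
    """One occurrence of a chemical component in one structure."""

    component_id: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    atoms: list[Atom] = field(default_factory=list)
    heavy_atom_count: int = 0
    source_structure_id: str = ""

    @property
    def instance_key(self) -> tuple[str, str, str, int, str]:
        return (self.source_structure_id, self.component_id, self.chain_id,
                self.residue_seq, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element not in ("H", "D")]


def heavy_atom_count(atoms: list[Atom]) -> int:
    """Number of atoms whose element is neither H nor D.

    Unrecognized element symbols are counted as heavy and logged.
    """
    n = 0
    for a in atoms:
        el = a.element.upper()
        if el in ("H", "D"):
            continue
        if el not in _KNOWN_ELEMENTS:
            logger.warning("unrecognized element %r counted as heavy", a.element)
        n += 1
    return n


def identify_ligand_instances(
    s: Structure,
    min_heavy_atoms: int = 8,
    exclusion_list: frozenset[str] | set[str] = frozenset(),
) -> list[LigandInstance]:
    """Hetero residues with strictly more than ``min_heavy_atoms`` heavy atoms.

    Water (HOH/DOD/WAT) is always excluded; ``exclusion_list`` adds further
    component codes. Output order is (chain, residue_seq, insertion_code).
    """
    excluded = WATER_CODES | set(exclusion_list)
    groups: dict[tuple[str, str, int, str], list[Atom]] = {}
    for atom in s.hetero_atoms():
        key = (atom.residue_name, atom.chain_id, atom.residue_seq,
               atom.insertion_code)
        groups.setdefault(key, []).append(atom)
    instances: list[LigandInstance] = []
    for (comp, chain, seq, icode), atoms in groups.items():
        if comp in excluded:
            continue
        n_heavy = heavy_atom_count(atoms)
        if n_heavy <= min_heavy_atoms:
            continue
        instances.append(LigandInstance(
            component_id=comp, chain_id=chain, residue_seq=seq,
            insertion_code=icode, atoms=atoms, heavy_atom_count=n_heavy,
            source_structure_id=s.structure_id,
        ))
    instances.sort(key=lambda li: (li.chain_id, li.residue_seq,
                                   li.insertion_code))
    return instances


def instance_filename(lig: LigandInstance) -> str:
    return (f"{lig.source_structure_id}_{lig.component_id}_"
            f"{lig.chain_id}_{lig.residue_seq}.pdb")
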