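"""Binding-site extraction: all amino-acid polymer residues with any atom
within the cutoff radius (inclusive) of any ligand atom, whole residues
included, plus the strict site-size filter (>5 residues)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .pdb_io import Atom, NUCLEIC_RESIDUES, Structure
from .ligand_extract import LigandInstance

ResidueKey = tuple[str, int, str]


@dataclass
class BindingSite:
    """Protein residues in contact with one ligand instance."""

    ligand_ref: tuple[str, str, str, int]   # (structure_id, component, chain, seq)
    residues: list[tuple[str, int, str, str]]  # (chain, seq, icode, resname)
    residue_count: int
    contributing_chain_tally: dict[str, int]
    site_atoms: list[Atom] = field(default_factory=list)
    min_distances: dict[ResidueKey, float] = field(default_factory=dict)


def _protein_atoms(s: Structure) -> list[Atom]:
    return [a for a in s.polymer_atoms()
            if a.residue_name not in NUCLEIC_RESIDUES]


def extract_binding_site(s: Structure, lig: LigandInstance,
                         radius: float = 6.0) -> BindingSite:
    """Residues with any atom at Euclidean distance <= radius from any
    ligand atom. All ligand atoms participate, hydrogens included."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ligand_ref = (lig.source_structure_id, lig.component_id, lig.chain_id,
                  lig.residue_seq)
    protein = _protein_atoms(s)
    if not protein or not lig.atoms:
        return BindingSite(ligand_ref, [], 0, {}, [], {})

    lig_xyz = np.array([a.coords for a in lig.atoms], dtype=float)
    prot_xyz = np.array([a.coords for a in protein], dtype=float)
    nearest = cdist(prot_xyz, lig_xyz).min(axis=1)

    res_min: dict[ResidueKey, float] = {}
    res_name: dict[ResidueKey, str] = {}
    res_order: dict[ResidueKey, int] = {}
    for i, atom in enumerate(protein):
        key = atom.residue_key
        d = float(nearest[i])
        if key not in res_min or d < res_min[key]:
            res_min[key] = d
        res_name.setdefault(key, atom.residue_name)
        res_order.setdefault(key, i)

    member_keys = {k for k, d in res_min.items() if d <= radius}
    ordered = sorted(member_keys)
    residues = [(c, seq, ic, res_name[(c, seq, ic)]) for c, seq, ic in ordered]
    site_atoms = [a for a in protein if a.residue_key in member_keys]
    tally: dict[str, int] = {}
    for c, _seq, _ic in ordered:
        tally[c] = tally.get(c, 0) + 1
    return BindingSite(
        ligand_ref=ligand_ref, residues=residues, residue_count=len(residues),
        contributing_chain_tally=tally, site_atoms=site_atoms,
        min_distances={k: res_min[k] for k in ordered},
    )


def passes_site_filter(site: BindingSite, min_residues: int = 5) -> bool:
    """True iff the site has strictly more than ``min_residues`` residues."""
    return site.residue_count > min_residues


def primary_binding_chain(site: BindingSite) -> str:
    """Chain contributing the most site residues; ties break alphabetically."""
    if not site.residues:
        raise ValueError("empty binding site has no primary chain")
    return min(site.contributing_chain_tally.items(),
               key=lambda kv: (-kv[1], kv[0]))[0]


def site_residues_tsv(site: BindingSite) -> str:
    """Sidecar TSV: chain, seq, icode, name, min distance to ligand (3 dp)."""
    lines = ["chain\tresidue_seq\tinsertion_code\tresidue_name\tmin_distance"]
    for chain, seq, icode, name in site.residues:
        d = site.min_distances[(chain, seq, icode)]
        lines.append(f"{chain}\t{seq}\t{icode}\t{name}\t{d:.3f}")
    return "\n".join(lines) + "\n"
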