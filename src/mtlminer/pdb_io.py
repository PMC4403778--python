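"""Legacy PDB text parsing and writing.

Reads ATOM/HETATM/MODEL/ENDMDL/REMARK 2/EXPDTA/HEADER records from
fixed-column PDB text and exposes atoms, per-chain protein sequences and
experiment metadata. Only the first MODEL of multi-model files is kept;
alternate locations other than blank/'A' are dropped.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Standard 3-letter -> 1-letter amino-acid codes.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Residue names of standard nucleic-acid components (not amino acids).
NUCLEIC_RESIDUES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}

_KNOWN_ELEMENTS = {
    "H", "D", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG",
    "AL", "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR",
    "MN", "FE", "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR",
    "RB", "SR", "Y", "ZR", "MO", "RU", "RH", "PD", "AG", "CD", "IN", "SN",
    "SB", "TE", "I", "XE", "CS", "BA", "W", "RE", "OS", "IR", "PT", "AU",
    "HG", "TL", "PB", "BI", "U",
}


@dataclass(frozen=True)
class Atom:
    """One coordinate record (ATOM or HETATM) from a PDB file."""

    record_kind: str          # "polymer" (ATOM) or "hetero" (HETATM)
    serial: int
    name: str                 # stripped atom name, e.g. "CA", "C1"
    alt_loc: str              # "" or a single character
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    x: float
    y: float
    z: float
    occupancy: float
    element: str

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Structure:
    """One parsed crystal structure (first model only)."""

    structure_id: str
    experiment_method: str
    resolution: float | None
    atoms: list[Atom]
    model_count: int = 1

    def polymer_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.record_kind == "polymer"]

    def hetero_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.record_kind == "hetero"]


@dataclass
class ChainSequence:
    """One-letter protein sequence of a chain, ATOM-record derived."""

    chain_id: str
    sequence: str
    residue_index_map: list[tuple[int, str]] = field(default_factory=list)


_RESOLUTION_RE = re.compile(
    r"REMARK\s+2\s+RESOLUTION\.\s+(\d+(?:\.\d+)?)\s+ANGSTROM"
)


def _infer_element(name: str, residue_name: str) -> str:
    """Fallback element inference from the atom-name field."""
    alpha = "".join(c for c in name if c.isalpha()).upper()
    if not alpha:
        return ""
    if len(alpha) >= 2 and alpha[:2] in _KNOWN_ELEMENTS and alpha[:2] not in (
        "CA", "CB", "CD", "CE", "CG", "ND", "NE", "NH", "OD", "OE", "OG",
        "OH", "SD", "SG", "CH", "NZ", "CZ", "HB", "HA", "HD", "HE", "HG",
    ):
        return alpha[:2]
    return alpha[0]


def _parse_coord_line(line: str, kind: str) -> Atom | None:
    line = line.rstrip("\n")
    if len(line) < 54:
        raise ValueError("line too short")
    serial = int(line[6:11])
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21].strip()
    residue_seq = int(line[22:26])
    insertion_code = line[26].strip() if len(line) > 26 else ""
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    occ_field = line[54:60].strip() if len(line) >= 60 else ""
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name, residue_name)
    if not element:
        raise ValueError("element could not be resolved")
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise ValueError("non-finite coordinate")
    return Atom(
        record_kind=kind, serial=serial, name=name, alt_loc=alt_loc,
        residue_name=residue_name, chain_id=chain_id, residue_seq=residue_seq,
        insertion_code=insertion_code, x=x, y=y, z=z, occupancy=occupancy,
        element=element,
    )


def parse_structure(pdb_text: str, structure_id: str = "") -> Structure:
    """Parse legacy PDB text into a :class:`Structure` (model 1 only).

    Malformed coordinate lines are skipped with a warning. Raises
    ``ValueError`` if the text contains no parseable coordinate line.
    """
    atoms: list[Atom] = []
    resolution: float | None = None
    method = ""
    sid = structure_id
    model_count = 0
    in_later_model = False
    for line in pdb_text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            model_count += 1
            in_later_model = model_count > 1
            continue
        if rec == "ENDMDL":
            continue
        if rec == "HEADER" and len(line) >= 66 and not sid:
            sid = line[62:66].strip()
            continue
        if rec == "EXPDTA":
            method = line[6:].strip()
            continue
        if rec == "REMARK" and resolution is None:
            m = _RESOLUTION_RE.match(line)
            if m:
                resolution = float(m.group(1))
            continue
        if rec in ("ATOM  ", "HETATM"):
            if in_later_model:
                continue
            kind = "polymer" if rec == "ATOM  " else "hetero"
            try:
                atom = _parse_coord_line(line, kind)
            except (ValueError, IndexError) as exc:
                logger.warning("skipping malformed coordinate line (%s): %r",
                               exc, line[:30])
                continue
            if atom.alt_loc not in ("", "A"):
                continue
            atoms.append(atom)
    if not atoms:
        raise ValueError("no coordinate records found in PDB text")
    return Structure(
        structure_id=sid, experiment_method=method, resolution=resolution,
        atoms=atoms, model_count=max(model_count, 1),
    )


def passes_structure_filter(s: Structure, max_resolution: float = 3.0,
                            require_xray: bool = True) -> bool:
    """True iff the structure is X-ray (when required) with resolution
    strictly below ``max_resolution``. Absent resolution fails."""
    if require_xray and "X-RAY" not in s.experiment_method.upper():
        return False
    return s.resolution is not None and s.resolution < max_resolution


def chain_sequences(s: Structure, mse_to_met: bool = False) -> list[ChainSequence]:
    """ATOM-derived one-letter sequences, one per chain with polymer residues.

    Unknown 3-letter codes map to 'X' (optionally MSE->M). Duplicate
    residue keys collapse to the first occurrence; residue order follows
    file order.
    """
    mapping = dict(THREE_TO_ONE)
    if mse_to_met:
        mapping["MSE"] = "M"
    per_chain: dict[str, tuple[list[str], list[tuple[int, str]]]] = {}
    seen: set[tuple[str, int, str]] = set()
    for atom in s.atoms:
        if atom.record_kind != "polymer":
            continue
        key = atom.residue_key
        if key in seen:
            continue
        seen.add(key)
        letters, index_map = per_chain.setdefault(atom.chain_id, ([], []))
        letters.append(mapping.get(atom.residue_name, "X"))
        index_map.append((atom.residue_seq, atom.insertion_code))
    return [
        ChainSequence(chain_id=cid, sequence="".join(letters),
                      residue_index_map=index_map)
        for cid, (letters, index_map) in sorted(per_chain.items())
    ]


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2 or len(name) == 4:
        return f"{name:<4}"
    return f" {name:<3}"


def write_substructure(atoms: list[Atom], header_comment: str = "") -> str:
    """Serialize atoms back to PDB text (ends with END).

    Re-parsing preserves names, residues, chains and coordinates to 3
    decimals. Raises ``ValueError`` on an empty atom list.
    """
    if not atoms:
        raise ValueError("cannot write an empty atom list")
    lines: list[str] = []
    for comment in header_comment.splitlines():
        lines.append(f"REMARK 999 {comment}"[:80])
    for i, a in enumerate(atoms, start=1):
        rec = "ATOM  " if a.record_kind == "polymer" else "HETATM"
        name = _format_atom_name(a.name, a.element)
        lines.append(
            f"{rec}{i:>5} {name}{a.alt_loc:1}{a.residue_name:>3} "
            f"{a.chain_id:1}{a.residue_seq:>4}{a.insertion_code:1}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def chains_to_fasta(s: Structure, mse_to_met: bool = False) -> str:
    """FASTA with one record per polymer chain, ID ``<structure_id>_<chain>``."""
    out = []
    for cs in chain_sequences(s, mse_to_met=mse_to_met):
        out.append(f">{s.structure_id}_{cs.chain_id}")
        out.append(cs.sequence)
    return "\n".join(out) + ("\n" if out else "")
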