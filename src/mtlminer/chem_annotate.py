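"""Chemical annotation of ligands.

Bonds are perceived from coordinates with a covalent-radius-plus-tolerance
rule; on top of the resulting element-labelled graph the module computes
molecular weight, Lipinski rule-of-five descriptors, an FP2-style path
fingerprint (linear paths of 1..7 heavy atoms hashed into 1024 bits,
deterministic, versioned), Tanimoto similarity and connectivity-level
SMILES. Bond orders, aromaticity and stereochemistry are intentionally
not perceived.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

FINGERPRINT_HASH_VERSION = "mtl-path-v1"

#: Covalent radii (Angstrom) for bond perception.
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "NA": 1.66, "MG": 1.41, "SI": 1.11, "P": 1.07, "S": 1.05,
    "CL": 1.02, "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26,
    "NI": 1.24, "CU": 1.32, "ZN": 1.22, "SE": 1.20, "BR": 1.20, "I": 1.39,
}

#: IUPAC standard atomic weights (Da).
ATOMIC_WEIGHTS = {
    "H": 1.008, "D": 2.014, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "NA": 22.990, "MG": 24.305, "SI": 28.085,
    "P": 30.974, "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078,
    "MN": 54.938, "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546,
    "ZN": 65.38, "SE": 78.971, "BR": 79.904, "I": 126.904,
}

_DEFAULT_VALENCE = {"N": 3, "O": 2}


@dataclass
class MolecularGraph:
    """Element-labelled molecular topology (no bond orders)."""

    atoms: list[str]                       # element symbol per atom index
    bonds: list[tuple[int, int]]           # i < j, unique
    component_id: str = ""

    def __post_init__(self) -> None:
        canon = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError("self-bond in molecular graph")
            canon.add((min(i, j), max(i, j)))
        self.bonds = sorted(canon)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def heavy_indices(self) -> list[int]:
        return [i for i, el in enumerate(self.atoms)
                if el.upper() not in ("H", "D")]


def perceive_bonds(atoms: list[tuple[str, tuple[float, float, float]]],
                   tolerance: float = 0.45,
                   component_id: str = "") -> MolecularGraph:
    """Bond i-j iff distance <= r_cov(i) + r_cov(j) + tolerance.

    Hydrogens bond only to their single nearest heavy atom. Unknown
    elements raise ``ValueError`` naming the symbol.
    """
    if not atoms:
        raise ValueError("at least one atom required")
    elements = [el.upper() for el, _ in atoms]
    for el in elements:
        if el not in COVALENT_RADII:
            raise ValueError(f"unknown element symbol: {el!r}")
    xyz = np.array([c for _, c in atoms], dtype=float)
    if not np.isfinite(xyz).all():
        raise ValueError("non-finite coordinates")
    n = len(atoms)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    heavy = [i for i in range(n) if elements[i] not in ("H", "D")]
    bonds: set[tuple[int, int]] = set()
    for i in range(n):
        if elements[i] in ("H", "D"):
            continue
        for j in range(i + 1, n):
            if elements[j] in ("H", "D"):
                continue
            cut = COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]] + tolerance
            if dist[i, j] <= cut:
                bonds.add((i, j))
    for i in range(n):
        if elements[i] not in ("H", "D") or not heavy:
            continue
        j = min(heavy, key=lambda k: dist[i, k])
        cut = COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]] + tolerance
        if dist[i, j] <= cut:
            bonds.add((min(i, j), max(i, j)))
    return MolecularGraph(atoms=[el for el, _ in atoms], bonds=sorted(bonds),
                          component_id=component_id)


def molecular_weight(g: MolecularGraph) -> float:
    """Sum of standard atomic weights over all atoms (H included)."""
    total = 0.0
    for el in g.atoms:
        key = el.upper()
        if key not in ATOMIC_WEIGHTS:
            raise ValueError(f"no atomic weight for element {el!r}")
        total += ATOMIC_WEIGHTS[key]
    return total


@dataclass
class Descriptors:
    molecular_weight: float
    hbd: int
    hba: int
    logp: float | None
    lipinski_violations: int
    druglike: bool

    def to_dict(self) -> dict:
        return {
            "molecular_weight": round(self.molecular_weight, 3),
            "hbd": self.hbd, "hba": self.hba,
            "logp": None if self.logp is None else round(self.logp, 3),
            "lipinski_violations": self.lipinski_violations,
            "druglike": self.druglike,
        }


def lipinski(g: MolecularGraph, logp_provider=None) -> Descriptors:
    """Rule-of-five descriptors; drug-like iff at most one violation.

    HBD counts O-H/N-H bonds when explicit hydrogens are present;
    otherwise each N/O is imputed max(0, default valence - heavy degree)
    donors. HBA counts N and O atoms. The logP criterion is skipped when
    no provider is given.
    """
    mw = molecular_weight(g)
    elements = [el.upper() for el in g.atoms]
    adj = g.adjacency()
    has_h = any(el in ("H", "D") for el in elements)
    hbd = 0
    for i, el in enumerate(elements):
        if el not in ("N", "O"):
            continue
        if has_h:
            hbd += sum(1 for j in adj[i] if elements[j] in ("H", "D"))
        else:
            heavy_deg = sum(1 for j in adj[i] if elements[j] not in ("H", "D"))
            hbd += max(0, _DEFAULT_VALENCE[el] - heavy_deg)
    hba = sum(1 for el in elements if el in ("N", "O"))
    logp = logp_provider(g) if logp_provider is not None else None
    violations = 0
    if mw > 500:
        violations += 1
    if hbd > 5:
        violations += 1
    if hba > 10:
        violations += 1
    if logp is not None and logp > 5:
        violations += 1
    return Descriptors(molecular_weight=mw, hbd=hbd, hba=hba, logp=logp,
                       lipinski_violations=violations,
                       druglike=violations <= 1)


@dataclass
class Fingerprint:
    bits: frozenset[int]
    n_bits: int = 1024

    @property
    def n_set(self) -> int:
        return len(self.bits)

    def to_hex(self) -> str:
        value = 0
        for b in self.bits:
            value |= 1 << b
        width = (self.n_bits + 3) // 4
        return f"{value:0{width}x}"

    @classmethod
    def from_hex(cls, hex_str: str, n_bits: int = 1024) -> "Fingerprint":
        value = int(hex_str, 16)
        bits = frozenset(i for i in range(n_bits) if value >> i & 1)
        return cls(bits=bits, n_bits=n_bits)


def _canonical_path(elements: tuple[str, ...]) -> tuple[str, ...]:
    return min(elements, elements[::-1])


def enumerate_paths(g: MolecularGraph, max_path_len: int = 7) -> set[tuple[str, ...]]:
    """Canonical element sequences of all simple linear heavy-atom paths of
    1..max_path_len atoms."""
    heavy = set(g.heavy_indices())
    adj = g.adjacency()
    elements = [el.upper() for el in g.atoms]
    found: set[tuple[str, ...]] = set()

    def walk(path: list[int]) -> None:
        found.add(_canonical_path(tuple(elements[i] for i in path)))
        if len(path) == max_path_len:
            return
        for nxt in adj[path[-1]]:
            if nxt in heavy and nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    for start in sorted(heavy):
        walk([start])
    return found


def _hash_path(path: tuple[str, ...], n_bits: int) -> int:
    digest = hashlib.sha256("|".join(path).encode("ascii")).digest()
    return int.from_bytes(digest[:8], "big") % n_bits


def path_fingerprint(g: MolecularGraph, max_path_len: int = 7,
                     n_bits: int = 1024) -> Fingerprint:
    """Deterministic FP2-style fingerprint over canonical linear paths."""
    bits = {_hash_path(p, n_bits) for p in enumerate_paths(g, max_path_len)}
    return Fingerprint(bits=frozenset(bits), n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A n B| / |A u B|; 1.0 when both bitsets are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = a.bits | b.bits
    if not union:
        return 1.0
    return len(a.bits & b.bits) / len(union)


def similarity_search(query: MolecularGraph, db, cutoff: float = 0.8,
                      max_path_len: int = 7,
                      n_bits: int = 1024) -> list[tuple[str, float]]:
    """Records with tanimoto >= cutoff, sorted by score desc then id asc.

    ``db`` is an iterable of objects exposing ``component_id`` and
    ``fingerprint`` (or (component_id, Fingerprint) pairs).
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    qfp = path_fingerprint(query, max_path_len=max_path_len, n_bits=n_bits)
    hits = []
    for rec in db:
        if isinstance(rec, tuple):
            comp, fp = rec
        else:
            comp, fp = rec.component_id, rec.fingerprint
        score = tanimoto(qfp, fp)
        if score >= cutoff:
            hits.append((comp, score))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


_ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "CL", "BR", "I"}


def _smiles_symbol(element: str) -> str:
    el = element.upper()
    sym = el.capitalize() if len(el) == 2 else el
    return f"[{sym}]"


def to_smiles(g: MolecularGraph) -> str:
    """Connectivity-level SMILES over heavy atoms (single bonds only).

    Every atom is written bracketed so no implicit-hydrogen or valence
    model is implied; disconnected graphs yield dot-separated fragments.
    """
    heavy = g.heavy_indices()
    if not heavy:
        raise ValueError("graph has no heavy atoms")
    heavy_set = set(heavy)
    adj = {i: sorted(j for j in nbrs if j in heavy_set)
           for i, nbrs in enumerate(g.adjacency()) if i in heavy_set}

    visited: set[int] = set()
    ring_bonds: dict[tuple[int, int], int] = {}
    ring_counter = [0]

    def assign_rings(start: int) -> None:
        # iterative DFS marking back-edges with ring-closure numbers
        stack = [(start, -1)]
        parent: dict[int, int] = {start: -1}
        order: list[int] = []
        while stack:
            node, par = stack.pop()
            if node in visited:
                continue
            visited.add(node)
            parent[node] = par
            order.append(node)
            for nbr in reversed(adj[node]):
                if nbr not in visited:
                    stack.append((nbr, node))
        tree_edges = {(min(n, p), max(n, p)) for n, p in parent.items() if p >= 0}
        for node in order:
            for nbr in adj[node]:
                e = (min(node, nbr), max(node, nbr))
                if e not in tree_edges and e not in ring_bonds:
                    ring_counter[0] += 1
                    ring_bonds[e] = ring_counter[0]

    def emit(node: int, par: int, done: set[int]) -> str:
        done.add(node)
        out = [_smiles_symbol(g.atoms[node])]
        for nbr in adj[node]:
            e = (min(node, nbr), max(node, nbr))
            if e in ring_bonds:
                num = ring_bonds[e]
                if nbr == par:
                    continue
                out.append(f"%{num:02d}" if num > 9 else str(num))
        ring_edges = {(min(node, n), max(node, n)) for n in adj[node]
                      if (min(node, n), max(node, n)) in ring_bonds}
        children = [n for n in adj[node] if n != par and n not in done
                    and (min(node, n), max(node, n)) not in ring_edges]
        for k, child in enumerate(children):
            if child in done:
                continue
            sub = emit(child, node, done)
            if k < len(children) - 1:
                out.append(f"({sub})")
            else:
                out.append(sub)
        return "".join(out)

    fragments = []
    for start in heavy:
        if start in visited:
            continue
        assign_rings(start)
        fragments.append(emit(start, -1, set()))
    return ".".join(fragments)


def from_smiles(smiles: str, component_id: str = "") -> MolecularGraph:
    """Parse connectivity-level SMILES (bracket atoms, organic subset,
    branches, ring closures, dots; bond symbols treated as single)."""
    atoms: list[str] = []
    bonds: list[tuple[int, int]] = []
    stack: list[int] = []
    rings: dict[str, int] = {}
    prev = -1
    i = 0
    s = smiles.strip()
    while i < len(s):
        c = s[i]
        if c == "(":
            stack.append(prev)
            i += 1
        elif c == ")":
            prev = stack.pop()
            i += 1
        elif c == ".":
            prev = -1
            i += 1
        elif c in "-=#:/\\":
            i += 1
        elif c == "[":
            end = s.index("]", i)
            body = s[i + 1:end]
            sym = "".join(ch for ch in body if ch.isalpha())
            atoms.append(sym.upper())
            if prev >= 0:
                bonds.append((prev, len(atoms) - 1))
            prev = len(atoms) - 1
            i = end + 1
        elif c == "%":
            label = s[i + 1:i + 3]
            _close_ring(label, prev, rings, bonds)
            i += 3
        elif c.isdigit():
            _close_ring(c, prev, rings, bonds)
            i += 1
        elif c.isalpha():
            sym = c
            if i + 1 < len(s) and c.upper() + s[i + 1].upper() in ("CL", "BR"):
                sym = s[i:i + 2]
                i += 1
            if sym.upper() not in _ORGANIC_SUBSET:
                raise ValueError(f"cannot parse atom symbol at {s[i:]!r}")
            atoms.append(sym.upper())
            if prev >= 0:
                bonds.append((prev, len(atoms) - 1))
            prev = len(atoms) - 1
            i += 1
        else:
            raise ValueError(f"unsupported SMILES token {c!r}")
    if rings:
        raise ValueError(f"unclosed ring labels: {sorted(rings)}")
    return MolecularGraph(atoms=atoms, bonds=bonds, component_id=component_id)


def _close_ring(label: str, prev: int, rings: dict[str, int],
                bonds: list[tuple[int, int]]) -> None:
    if prev < 0:
        raise ValueError("ring closure before any atom")
    if label in rings:
        bonds.append((rings.pop(label), prev))
    else:
        rings[label] = prev


def graph_from_atoms(atoms, component_id: str = "",
                     tolerance: float = 0.45) -> MolecularGraph:
    """Perceive a graph from pdb_io Atom objects (element + coordinates)."""
    return perceive_bonds([(a.element, a.coords) for a in atoms],
                          tolerance=tolerance, component_id=component_id)
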