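"""Synthetic PDB corpora with declared ground truth.

Generates parseable legacy-PDB complexes — a short polypeptide chain whose
residues sit at planted nearest-atom distances from a hetero group — plus a
machine-readable truth table (MTL status, cluster counts, site residue
sets, max conformer RMSD). Chains are chemically simplistic by design;
everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pdb_io import Atom, parse_structure, write_substructure
from .ligand_extract import LigandInstance
from .conf_analysis import kabsch_superpose

# one-letter -> three-letter for chain construction
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
# disjoint 6-letter alphabets per family => cross-family identity exactly 0
_FAMILY_ALPHABETS = ["ARNDCQ", "EGHILK", "MFPSTW"]

_BACKBONE_TEMPLATE = [
    ("N", "N", np.array([0.0, 0.0, 0.0])),
    ("CA", "C", np.array([1.46, 0.0, 0.0])),
    ("C", "C", np.array([2.02, 1.42, 0.0])),
    ("O", "O", np.array([3.25, 1.55, 0.0])),
]
_CLASH_LIMIT = 1.8


@dataclass
class ComplexSpec:
    """Geometry recipe for one synthetic protein-ligand complex."""

    structure_id: str
    resolution: float
    chain_id: str
    sequence: str
    residue_distances: list[float]      # planted nearest-atom distance per residue
    component_id: str
    n_heavy: int
    ligand_seq: int = 901
    experiment_method: str = "X-RAY DIFFRACTION"
    conformer_shift: float = 0.0        # planted RMSD vs the base conformer
    extra_hydrogens: int = 0


@dataclass
class FixtureSpec:
    """A whole corpus: structures plus planted identity/MTL relations."""

    seed: int
    complexes: list[ComplexSpec] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        raw = json.loads(text)
        return cls(seed=raw["seed"],
                   complexes=[ComplexSpec(**c) for c in raw["complexes"]])


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic well-spread unit vectors (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def ligand_template(component_id: str, n_heavy: int) -> list[tuple[str, str, np.ndarray]]:
    """Deterministic zigzag heavy-atom chain (~1.5 A bonds) with a couple
    of heteroatoms for descriptor variety. Returns (name, element, xyz)."""
    if n_heavy < 1:
        raise ValueError("n_heavy must be >= 1")
    atoms = []
    counts: dict[str, int] = {}
    for k in range(n_heavy):
        element = "C"
        if n_heavy >= 9:
            if k == 2:
                element = "N"
            elif k == 5:
                element = "O"
        pos = np.array([1.4 * k, 0.55 * (k % 2), 0.25 * ((k // 2) % 2)])
        counts[element] = counts.get(element, 0) + 1
        atoms.append((f"{element}{counts[element]}", element, pos))
    return atoms


def _ligand_base_coords(component_id: str, n_heavy: int) -> np.ndarray:
    return np.array([p for _, _, p in ligand_template(component_id, n_heavy)])


def perturb_coords(base: np.ndarray, planted_rmsd: float,
                   rng: np.random.Generator,
                   tol: float = 0.01) -> np.ndarray:
    """Coordinates whose optimal-superposition RMSD to ``base`` equals
    ``planted_rmsd`` within ``tol`` (orthogonal-complement displacement,
    then scale calibration)."""
    if planted_rmsd < 0:
        raise ValueError("planted_rmsd must be >= 0")
    n = base.shape[0]
    if planted_rmsd == 0:
        return base.copy()
    d = rng.normal(size=base.shape)
    d -= d.mean(axis=0)
    centered = base - base.mean(axis=0)
    # project out infinitesimal rotations so displacement survives superposition
    modes = []
    for axis in np.eye(3):
        m = np.cross(np.broadcast_to(axis, centered.shape), centered)
        norm = np.linalg.norm(m)
        if norm > 1e-9:
            modes.append(m / norm)
    for m in modes:
        d -= (d * m).sum() * m
    d /= math.sqrt((d ** 2).sum() / n)      # unit RMS displacement

    def measured(scale: float) -> float:
        return kabsch_superpose(base, base + scale * d).rmsd

    lo, hi = 0.0, planted_rmsd
    while measured(hi) < planted_rmsd:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = measured(mid)
        if abs(m - planted_rmsd) <= tol * 0.5:
            return base + mid * d
        if m < planted_rmsd:
            lo = mid
        else:
            hi = mid
    return base + 0.5 * (lo + hi) * d


def _rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    return coords @ rot.T + shift


def make_complex(entry: ComplexSpec, seed: int = 0) -> str:
    """One parseable PDB file honoring the entry's geometry to 0.01 A."""
    rng = np.random.default_rng((seed, hash(entry.structure_id) & 0xFFFF))
    template = ligand_template(entry.component_id, entry.n_heavy)
    lig_xyz = np.array([p for _, _, p in template])
    if entry.conformer_shift > 0:
        lig_xyz = perturb_coords(lig_xyz, entry.conformer_shift, rng, tol=0.01)

    n_res = len(entry.sequence)
    if len(entry.residue_distances) != n_res:
        raise ValueError("residue_distances must align with sequence")
    directions = _sphere_directions(max(n_res, 4))[:n_res]
    lig_center = lig_xyz.mean(axis=0)

    atoms: list[Atom] = []
    serial = 1
    for idx, (letter, target, u) in enumerate(
            zip(entry.sequence, entry.residue_distances, directions)):
        if target < _CLASH_LIMIT:
            raise ValueError(
                f"requested distance {target} below clash limit {_CLASH_LIMIT}")
        resname = ONE_TO_THREE.get(letter, "ALA")
        local = np.array([p for _, _, p in _BACKBONE_TEMPLATE])
        local = local - local.mean(axis=0)
        center = lig_center + u * (target + 1.5)
        for _ in range(80):
            res_xyz = local + center
            diff = res_xyz[:, None, :] - lig_xyz[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=2))
            err = dist.min() - target
            if abs(err) <= 0.005:
                break
            center = center - u * err
        res_xyz = local + center
        for (name, element, _), pos in zip(_BACKBONE_TEMPLATE, res_xyz):
            atoms.append(Atom(
                record_kind="polymer", serial=serial, name=name, alt_loc="",
                residue_name=resname, chain_id=entry.chain_id,
                residue_seq=idx + 1, insertion_code="",
                x=round(float(pos[0]), 3), y=round(float(pos[1]), 3),
                z=round(float(pos[2]), 3), occupancy=1.0, element=element,
            ))
            serial += 1
    for (name, element, _), pos in zip(template, lig_xyz):
        atoms.append(Atom(
            record_kind="hetero", serial=serial, name=name, alt_loc="",
            residue_name=entry.component_id, chain_id="L",
            residue_seq=entry.ligand_seq, insertion_code="",
            x=round(float(pos[0]), 3), y=round(float(pos[1]), 3),
            z=round(float(pos[2]), 3), occupancy=1.0, element=element,
        ))
        serial += 1
    for h in range(entry.extra_hydrogens):
        anchor = lig_xyz[h % len(lig_xyz)]
        pos = anchor + np.array([0.0, 0.0, 1.0])
        atoms.append(Atom(
            record_kind="hetero", serial=serial, name=f"H{h + 1}",
            alt_loc="", residue_name=entry.component_id, chain_id="L",
            residue_seq=entry.ligand_seq, insertion_code="",
            x=round(float(pos[0]), 3), y=round(float(pos[1]), 3),
            z=round(float(pos[2]), 3), occupancy=1.0, element="H",
        ))
        serial += 1

    header = (f"HEADER    SYNTHETIC COMPLEX                       01-JAN-13"
              f"   {entry.structure_id:<4}")
    lines = [
        header,
        f"EXPDTA    {entry.experiment_method}",
        f"REMARK   2 RESOLUTION.    {entry.resolution:.2f} ANGSTROMS.",
    ]
    body = write_substructure(atoms)
    return "\n".join(lines) + "\n" + body


def family_sequences(n_chains: int, n_families: int, seed: int,
                     length: int = 30,
                     mutations: int = 1) -> list[tuple[int, str]]:
    """(family_index, sequence) pairs with planted identity structure:
    within-family identity >= 100*(length-2*mutations)/length, cross-family
    identity exactly 0 (disjoint alphabets)."""
    if n_families > len(_FAMILY_ALPHABETS):
        raise ValueError("at most 3 families supported")
    rng = np.random.default_rng(seed)
    parents = []
    for f in range(n_families):
        alphabet = _FAMILY_ALPHABETS[f]
        parents.append("".join(rng.choice(list(alphabet), size=length)))
    out = []
    for i in range(n_chains):
        f = i % n_families
        seq = list(parents[f])
        alphabet = _FAMILY_ALPHABETS[f]
        for _ in range(mutations):
            pos = int(rng.integers(length))
            seq[pos] = alphabet[int(rng.integers(len(alphabet)))]
        out.append((f, "".join(seq)))
    return out


def make_ligand_instance(component_id: str, n_heavy: int,
                         source_structure_id: str = "BASE",
                         coords: np.ndarray | None = None) -> LigandInstance:
    """Standalone ligand instance (no protein), for conformer fixtures."""
    template = ligand_template(component_id, n_heavy)
    xyz = coords if coords is not None else np.array([p for _, _, p in template])
    atoms = [
        Atom(record_kind="hetero", serial=k + 1, name=name, alt_loc="",
             residue_name=component_id, chain_id="L", residue_seq=901,
             insertion_code="", x=float(p[0]), y=float(p[1]), z=float(p[2]),
             occupancy=1.0, element=element)
        for k, ((name, element, _), p) in enumerate(zip(template, xyz))
    ]
    return LigandInstance(component_id=component_id, chain_id="L",
                          residue_seq=901, insertion_code="", atoms=atoms,
                          heavy_atom_count=len(atoms),
                          source_structure_id=source_structure_id)


def make_conformer_pair(base: LigandInstance, planted_rmsd: float,
                        seed: int) -> LigandInstance:
    """A conformer whose optimal-superposition RMSD to ``base`` is
    ``planted_rmsd`` within 0.05 A, returned under a random rigid motion."""
    rng = np.random.default_rng(seed)
    xyz = np.array([a.coords for a in base.atoms])
    moved = perturb_coords(xyz, planted_rmsd, rng) if planted_rmsd > 0 else xyz.copy()
    moved = _rigid_motion(moved, rng)
    atoms = [
        Atom(record_kind=a.record_kind, serial=a.serial, name=a.name,
             alt_loc=a.alt_loc, residue_name=a.residue_name,
             chain_id=a.chain_id, residue_seq=a.residue_seq,
             insertion_code=a.insertion_code, x=float(p[0]), y=float(p[1]),
             z=float(p[2]), occupancy=a.occupancy, element=a.element)
        for a, p in zip(base.atoms, moved)
    ]
    return LigandInstance(component_id=base.component_id,
                          chain_id=base.chain_id, residue_seq=base.residue_seq,
                          insertion_code=base.insertion_code, atoms=atoms,
                          heavy_atom_count=base.heavy_atom_count,
                          source_structure_id=base.source_structure_id + "'")


@dataclass
class ComponentPlan:
    component_id: str
    n_heavy: int
    partner_families: list[int]      # family index per partner structure
    conformer_shifts: list[float] | None = None
    resolutions: list[float] | None = None


def build_corpus_spec(seed: int, plans: list[ComponentPlan],
                      n_residues: int = 10,
                      contact_distances: tuple[float, ...] = (3.5, 4.0, 4.5,
                                                              5.0, 5.5, 5.9),
                      identity_threshold: float = 35.0) -> tuple[FixtureSpec, dict]:
    """Expand component plans into a FixtureSpec plus its truth table."""
    rng = np.random.default_rng(seed)
    n_families = max((max(p.partner_families) + 1 for p in plans), default=1)
    total_chains = sum(len(p.partner_families) for p in plans)
    seqs = family_sequences(total_chains * 2, min(n_families, 3), seed + 7)
    by_family: dict[int, list[str]] = {}
    for fam, seq in seqs:
        by_family.setdefault(fam, []).append(seq)

    complexes: list[ComplexSpec] = []
    truth: dict = {"seed": seed, "identity_threshold": identity_threshold,
                   "components": {}}
    sid = 0
    used: dict[int, int] = {}
    for plan in plans:
        shifts = plan.conformer_shifts or [0.0] * len(plan.partner_families)
        resolutions = plan.resolutions or [
            round(float(rng.uniform(1.2, 2.8)), 2)
            for _ in plan.partner_families]
        structure_ids = []
        for fam, shift, res in zip(plan.partner_families, shifts, resolutions):
            k = used.get(fam, 0)
            used[fam] = k + 1
            seq = by_family[fam][k % len(by_family[fam])][:n_residues]
            distances = [contact_distances[i % len(contact_distances)]
                         if i < max(6, n_residues - 2) else 8.0 + i
                         for i in range(n_residues)]
            structure_id = f"Z{sid:03d}"
            sid += 1
            structure_ids.append(structure_id)
            complexes.append(ComplexSpec(
                structure_id=structure_id, resolution=res, chain_id="A",
                sequence=seq, residue_distances=distances,
                component_id=plan.component_id, n_heavy=plan.n_heavy,
                conformer_shift=shift,
            ))
        families = sorted(set(plan.partner_families))
        qualifying = [cx for cx in complexes
                      if cx.component_id == plan.component_id
                      and cx.resolution < 3.0]
        q_families = sorted({
            fam for fam, cx in zip(plan.partner_families,
                                   complexes[-len(plan.partner_families):])
            if cx.resolution < 3.0})
        n_q = len(qualifying)
        planted = [cx.residue_distances for cx in
                   complexes[-len(plan.partner_families):]]
        truth["components"][plan.component_id] = {
            "expected_site_residue_counts": [
                sum(1 for d in dists if d <= 6.0) for dists in planted],
            "structure_ids": structure_ids,
            "n_structures": len(structure_ids),
            "n_qualifying_structures": n_q,
            "n_families": len(families),
            "expected_cluster_count": len(q_families),
            "in_database": n_q >= 2,
            "is_mtl": n_q >= 2 and len(q_families) >= 2,
            "filtration_off_count": n_q,
        }
    return FixtureSpec(seed=seed, complexes=complexes), truth


def make_corpus(spec: FixtureSpec, out_dir: str | Path,
                truth: dict | None = None) -> dict:
    """Write all structures of a spec (plus truth table) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    measured_rmsd: dict[str, dict[str, float]] = {}
    per_component: dict[str, list[np.ndarray]] = {}
    for entry in spec.complexes:
        if entry.structure_id in seen:
            raise ValueError(f"duplicate structure_id {entry.structure_id}")
        seen.add(entry.structure_id)
        text = make_complex(entry, seed=spec.seed)
        (out / f"{entry.structure_id}.pdb").write_text(text)
        s = parse_structure(text)
        het = [a for a in s.hetero_atoms()
               if a.residue_name == entry.component_id]
        if entry.resolution < 3.0:
            per_component.setdefault(entry.component_id, []).append(
                np.array([a.coords for a in het]))
    for comp, confs in per_component.items():
        if len(confs) < 2:
            continue
        max_r = 0.0
        for i in range(len(confs)):
            for j in range(i + 1, len(confs)):
                max_r = max(max_r, kabsch_superpose(confs[i], confs[j]).rmsd)
        measured_rmsd[comp] = {"max_rmsd": round(max_r, 4)}
    table = dict(truth or {})
    if "components" in table:
        for comp, info in table["components"].items():
            if comp in measured_rmsd:
                info["expected_max_rmsd"] = measured_rmsd[comp]["max_rmsd"]
    table["structure_files"] = sorted(f"{c.structure_id}.pdb"
                                      for c in spec.complexes)
    (out / "truth.json").write_text(json.dumps(table, indent=1, sort_keys=True))
    (out / "fixture_spec.json").write_text(spec.to_json())
    return table


def random_corpus(seed: int, out_dir: str | Path,
                  n_components: int | None = None) -> dict:
    """A seeded random corpus (6-40 structures) with declared MTL truth."""
    rng = np.random.default_rng(seed)
    if n_components is None:
        n_components = int(rng.integers(2, 5))
    plans = []
    for c in range(n_components):
        n_partners = int(rng.integers(1, 6))
        n_fam = int(rng.integers(1, 4))
        families = [int(rng.integers(n_fam)) for _ in range(n_partners)]
        resolutions = [round(float(rng.uniform(1.2, 2.8)), 2)
                       for _ in range(n_partners)]
        if n_partners >= 3 and rng.random() < 0.4:
            resolutions[0] = round(float(rng.uniform(3.0, 4.0)), 2)  # gated out
        shifts = [0.0] + [round(float(rng.uniform(0.0, 2.8)), 2)
                          for _ in range(n_partners - 1)]
        plans.append(ComponentPlan(
            component_id=f"L{c:02d}", n_heavy=int(rng.integers(9, 16)),
            partner_families=families, conformer_shifts=shifts,
            resolutions=resolutions,
        ))
    spec, truth = build_corpus_spec(seed, plans)
    return make_corpus(spec, out_dir, truth)
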