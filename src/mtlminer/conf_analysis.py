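"""Conformational variability of a ligand across its complexes.

Heavy atoms are matched by name, superposed with the closed-form
least-squares (Kabsch) rigid motion, and the pairwise RMSD matrix is
summarized by its maximum; a ligand is "rigid" when max RMSD <= 2.0 A
(inclusive), else "flexible".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ligand_extract import LigandInstance


@dataclass
class Superposition:
    rotation: np.ndarray        # 3x3 proper rotation (det +1)
    translation: np.ndarray     # 3-vector, Angstrom
    rmsd: float
    matched_atom_count: int


def match_atoms(a: LigandInstance, b: LigandInstance) -> list[tuple[int, int]]:
    """Heavy-atom index pairs matched by identical atom name.

    Indices refer to each instance's full atom list; order follows a's
    atoms. Duplicate names pair in order of occurrence. Raises
    ``ValueError`` when the instances share different components or fewer
    than 3 matched atoms (superposition under-determined).
    """
    if a.component_id != b.component_id:
        raise ValueError("cannot match atoms across different components")
    b_by_name: dict[str, list[int]] = {}
    for j, atom in enumerate(b.atoms):
        if atom.element in ("H", "D"):
            continue
        b_by_name.setdefault(atom.name, []).append(j)
    pairs: list[tuple[int, int]] = []
    used: dict[str, int] = {}
    for i, atom in enumerate(a.atoms):
        if atom.element in ("H", "D"):
            continue
        candidates = b_by_name.get(atom.name, [])
        k = used.get(atom.name, 0)
        if k < len(candidates):
            pairs.append((i, candidates[k]))
            used[atom.name] = k + 1
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} matched atoms; superposition under-determined")
    return pairs


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Optimal proper rigid motion mapping b onto a, with residual RMSD.

    Solves min over rotation R (det +1) and translation t of
    ||a - (R b + t)||; degenerate point sets still return a valid
    minimizer. NaN coordinates raise ``ValueError``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must share shape (N, 3)")
    if a.shape[0] < 3:
        raise ValueError("at least 3 points required")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ca - rotation @ cb
    moved = b0 @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((a0 - moved) ** 2, axis=1))))
    return Superposition(rotation=rotation, translation=translation,
                         rmsd=rmsd, matched_atom_count=a.shape[0])


def instance_rmsd(a: LigandInstance, b: LigandInstance) -> float:
    pairs = match_atoms(a, b)
    xa = np.array([a.atoms[i].coords for i, _ in pairs])
    xb = np.array([b.atoms[j].coords for _, j in pairs])
    return kabsch_superpose(xa, xb).rmsd


@dataclass
class ConformerReport:
    component_id: str
    conformer_keys: list[tuple]
    pairwise_rmsd: np.ndarray        # NaN for unmatchable pairs
    max_rmsd: float | None
    flexibility_class: str           # "rigid" | "flexible" | "undetermined"
    missing_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "conformer_keys": [list(k) for k in self.conformer_keys],
            "pairwise_rmsd": [
                [None if math.isnan(v) else round(float(v), 6) for v in row]
                for row in self.pairwise_rmsd
            ],
            "max_rmsd": None if self.max_rmsd is None
            else round(float(self.max_rmsd), 6),
            "flexibility_class": self.flexibility_class,
        }


def conformer_report(instances: list[LigandInstance],
                     class_cutoff: float = 2.0) -> ConformerReport:
    """Full pairwise RMSD matrix over >=2 instances of one component.

    Pairs that cannot be matched are excluded from the maximum; with no
    matchable pair the class is "undetermined".
    """
    if len(instances) < 2:
        raise ValueError("need at least 2 instances of one component")
    component = instances[0].component_id
    n = len(instances)
    matrix = np.full((n, n), np.nan)
    np.fill_diagonal(matrix, 0.0)
    missing: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = instance_rmsd(instances[i], instances[j])
            except ValueError:
                missing.append((i, j))
                continue
            matrix[i, j] = matrix[j, i] = r
    upper = matrix[np.triu_indices(n, k=1)]
    finite = upper[np.isfinite(upper)]
    if finite.size == 0:
        max_rmsd: float | None = None
        flex = "undetermined"
    else:
        max_rmsd = float(finite.max())
        flex = "rigid" if max_rmsd <= class_cutoff else "flexible"
    return ConformerReport(
        component_id=component,
        conformer_keys=[inst.instance_key for inst in instances],
        pairwise_rmsd=matrix, max_rmsd=max_rmsd, flexibility_class=flex,
        missing_pairs=missing,
    )
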