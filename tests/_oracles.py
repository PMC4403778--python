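"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: pure-Python distance
scans, a hand-rolled affine-gap dynamic program, a rotational grid +
simplex-refinement superposition optimizer, exhaustive path enumeration
and formula-based molecular weights.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def gotoh_global(a: str, b: str, gap_open: float = 10.0,
                 gap_extend: float = 0.5):
    """Affine-gap global alignment (end gaps penalized).

    Gap of length L costs open + (L-1)*extend, matching the package's
    stated scoring convention. Returns (score, n_identical, n_aligned).
    """
    n, m = len(a), len(b)
    sub = lambda x, y: float(_BLOSUM62[x][y])
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]   # gap in b
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]   # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + sub(a[i - 1], b[j - 1])
            Ix[i][j] = max(M[i - 1][j] - gap_open,
                           Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - gap_open)
            Iy[i][j] = max(M[i][j - 1] - gap_open,
                           Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - gap_open)
    score = max(M[n][m], Ix[n][m], Iy[n][m])

    # traceback for identity count
    state = max(((M[n][m], "M"), (Ix[n][m], "X"), (Iy[n][m], "Y")))[1]
    i, j = n, m
    ident = aligned = 0
    while i > 0 or j > 0:
        if state == "M":
            aligned += 1
            if a[i - 1] == b[j - 1]:
                ident += 1
            prev = max(((M[i - 1][j - 1], "M"), (Ix[i - 1][j - 1], "X"),
                        (Iy[i - 1][j - 1], "Y")))
            i, j = i - 1, j - 1
            state = prev[1] if (i > 0 or j > 0) else "M"
        elif state == "X":
            cands = [(M[i - 1][j] - 10.0, "M"), (Ix[i - 1][j] - 0.5, "X"),
                     (Iy[i - 1][j] - 10.0, "Y")]
            val = Ix[i][j]
            state = next(s for v, s in cands if math.isclose(v, val))
            i -= 1
        else:
            cands = [(M[i][j - 1] - 10.0, "M"), (Iy[i][j - 1] - 0.5, "Y"),
                     (Ix[i][j - 1] - 10.0, "X")]
            val = Iy[i][j]
            state = next(s for v, s in cands if math.isclose(v, val))
            j -= 1
    return score, ident, aligned


def identity_oracle(a: str, b: str) -> float:
    _score, ident, _cols = gotoh_global(a, b)
    return 100.0 * ident / min(len(a), len(b))


def site_residues_bruteforce(structure, ligand, radius: float,
                             nucleic: frozenset | set = frozenset()) -> set:
    """Pure-Python all-pairs scan: residue keys of amino-acid polymer
    residues with any atom within ``radius`` of any ligand atom."""
    lig_coords = [at.coords for at in ligand.atoms]
    members = set()
    for atom in structure.atoms:
        if atom.record_kind != "polymer" or atom.residue_name in nucleic:
            continue
        ax, ay, az = atom.coords
        for lx, ly, lz in lig_coords:
            d = math.sqrt((ax - lx) ** 2 + (ay - ly) ** 2 + (az - lz) ** 2)
            if d <= radius:
                members.add(atom.residue_key)
                break
    return members


def rmsd_for_rotation(rotvec: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    rot = Rotation.from_rotvec(rotvec).as_matrix()
    moved = (b - b.mean(axis=0)) @ rot.T
    target = a - a.mean(axis=0)
    return math.sqrt(np.mean(np.sum((target - moved) ** 2, axis=1)))


def rmsd_oracle(a: np.ndarray, b: np.ndarray, n_grid: int = 800,
                seed: int = 0) -> float:
    """Brute-force rotational grid + local simplex refinement."""
    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rotvecs = Rotation.from_quat(quats).as_rotvec()
    values = [rmsd_for_rotation(v, a, b) for v in rotvecs]
    best = rotvecs[int(np.argmin(values))]
    res = minimize(rmsd_for_rotation, best, args=(a, b),
                   method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000,
                            "maxfev": 20000})
    return float(res.fun)


def enumerate_paths_bruteforce(elements: list[str],
                               bonds: list[tuple[int, int]],
                               max_len: int) -> set[tuple[str, ...]]:
    """All simple heavy-atom paths by exhaustive vertex-sequence search."""
    heavy = [i for i, el in enumerate(elements) if el.upper() not in ("H", "D")]
    adj = set()
    for i, j in bonds:
        adj.add((i, j))
        adj.add((j, i))
    found = set()
    for length in range(1, max_len + 1):
        for seq in itertools.permutations(heavy, length):
            if all((seq[k], seq[k + 1]) in adj for k in range(length - 1)):
                els = tuple(elements[i].upper() for i in seq)
                found.add(min(els, els[::-1]))
    return found


ATOMIC_WEIGHTS_IUPAC = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904,
}


def formula_weight(formula_counts: dict[str, int]) -> float:
    return sum(ATOMIC_WEIGHTS_IUPAC[el.upper()] * n
               for el, n in formula_counts.items())
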