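"""Pairwise sequence identity and single-linkage target clustering.

Identity is computed from a global (end-gap-penalized) alignment —
BLOSUM62, gap open -10, gap extend -0.5 (the open score applies to the
first position of a gap) — as 100 x identical positions / shorter
sequence length. Two chains are redundant when identity >= threshold
(35.0% exactly is redundant); clusters are the connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

ChainKey = tuple[str, str]   # (structure_id, chain_id)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ALPHABET = set(str(_BLOSUM62.alphabet))


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str) -> str:
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq.upper())


def pairwise_identity(seq_a: str, seq_b: str, gap_open: float = 10.0,
                      gap_extend: float = 0.5,
                      denominator: str = "shorter") -> float:
    """Percent identity in [0, 100] between two protein sequences.

    ``denominator`` is "shorter" (default) or "alignment".
    Raises ``ValueError`` on an empty sequence.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = _sanitize(seq_a), _sanitize(seq_b)
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_cols += a1 - a0
        matches += sum(1 for i in range(a1 - a0) if a[a0 + i] == b[b0 + i])
    if denominator == "shorter":
        denom = min(len(a), len(b))
    elif denominator == "alignment":
        denom = len(aln[0])
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * matches / denom if denom else 0.0


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over an ordered chain-key list."""

    chain_keys: list[ChainKey]
    values: np.ndarray

    def to_tsv(self) -> str:
        header = "\t" + "\t".join("_".join(k) for k in self.chain_keys)
        lines = [header]
        for i, key in enumerate(self.chain_keys):
            row = "\t".join(f"{v:.1f}" for v in self.values[i])
            lines.append(f"{'_'.join(key)}\t{row}")
        return "\n".join(lines) + "\n"


def identity_matrix(chains: list[tuple[ChainKey, str]], **kwargs) -> IdentityMatrix:
    n = len(chains)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = 100.0 if chains[i][1] else 0.0
        for j in range(i + 1, n):
            pid = pairwise_identity(chains[i][1], chains[j][1], **kwargs)
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(chain_keys=[k for k, _ in chains], values=values)


@dataclass
class TargetCluster:
    """Chains collapsed under the identity threshold (single linkage)."""

    members: list[ChainKey]
    representative: ChainKey


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_targets(chains: list[tuple[ChainKey, str]],
                    threshold: float = 35.0, **kwargs) -> list[TargetCluster]:
    """Single-linkage clusters: chains linked iff identity >= threshold.

    Output is deterministic and order-independent: members sorted by key,
    clusters sorted by representative key.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    order = sorted(range(len(chains)), key=lambda i: chains[i][0])
    chains = [chains[i] for i in order]
    n = len(chains)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if chains[i][1] == chains[j][1]:
                uf.union(i, j)
                continue
            if pairwise_identity(chains[i][1], chains[j][1], **kwargs) >= threshold:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for idxs in groups.values():
        members = sorted(chains[i][0] for i in idxs)
        rep = min(((-len(chains[i][1]), chains[i][0]) for i in idxs))[1]
        clusters.append(TargetCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.representative)
    return clusters


def nonredundant_target_count(chains: list[tuple[ChainKey, str]],
                              threshold: float = 35.0,
                              filtration_enabled: bool = True) -> int:
    """Number of non-redundant targets among a ligand's primary binding
    chains: cluster count when filtration is on, else the number of
    distinct chain keys (the full list)."""
    unique: dict[ChainKey, str] = {}
    for key, seq in chains:
        unique.setdefault(key, seq)
    if not filtration_enabled:
        return len(unique)
    return len(cluster_targets(sorted(unique.items()), threshold=threshold))


def clusters_to_tsv(clusters: list[TargetCluster]) -> str:
    lines = ["chain_key\tcluster_id"]
    for cid, cluster in enumerate(clusters):
        for member in cluster.members:
            lines.append(f"{'_'.join(member)}\t{cid}")
    return "\n".join(lines) + "\n"
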