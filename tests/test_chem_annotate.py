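import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem, RDLogger
from rdkit.Chem import Lipinski as RDLipinski
from rdkit.Chem import Descriptors as RDDescriptors

from mtlminer.chem_annotate import (Fingerprint, MolecularGraph, from_smiles,
                                    lipinski, molecular_weight,
                                    path_fingerprint, perceive_bonds,
                                    similarity_search, tanimoto, to_smiles,
                                    enumerate_paths)

from _oracles import enumerate_paths_bruteforce, formula_weight

RDLogger.DisableLog("rdApp.*")


def random_molecule(rng, n_heavy, add_h=True):
    """Random valence-sane tree molecule (explicit hydrogens fill valence)."""
    max_valence = {"C": 4, "N": 3, "O": 2}
    elements = [str(rng.choice(["C", "C", "C", "N", "O"]))
                for _ in range(n_heavy)]
    bonds = []
    degree = [0] * n_heavy
    for i in range(1, n_heavy):
        candidates = [j for j in range(i)
                      if degree[j] < max_valence[elements[j]]]
        if not candidates:
            candidates = [i - 1]
        j = int(rng.choice(candidates))
        bonds.append((j, i))
        degree[j] += 1
        degree[i] += 1
    atoms = list(elements)
    if add_h:
        for i in range(n_heavy):
            for _ in range(max_valence[elements[i]] - degree[i]):
                atoms.append("H")
                bonds.append((i, len(atoms) - 1))
    return MolecularGraph(atoms=atoms, bonds=bonds)


def to_rdkit(g: MolecularGraph):
    mol = Chem.RWMol()
    for el in g.atoms:
        atom = Chem.Atom(el.capitalize())
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i, j in g.bonds:
        mol.AddBond(i, j, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def aspirin_graph():
    """Aspirin (C9H8O4) topology with explicit hydrogens, bond orders
    flattened to connectivity."""
    atoms = (["C"] * 6            # ring C0..C5
             + ["C", "O", "O"]    # C6(=O7)(O8-H)
             + ["O", "C", "O", "C"]   # O9-C10(=O11)-C12
             + ["H"] * 8)
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
             (0, 6), (6, 7), (6, 8),
             (1, 9), (9, 10), (10, 11), (10, 12),
             (8, 13),                        # carboxylic O-H
             (2, 14), (3, 15), (4, 16), (5, 17),   # ring H
             (12, 18), (12, 19), (12, 20)]         # methyl H
    return MolecularGraph(atoms=atoms, bonds=bonds, component_id="ASP")


class TestPerceiveBonds:
    def test_cc_standard_length(self):
        g = perceive_bonds([("C", (0, 0, 0)), ("C", (1.54, 0, 0))])
        assert g.bonds == [(0, 1)]

    def test_cc_beyond_tolerance(self):
        g = perceive_bonds([("C", (0, 0, 0)), ("C", (3.0, 0, 0))])
        assert g.bonds == []

    def test_benzene_ring_topology(self):
        r = 1.39
        atoms = [("C", (r * math.cos(k * math.pi / 3),
                        r * math.sin(k * math.pi / 3), 0.0))
                 for k in range(6)]
        g = perceive_bonds(atoms)
        assert len(g.bonds) == 6
        degrees = [0] * 6
        for i, j in g.bonds:
            degrees[i] += 1
            degrees[j] += 1
        assert degrees == [2] * 6       # a single 6-cycle

    def test_hydrogen_bonds_single_nearest_heavy(self):
        g = perceive_bonds([("C", (0, 0, 0)), ("C", (1.5, 0, 0)),
                            ("H", (0.74, 0.8, 0))])   # near both carbons
        h_bonds = [b for b in g.bonds if 2 in b]
        assert len(h_bonds) == 1

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="XX"):
            perceive_bonds([("XX", (0, 0, 0))])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            perceive_bonds([])


class TestMolecularWeight:
    def test_single_carbon(self):
        assert molecular_weight(MolecularGraph(["C"], [])) == \
            pytest.approx(12.011)

    def test_formula_oracle(self, rng):
        for _ in range(20):
            g = random_molecule(rng, int(rng.integers(3, 15)))
            counts = {}
            for el in g.atoms:
                counts[el] = counts.get(el, 0) + 1
            assert molecular_weight(g) == pytest.approx(
                formula_weight(counts), abs=0.01)

    def test_rdkit_oracle(self, rng):
        for _ in range(10):
            g = random_molecule(rng, int(rng.integers(3, 12)))
            assert molecular_weight(g) == pytest.approx(
                RDDescriptors.MolWt(to_rdkit(g)), abs=0.05)


class TestLipinski:
    def test_forced_two_violations(self):
        # 42 carbons (MW ~504) + 6 N-H donors -> MW and HBD violations
        atoms = ["C"] * 42 + ["N", "H"] * 6
        bonds = [(i, i + 1) for i in range(41)]
        base = 42
        for k in range(6):
            bonds.append((k, base + 2 * k))
            bonds.append((base + 2 * k, base + 2 * k + 1))
        d = lipinski(MolecularGraph(atoms=atoms, bonds=bonds))
        assert d.molecular_weight > 500
        assert d.hbd == 6
        assert d.lipinski_violations == 2
        assert not d.druglike

    def test_aspirin_fixture_against_rdkit(self):
        g = aspirin_graph()
        d = lipinski(g)
        mol = to_rdkit(g)
        assert d.molecular_weight == pytest.approx(180.16, abs=0.01)
        assert d.hbd == RDLipinski.NHOHCount(mol) == 1
        assert d.hba == RDLipinski.NOCount(mol) == 4
        assert d.lipinski_violations == 0
        assert d.druglike

    def test_all_carbon_no_heteroatoms(self):
        g = MolecularGraph(["C"] * 10, [(i, i + 1) for i in range(9)])
        d = lipinski(g)
        assert d.hbd == 0 and d.hba == 0

    def test_rdkit_oracle_random_molecules(self, rng):
        for _ in range(20):
            g = random_molecule(rng, int(rng.integers(3, 15)))
            mol = to_rdkit(g)
            d = lipinski(g)
            assert d.hbd == RDLipinski.NHOHCount(mol)
            assert d.hba == RDLipinski.NOCount(mol)

    def test_imputed_donors_without_explicit_h(self):
        # H-stripped ethanolamine: N-C-C-O; N imputes 2, O imputes 1
        g = MolecularGraph(["N", "C", "C", "O"], [(0, 1), (1, 2), (2, 3)])
        assert lipinski(g).hbd == 3

    def test_logp_provider_criterion(self):
        g = MolecularGraph(["C"] * 5, [(i, i + 1) for i in range(4)])
        assert lipinski(g).logp is None
        d = lipinski(g, logp_provider=lambda _g: 6.2)
        assert d.logp == pytest.approx(6.2)
        assert d.lipinski_violations == 1

    def test_mw_monotonicity_above_500(self, rng):
        g_small = MolecularGraph(["C"] * 10, [(i, i + 1) for i in range(9)])
        g_large = MolecularGraph(["C"] * 50, [(i, i + 1) for i in range(49)])
        assert lipinski(g_large).lipinski_violations >= \
            lipinski(g_small).lipinski_violations


class TestPathFingerprint:
    def test_single_atom_single_bit(self):
        fp = path_fingerprint(MolecularGraph(["C"], []))
        assert fp.n_set == 1

    def test_cno_path_enumeration(self):
        g = MolecularGraph(["C", "N", "O"], [(0, 1), (1, 2)])
        paths = enumerate_paths(g, 7)
        assert paths == {("C",), ("N",), ("O",),
                         ("C", "N"), ("N", "O"), ("C", "N", "O")}
        assert path_fingerprint(g).n_set <= 6

    def test_exhaustive_oracle_on_tiny_graphs(self, rng):
        for _ in range(15):
            g = random_molecule(rng, int(rng.integers(2, 7)), add_h=False)
            assert enumerate_paths(g, 4) == enumerate_paths_bruteforce(
                g.atoms, g.bonds, 4)

    def test_reindexing_invariance(self, rng):
        g = random_molecule(rng, 10)
        fp = path_fingerprint(g)
        for _ in range(25):
            perm = rng.permutation(len(g.atoms))
            inv = np.argsort(perm)
            atoms = [g.atoms[perm[i]] for i in range(len(g.atoms))]
            bonds = [(int(inv[i]), int(inv[j])) for i, j in g.bonds]
            assert path_fingerprint(MolecularGraph(atoms, bonds)).bits == fp.bits

    def test_hydrogens_excluded_from_paths(self):
        bare = MolecularGraph(["C", "C"], [(0, 1)])
        with_h = MolecularGraph(["C", "C", "H"], [(0, 1), (0, 2)])
        assert path_fingerprint(bare).bits == path_fingerprint(with_h).bits

    def test_hex_roundtrip(self, rng):
        fp = path_fingerprint(random_molecule(rng, 12))
        assert Fingerprint.from_hex(fp.to_hex()).bits == fp.bits


class TestTanimoto:
    def fp(self, bits, n=1024):
        return Fingerprint(bits=frozenset(bits), n_bits=n)

    def test_identical(self):
        assert tanimoto(self.fp({1, 5, 9}), self.fp({1, 5, 9})) == 1.0

    def test_disjoint(self):
        assert tanimoto(self.fp({1, 2}), self.fp({3, 4})) == 0.0

    def test_partial_overlap(self):
        assert tanimoto(self.fp({1, 2, 3}), self.fp({2, 3, 4})) == 0.5

    def test_both_empty(self):
        assert tanimoto(self.fp(set()), self.fp(set())) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(self.fp({1}), self.fp({1}, n=512))

    @settings(max_examples=50, deadline=None)
    @given(a=st.sets(st.integers(0, 1023), max_size=60),
           b=st.sets(st.integers(0, 1023), max_size=60))
    def test_bounds_and_symmetry(self, a, b):
        fa, fb = self.fp(a), self.fp(b)
        t = tanimoto(fa, fb)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(fb, fa)
        assert tanimoto(fa, fa) == 1.0


class TestSimilaritySearch:
    def make_db(self, rng, n=6):
        db = []
        for k in range(n):
            g = random_molecule(rng, 8 + k)
            db.append((f"L{k:02d}", path_fingerprint(g)))
        return db

    def test_self_hit_first(self, rng):
        g = random_molecule(rng, 9)
        db = [("SELF", path_fingerprint(g))] + self.make_db(rng)
        hits = similarity_search(g, db, cutoff=0.0)
        assert hits[0] == ("SELF", 1.0)

    def test_strict_cutoff_empty(self, rng):
        db = self.make_db(rng)
        query = random_molecule(rng, 20)
        hits = similarity_search(query, db, cutoff=1.0)
        assert all(score == 1.0 for _c, score in hits)

    def test_zero_cutoff_returns_all(self, rng):
        db = self.make_db(rng)
        assert len(similarity_search(random_molecule(rng, 9), db, 0.0)) == len(db)

    def test_hit_set_shrinks_with_cutoff(self, rng):
        db = self.make_db(rng, n=10)
        query = random_molecule(rng, 10)
        sizes = [len(similarity_search(query, db, c))
                 for c in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestSmiles:
    def test_single_oxygen(self):
        assert to_smiles(MolecularGraph(["O"], [])) == "[O]"

    def test_cco_contract(self):
        g = MolecularGraph(["C", "C", "O"], [(0, 1), (1, 2)])
        mol = Chem.MolFromSmiles(to_smiles(g))
        assert mol.GetNumAtoms() == 3
        assert mol.GetNumBonds() == 2

    def test_disconnected_dot_fragments(self):
        g = MolecularGraph(["C", "O"], [])
        assert to_smiles(g) == "[C].[O]"

    def test_ring_roundtrip(self):
        ring = MolecularGraph(["C"] * 6,
                              [(i, (i + 1) % 6) for i in range(6)])
        mol = Chem.MolFromSmiles(to_smiles(ring))
        assert mol.GetNumAtoms() == 6
        assert mol.GetNumBonds() == 6

    def test_roundtrip_random_graphs_via_rdkit(self, rng):
        for _ in range(50):
            g = random_molecule(rng, int(rng.integers(2, 14)))
            smiles = to_smiles(g)
            mol = Chem.MolFromSmiles(smiles)
            assert mol is not None, smiles
            heavy = [el for el in g.atoms if el != "H"]
            assert mol.GetNumAtoms() == len(heavy)
            heavy_bonds = [(i, j) for i, j in g.bonds
                           if g.atoms[i] != "H" and g.atoms[j] != "H"]
            assert mol.GetNumBonds() == len(heavy_bonds)
            assert sorted(a.GetSymbol().upper() for a in mol.GetAtoms()) == \
                sorted(heavy)

    def test_own_parser_roundtrip(self, rng):
        for _ in range(20):
            g = random_molecule(rng, int(rng.integers(2, 12)), add_h=False)
            back = from_smiles(to_smiles(g))
            assert sorted(back.atoms) == sorted(g.atoms)
            assert len(back.bonds) == len(g.bonds)

    def test_from_smiles_organic_subset(self):
        g = from_smiles("CC(N)O")
        assert sorted(g.atoms) == ["C", "C", "N", "O"]
        assert len(g.bonds) == 3
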