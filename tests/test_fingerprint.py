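"""Fingerprint engine tests, including the independent brute-force
environment enumerator oracle and an RDKit cross-check."""

import numpy as np
import pytest

from bitterfp.fingerprint import (
    ecfp,
    initial_identifiers,
    similarity_matrix,
    tanimoto,
)
from bitterfp.molecule_io import Atom, Bond, Molecule, read_smiles
from bitterfp.synthetic_fixtures import FixtureSpec, generate_library
from conftest import make_molecule


# ---------------------------------------------------------------------------
# Independent oracle: brute-force BFS environment enumeration.
# Enumerates every atom-centered environment per radius as (atom set, bond
# set) and applies the duplicate rule (earlier radius wins; radius-0
# environments deduplicate by invariant tuple) without any hashing.
# ---------------------------------------------------------------------------

def _invariant_tuple(mol, atom):
    degree = sum(1 for b in mol.bonds if atom.index in (b.a, b.b))
    return (atom.element, degree, atom.attached_h, atom.formal_charge,
            atom.in_ring, atom.sybyl_type)


def brute_force_environments(mol, n_iter):
    """Retained environments as a set of (radius, atom frozenset, bond
    frozenset) plus the retained radius-0 invariant tuples."""
    # all-pairs shortest path by BFS
    adj = {a.index: [] for a in mol.atoms}
    for b in mol.bonds:
        adj[b.a].append(b.b)
        adj[b.b].append(b.a)

    def bfs(start):
        dist = {start: 0}
        queue = [start]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist

    retained = set()
    r0_invariants = set()
    seen_bond_sets = set()
    for atom in mol.atoms:
        inv = _invariant_tuple(mol, atom)
        if inv not in r0_invariants:
            r0_invariants.add(inv)
            retained.add((0, frozenset([atom.index]), frozenset()))
    for r in range(1, n_iter + 1):
        for atom in mol.atoms:
            dist = bfs(atom.index)
            atoms_r = frozenset(i for i, d in dist.items() if d <= r)
            bonds_r = frozenset(
                b.key for b in mol.bonds
                if b.a in atoms_r and b.b in atoms_r
                and min(dist[b.a], dist[b.b]) <= r - 1
            )
            if not bonds_r or bonds_r in seen_bond_sets:
                continue
            seen_bond_sets.add(bonds_r)
            retained.add((r, atoms_r, bonds_r))
    return retained


def engine_environments(mol, diameter, k=2048):
    fp = ecfp(mol, diameter=diameter, k=k)
    return {
        (rec.radius, rec.atom_set, rec.bond_set) for rec in fp.records
    }


class TestInitialIdentifiers:
    def test_symmetry_equivalent_atoms_share_identifier(self, propane):
        ids = initial_identifiers(propane)
        assert ids[0] == ids[2]
        assert ids[0] != ids[1]

    def test_ethanol_carbons_differ(self, ethanol):
        ids = initial_identifiers(ethanol)
        assert ids[0] != ids[1]

    def test_permutation_leaves_identifier_multiset(self, ethanol):
        spec = ([("O", "O.3", 1), ("C", "C.3", 2), ("C", "C.3", 3)],
                [(0, 1, "single"), (1, 2, "single")])
        permuted = make_molecule("p", spec)
        assert sorted(initial_identifiers(ethanol)) == sorted(
            initial_identifiers(permuted)
        )


class TestEcfp:
    @pytest.mark.parametrize("diameter", [4, 6])
    def test_single_atom_molecule(self, methane, diameter):
        fp = ecfp(methane, diameter=diameter, k=1024)
        assert len(fp.records) == 1
        assert fp.records[0].radius == 0
        assert int(fp.bits.sum()) == 1

    def test_ethanol_ecfp4_six_features(self, ethanol):
        fp = ecfp(ethanol, diameter=4, k=1024)
        assert len(fp.records) == 6
        assert sorted(r.radius for r in fp.records) == [0, 0, 0, 1, 1, 1]

    def test_folding_only_changes_bit_placement(self, ethanol):
        fp1 = ecfp(ethanol, diameter=4, k=1024)
        fp2 = ecfp(ethanol, diameter=4, k=2048)
        assert sorted(r.identifier for r in fp1.records) == sorted(
            r.identifier for r in fp2.records
        )

    def test_empty_molecule_raises(self):
        with pytest.raises(ValueError):
            ecfp(Molecule("empty", [], []), 4, 1024)

    def test_every_set_bit_is_explained(self, clean_library):
        for mol in clean_library[:10]:
            fp = ecfp(mol, diameter=6, k=1024)
            explained = {r.bit_index for r in fp.records}
            assert set(np.flatnonzero(fp.bits)) == explained

    def test_ecfp6_retains_at_least_ecfp4(self, clean_library):
        for mol in clean_library[:10]:
            n4 = len(ecfp(mol, diameter=4, k=2048).records)
            n6 = len(ecfp(mol, diameter=6, k=2048).records)
            assert n6 >= n4

    def test_isomorphism_invariance(self, clean_library):
        rng = np.random.default_rng(5)
        for mol in clean_library[:8]:
            perm = rng.permutation(len(mol.atoms))
            inv = np.argsort(perm)
            atoms = [
                Atom(int(inv[a.index]), a.element, a.sybyl_type,
                     a.formal_charge, a.attached_h, a.in_ring)
                for a in mol.atoms
            ]
            atoms.sort(key=lambda a: a.index)
            bonds = [Bond(int(inv[b.a]), int(inv[b.b]), b.order) for b in mol.bonds]
            relabeled = Molecule(mol.name, atoms, bonds)
            ids_a = sorted(r.identifier for r in ecfp(mol, 6, 2048).records)
            ids_b = sorted(r.identifier for r in ecfp(relabeled, 6, 2048).records)
            assert ids_a == ids_b

    @pytest.mark.parametrize("diameter", [4, 6])
    def test_matches_brute_force_oracle(self, diameter, ethanol, propane, benzene):
        small = generate_library(FixtureSpec(n_per_class=15, label_noise=0.0,
                                             seed=23, max_atoms=8))
        molecules = [ethanol, propane, benzene] + [
            m for m in small if len(m.atoms) <= 8
        ]
        assert len(molecules) >= 10
        for mol in molecules:
            oracle = brute_force_environments(mol, diameter // 2)
            engine = engine_environments(mol, diameter)
            assert engine == oracle, mol.name

    def test_rdkit_environment_cross_check(self):
        """Retained radius>=1 environments (as bond sets) match RDKit's
        Morgan enumeration on asymmetric probe molecules."""
        from rdkit import Chem
        from rdkit.Chem import AllChem

        for smi in ["CCO", "CC(C)O", "CC(=O)NC", "OCC(N)CO", "c1ccccc1O"]:
            rd = Chem.MolFromSmiles(smi)
            info = {}
            AllChem.GetMorganFingerprint(rd, 2, bitInfo=info)
            rd_bondsets = set()
            for entries in info.values():
                for atom, radius in entries:
                    if radius == 0:
                        continue
                    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(rd, radius, atom)
                    rd_bondsets.add(frozenset(
                        tuple(sorted((rd.GetBondWithIdx(b).GetBeginAtomIdx(),
                                      rd.GetBondWithIdx(b).GetEndAtomIdx())))
                        for b in bond_ids
                    ))
            fp = ecfp(read_smiles(smi), diameter=4, k=2048)
            mine = {r.bond_set for r in fp.records if r.radius > 0}
            assert mine == rd_bondsets, smi


class TestTanimoto:
    def _fp_from_bits(self, on_bits, k=1024, diameter=4):
        from bitterfp.fingerprint import Fingerprint

        bits = np.zeros(k, dtype=bool)
        bits[list(on_bits)] = True
        return Fingerprint(k=k, diameter=diameter, bits=bits, records=[],
                           collided=False)

    def test_identity_is_one(self, ethanol):
        fp = ecfp(ethanol, 4, 1024)
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(self._fp_from_bits([1, 2]), self._fp_from_bits([3, 4])) == 0.0

    def test_partial_overlap(self):
        a = self._fp_from_bits([1, 2, 3])
        b = self._fp_from_bits([2, 3, 4])
        assert tanimoto(a, b) == 0.5

    def test_both_empty_is_zero(self):
        assert tanimoto(self._fp_from_bits([]), self._fp_from_bits([])) == 0.0

    def test_mismatched_settings_raise(self):
        with pytest.raises(ValueError):
            tanimoto(self._fp_from_bits([1], k=1024), self._fp_from_bits([1], k=2048))

    def test_similarity_matrix_unit_diagonal(self, clean_library):
        fps = [ecfp(m, 6, 2048) for m in clean_library[:6]]
        sim, mean = similarity_matrix(fps, fps)
        assert np.allclose(np.diag(sim), 1.0)
        assert 0 <= mean <= 1

    def test_similarity_matrix_mean(self):
        a = [self._fp_from_bits([1]), self._fp_from_bits([2])]
        sim, mean = similarity_matrix(a, a)
        assert mean == 0.5

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            similarity_matrix([], [])
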