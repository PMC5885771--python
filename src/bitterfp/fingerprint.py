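"""Extended-connectivity fingerprints with per-bit substructure records.

The circular-fingerprint algorithm: each heavy atom starts from a 32-bit
identifier hashing its local invariants, identifiers are iteratively updated
from neighbor identifiers up to diameter/2 rounds, equivalent atom
environments are de-duplicated by their bond set, and surviving identifiers
are folded into a fixed-length bit vector by modular reduction. Every set bit
stays traceable to the atom/bond environment(s) that produced it.

The hash is a fixed, seedless mix (BLAKE2b, 4-byte digest), so fingerprints
are bit-exact across runs and platforms. Bit positions are internal to this
engine and are not expected to match other circular-fingerprint
implementations; only the retained environment sets are comparable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .molecule_io import ATOMIC_NUMBER, BOND_ORDER_CODE, Molecule

__all__ = [
    "FeatureRecord",
    "Fingerprint",
    "initial_identifiers",
    "ecfp",
    "tanimoto",
    "similarity_matrix",
]


def _hash32(*parts) -> int:
    """Deterministic 32-bit hash of a flat tuple of ints/strings."""
    h = hashlib.blake2b(digest_size=4)
    for p in parts:
        if isinstance(p, str):
            h.update(b"s")
            h.update(p.encode())
        else:
            h.update(b"i")
            h.update(int(p).to_bytes(8, "little", signed=True))
        h.update(b"\x00")
    return int.from_bytes(h.digest(), "little")


@dataclass(frozen=True)
class FeatureRecord:
    """Provenance of one retained atom environment."""

    bit_index: int
    identifier: int
    center_atom: int
    radius: int
    atom_set: frozenset[int]
    bond_set: frozenset[tuple[int, int]]


@dataclass
class Fingerprint:
    """Fixed-length binary fingerprint plus its feature provenance."""

    k: int
    diameter: int
    bits: np.ndarray  # bool, shape (k,)
    records: list[FeatureRecord]
    collided: bool

    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def records_for_bit(self, bit: int) -> list[FeatureRecord]:
        return [r for r in self.records if r.bit_index == bit]

    def to_hex(self) -> str:
        return np.packbits(self.bits.astype(np.uint8)).tobytes().hex()


def initial_identifiers(mol: Molecule) -> list[int]:
    """One 32-bit identifier per heavy atom from its invariant tuple.

    Invariants: atomic number, heavy-atom degree, attached hydrogens, formal
    charge, ring membership, and the Sybyl atom type string.
    """
    degree = [0] * len(mol.atoms)
    for b in mol.bonds:
        degree[b.a] += 1
        degree[b.b] += 1
    return [
        _hash32(
            "init",
            ATOMIC_NUMBER[a.element],
            degree[a.index],
            a.attached_h,
            a.formal_charge,
            int(a.in_ring),
            a.sybyl_type,
        )
        for a in mol.atoms
    ]


def _environment(mol: Molecule, adj, center: int, radius: int):
    """Atom and bond sets of the radius-r circular environment of an atom.

    Atoms at graph distance <= r from the center; bonds whose nearer endpoint
    is at distance <= r-1 (i.e. every bond crossed while growing the sphere,
    including closure bonds between perimeter-adjacent atoms).
    """
    dist = {center: 0}
    frontier = [center]
    for d in range(1, radius + 1):
        nxt = []
        for u in frontier:
            for v, _ in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    atoms = frozenset(dist)
    bonds = set()
    for b in mol.bonds:
        if b.a in dist and b.b in dist and min(dist[b.a], dist[b.b]) <= radius - 1:
            bonds.add(b.key)
    return atoms, frozenset(bonds)


def ecfp(mol: Molecule, diameter: int = 4, k: int = 1024) -> Fingerprint:
    """Generate the circular fingerprint of a curated molecule.

    Iterations r = 1..diameter/2 rehash each atom identifier together with
    its sorted (bond-order code, neighbor identifier) pairs. A candidate
    feature is dropped when its bond set equals that of an already-retained
    feature (earlier iteration wins; within an iteration the smaller
    identifier wins). Radius-0 features carry empty bond sets and instead
    de-duplicate by identical identifiers.
    """
    if diameter not in (2, 4, 6, 8):
        raise ValueError("diameter must be an even number of bond steps")
    if not mol.atoms:
        raise ValueError("empty molecule")
    adj = mol.neighbors()
    n_iter = diameter // 2

    identifiers = initial_identifiers(mol)
    retained: list[tuple[int, int, int, frozenset, frozenset]] = []
    # (identifier, center, radius, atom_set, bond_set)
    seen_bond_sets: set[frozenset] = set()
    seen_init_ids: set[int] = set()

    for atom in mol.atoms:
        ident = identifiers[atom.index]
        if ident in seen_init_ids:
            continue
        seen_init_ids.add(ident)
        retained.append((ident, atom.index, 0, frozenset([atom.index]), frozenset()))

    current = identifiers
    for r in range(1, n_iter + 1):
        updated = []
        candidates = []
        for atom in mol.atoms:
            i = atom.index
            nbrs = sorted(
                (BOND_ORDER_CODE[order], current[j]) for j, order in adj[i]
            )
            flat: list[int] = [r, current[i]]
            for code, ident in nbrs:
                flat.extend((code, ident))
            new_id = _hash32("iter", *flat)
            updated.append(new_id)
            atoms_r, bonds_r = _environment(mol, adj, i, r)
            if bonds_r:  # isolated atoms add nothing beyond radius 0
                candidates.append((new_id, i, r, atoms_r, bonds_r))
        # within an iteration, smaller identifier wins ties on bond set
        for cand in sorted(candidates, key=lambda c: (c[0], c[1])):
            if cand[4] in seen_bond_sets:
                continue
            seen_bond_sets.add(cand[4])
            retained.append(cand)
        current = updated

    bits = np.zeros(k, dtype=bool)
    records = []
    for ident, center, radius, atom_set, bond_set in retained:
        bit = ident % k
        bits[bit] = True
        records.append(FeatureRecord(bit, ident, center, radius, atom_set, bond_set))
    distinct = {rec.identifier for rec in records}
    collided = int(bits.sum()) < len(distinct)
    return Fingerprint(k=k, diameter=diameter, bits=bits, records=records, collided=collided)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A AND B| / |A OR B|; 0 for two empty vectors."""
    if a.k != b.k or a.diameter != b.diameter:
        raise ValueError("fingerprint settings (k, diameter) must match")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a.bits, b.bits).sum()) / union


def similarity_matrix(
    fps_a: list[Fingerprint], fps_b: list[Fingerprint]
) -> tuple[np.ndarray, float]:
    """All-pairs Tanimoto matrix between two fingerprint sets, plus its mean."""
    if not fps_a or not fps_b:
        raise ValueError("empty fingerprint sequence")
    k, d = fps_a[0].k, fps_a[0].diameter
    for fp in [*fps_a, *fps_b]:
        if fp.k != k or fp.diameter != d:
            raise ValueError("all fingerprints must share (k, diameter)")
    A = np.stack([fp.bits for fp in fps_a]).astype(np.int32)
    B = np.stack([fp.bits for fp in fps_b]).astype(np.int32)
    inter = A @ B.T
    union = A.sum(1)[:, None] + B.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim, float(sim.mean())


def fingerprint_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """Stack fingerprints into a (n, k) float matrix for model training."""
    return np.stack([fp.bits for fp in fps]).astype(np.float64)
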