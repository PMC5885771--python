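"""Molecular graph I/O: Tripos MOL2 parsing/writing, curation, and simple counts.

Molecules are stored as heavy-atom graphs: explicit hydrogens in the input
are folded into the ``attached_h`` count of their heavy neighbor, because
fingerprint generation operates on non-hydrogen atoms only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "ParseError",
    "CurationError",
    "BOND_ORDERS",
    "ALLOWED_ELEMENTS",
    "read_mol2",
    "write_mol2",
    "read_smiles",
    "curate",
    "mol_counts",
    "structure_key",
    "read_manifest",
]

#: Bond-order tokens accepted from the MOL2 BOND section, mapped to the
#: internal order names. "du"/"un"/"nc" are not chemical bonds we model.
_MOL2_BOND_TOKENS = {
    "1": "single",
    "2": "double",
    "3": "triple",
    "ar": "aromatic",
    "am": "amide",
}
_BOND_TOKEN_OUT = {v: k for k, v in _MOL2_BOND_TOKENS.items()}

BOND_ORDERS = ("single", "double", "triple", "aromatic", "amide")

#: Integer codes used when hashing bond orders into fingerprints.
BOND_ORDER_CODE = {name: i + 1 for i, name in enumerate(BOND_ORDERS)}

#: Elements admitted by the curation rules.
ALLOWED_ELEMENTS = frozenset(
    ["C", "H", "O", "N", "S", "P", "Si", "F", "Cl", "Br", "I"]
)

#: Standard atomic masses (g/mol). Extends beyond the admitted set so that
#: molecules with exotic elements can be parsed and then rejected by curation.
ATOMIC_MASS = {
    "H": 1.008, "Li": 6.94, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Na": 22.99, "Mg": 24.305, "Al": 26.982,
    "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098,
    "Ca": 40.078, "Fe": 55.845, "Zn": 65.38, "As": 74.922, "Se": 78.971,
    "Br": 79.904, "I": 126.904,
}

ATOMIC_NUMBER = {
    "H": 1, "Li": 3, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11,
    "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19,
    "Ca": 20, "Fe": 26, "Zn": 30, "As": 33, "Se": 34, "Br": 35, "I": 53,
}


class ParseError(ValueError):
    """Raised when a molecular file cannot be interpreted."""


class CurationError(ValueError):
    """Raised when curation preconditions are violated (e.g. missing label)."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    sybyl_type: str
    formal_charge: int = 0
    attached_h: int = 0
    in_ring: bool = False

    def __post_init__(self):
        if self.attached_h < 0:
            raise ValueError("attached_h must be non-negative")
        if self.element not in ATOMIC_NUMBER:
            raise ValueError(f"unsupported element {self.element!r}")


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: str

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("bond endpoints must differ")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")

    @property
    def key(self) -> tuple[int, int]:
        """Canonical (min, max) endpoint pair identifying this bond."""
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class Molecule:
    """A heavy-atom molecular graph with an optional binary taste label."""

    name: str
    atoms: list[Atom]
    bonds: list[Bond]
    label: str | None = None  # "bitter" | "non-bitter" | None

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond {bond} references a missing atom")
            if bond.key in seen:
                raise ValueError(f"duplicate bond {bond.key}")
            seen.add(bond.key)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for atom in self.atoms:
            g.add_node(
                atom.index,
                element=atom.element,
                charge=atom.formal_charge,
                attached_h=atom.attached_h,
            )
        for bond in self.bonds:
            g.add_edge(bond.a, bond.b, order=bond.order)
        return g

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph())

    def neighbors(self) -> list[list[tuple[int, str]]]:
        """Adjacency as, per atom, a list of (neighbor index, bond order)."""
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for bond in self.bonds:
            adj[bond.a].append((bond.b, bond.order))
            adj[bond.b].append((bond.a, bond.order))
        return adj


# ---------------------------------------------------------------------------
# MOL2 reading / writing
# ---------------------------------------------------------------------------

def _element_from_sybyl(sybyl: str) -> str:
    elem = sybyl.split(".", 1)[0]
    # Normalize case, e.g. "CL" -> "Cl"
    return elem[0].upper() + elem[1:].lower() if len(elem) > 1 else elem.upper()


def _mark_rings(atoms: list[Atom], bonds: list[Bond]) -> list[Atom]:
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from((b.a, b.b) for b in bonds)
    ring_atoms: set[int] = set()
    for cycle in nx.cycle_basis(g):
        ring_atoms.update(cycle)
    return [replace(a, in_ring=(a.index in ring_atoms)) for a in atoms]


def read_mol2(text_or_path: str | Path) -> list[Molecule]:
    """Parse one or more molecules from Tripos MOL2 text or a file path.

    Explicit hydrogens are collapsed into the ``attached_h`` count of their
    heavy neighbor; heavy-atom input order is preserved. A comment line of the
    form ``# label: Y`` (or ``N``) preceding a MOLECULE block attaches the
    taste label.
    """
    text = str(text_or_path)
    if "@<TRIPOS>" not in text:
        path = Path(text) if text.strip() else None
        if path is None or not path.is_file():
            raise ParseError("no MOLECULE block found and input is not a file")
        text = path.read_text()

    lines = text.splitlines()
    # Locate MOLECULE blocks and any immediately-preceding label comments.
    starts = [i for i, ln in enumerate(lines) if ln.strip() == "@<TRIPOS>MOLECULE"]
    if not starts:
        raise ParseError("no MOLECULE block")

    molecules = []
    for n_block, start in enumerate(starts):
        end = starts[n_block + 1] if n_block + 1 < len(starts) else len(lines)
        label = None
        j = start - 1
        while j >= 0 and (not lines[j].strip() or lines[j].lstrip().startswith("#")):
            stripped = lines[j].lstrip()
            if stripped.startswith("#") and "label:" in stripped:
                token = stripped.split("label:", 1)[1].strip().upper()
                label = {"Y": "bitter", "N": "non-bitter"}.get(token)
                break
            j -= 1
        molecules.append(_parse_block(lines[start:end], label))
    return molecules


def _parse_block(block: list[str], label: str | None) -> Molecule:
    sections: dict[str, list[str]] = {}
    current = None
    for ln in block:
        stripped = ln.strip()
        if stripped.startswith("@<TRIPOS>"):
            current = stripped[len("@<TRIPOS>"):]
            sections[current] = []
        elif current is not None and stripped and not stripped.startswith("#"):
            sections[current].append(stripped)

    if "ATOM" not in sections:
        raise ParseError("missing ATOM section")
    if "BOND" not in sections:
        raise ParseError("missing BOND section")
    name = sections["MOLECULE"][0] if sections.get("MOLECULE") else "unnamed"

    raw_atoms = []  # (orig_id, element, sybyl, charge)
    for ln in sections["ATOM"]:
        parts = ln.split()
        if len(parts) < 6:
            raise ParseError(f"malformed ATOM record: {ln!r}")
        orig_id = int(parts[0])
        sybyl = parts[5]
        charge = 0
        if len(parts) >= 9:
            q = float(parts[8])
            charge = round(q) if abs(q - round(q)) < 0.25 else 0
        raw_atoms.append((orig_id, _element_from_sybyl(sybyl), sybyl, charge))

    raw_bonds = []
    for ln in sections["BOND"]:
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"malformed BOND record: {ln!r}")
        token = parts[3].lower()
        if token not in _MOL2_BOND_TOKENS:
            raise ParseError(f"unknown bond order token {parts[3]!r}")
        raw_bonds.append((int(parts[1]), int(parts[2]), _MOL2_BOND_TOKENS[token]))

    # Collapse explicit hydrogens into heavy-atom attached_h counts.
    id_to_pos = {orig: i for i, (orig, *_rest) in enumerate(raw_atoms)}
    is_h = [elem == "H" for _, elem, _, _ in raw_atoms]
    heavy_index: dict[int, int] = {}
    atoms: list[Atom] = []
    for orig_id, elem, sybyl, charge in raw_atoms:
        if elem == "H":
            continue
        heavy_index[orig_id] = len(atoms)
        atoms.append(Atom(len(atoms), elem, sybyl, charge, 0))

    h_counts = [0] * len(atoms)
    bonds: list[Bond] = []
    for a_id, b_id, order in raw_bonds:
        if a_id not in id_to_pos or b_id not in id_to_pos:
            raise ParseError(f"bond references unknown atom ({a_id}, {b_id})")
        a_h, b_h = is_h[id_to_pos[a_id]], is_h[id_to_pos[b_id]]
        if a_h and b_h:
            continue  # H2 fragment; ignored
        if a_h or b_h:
            heavy = heavy_index[b_id if a_h else a_id]
            h_counts[heavy] += 1
        else:
            bonds.append(Bond(heavy_index[a_id], heavy_index[b_id], order))

    atoms = [replace(a, attached_h=h) for a, h in zip(atoms, h_counts)]
    atoms = _mark_rings(atoms, bonds)
    return Molecule(name=name, atoms=atoms, bonds=bonds, label=label)


def write_mol2(molecules: Iterable[Molecule]) -> str:
    """Serialize molecules to MOL2 text, re-expanding attached hydrogens.

    Coordinates are written as zeros (2D topology only); formal charges go in
    the charge column; labels are written as ``# label:`` comments so that
    ``read_mol2(write_mol2(ms))`` round-trips graphs, Sybyl types and labels.
    """
    out = []
    for mol in molecules:
        n_h = sum(a.attached_h for a in mol.atoms)
        if mol.label is not None:
            out.append(f"# label: {'Y' if mol.label == 'bitter' else 'N'}")
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.name)
        out.append(f"{len(mol.atoms) + n_h} {len(mol.bonds) + n_h} 0 0 0")
        out.append("SMALL")
        out.append("USER_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for a in mol.atoms:
            out.append(
                f"{a.index + 1:>4} {a.element}{a.index + 1:<4} "
                f"0.0000 0.0000 0.0000 {a.sybyl_type:<6} 1 MOL "
                f"{float(a.formal_charge):.4f}"
            )
        h_id = len(mol.atoms)
        h_records = []
        for a in mol.atoms:
            for _ in range(a.attached_h):
                h_id += 1
                out.append(
                    f"{h_id:>4} H{h_id:<4} 0.0000 0.0000 0.0000 H      1 MOL 0.0000"
                )
                h_records.append((h_id, a.index + 1))
        out.append("@<TRIPOS>BOND")
        for i, b in enumerate(mol.bonds):
            out.append(f"{i + 1:>4} {b.a + 1:>4} {b.b + 1:>4} {_BOND_TOKEN_OUT[b.order]}")
        for j, (hid, heavy) in enumerate(h_records):
            out.append(f"{len(mol.bonds) + j + 1:>4} {heavy:>4} {hid:>4} 1")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# SMILES convenience input (via RDKit)
# ---------------------------------------------------------------------------

_HYB_SUFFIX = {"SP3": "3", "SP2": "2", "SP": "1"}


def read_smiles(smiles: str, name: str = "", label: str | None = None) -> Molecule:
    """Build a Molecule from a SMILES string (RDKit-backed convenience path).

    Sybyl-like atom types are synthesized from element + hybridization
    ("C.3", "N.ar", ...) since SMILES carries no Sybyl typing.
    """
    from rdkit import Chem

    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    atoms = []
    for i, a in enumerate(rd.GetAtoms()):
        if a.GetIsAromatic():
            suffix = "ar"
        else:
            suffix = _HYB_SUFFIX.get(str(a.GetHybridization()), "3")
        atoms.append(
            Atom(
                index=i,
                element=a.GetSymbol(),
                sybyl_type=f"{a.GetSymbol()}.{suffix}",
                formal_charge=a.GetFormalCharge(),
                attached_h=a.GetTotalNumHs(),
            )
        )
    order_map = {
        Chem.BondType.SINGLE: "single",
        Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple",
        Chem.BondType.AROMATIC: "aromatic",
    }
    bonds = []
    for b in rd.GetBonds():
        if b.GetBondType() not in order_map:
            raise ParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map[b.GetBondType()]))
    atoms = _mark_rings(atoms, bonds)
    return Molecule(name=name or smiles, atoms=atoms, bonds=bonds, label=label)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def structure_key(mol: Molecule) -> str:
    """Permutation-invariant structure hash used for duplicate detection.

    Weisfeiler-Lehman graph hash over (element, formal charge, attached-H)
    node labels and bond-order edge labels.
    """
    g = nx.Graph()
    for a in mol.atoms:
        g.add_node(a.index, lab=f"{a.element}|{a.formal_charge}|{a.attached_h}")
    for b in mol.bonds:
        g.add_edge(b.a, b.b, lab=b.order)
    if len(g) == 0:
        return "empty"
    return nx.weisfeiler_lehman_graph_hash(g, node_attr="lab", edge_attr="lab", iterations=4)


@dataclass
class Rejection:
    molecule: Molecule
    reason: str  # "disconnected" | "element" | "conflicting label" | "duplicate"


def curate(molecules: Sequence[Molecule]) -> tuple[list[Molecule], list[Rejection]]:
    """Apply the four curation rules to a labeled molecule sequence.

    1. disconnected structures (salts, mixtures) are rejected;
    2. molecules with elements outside the admitted set are rejected;
    3. identical structures carrying conflicting labels are all rejected;
    4. exact duplicates within one label keep only the first occurrence.
    """
    for m in molecules:
        if m.label is None:
            raise CurationError(f"molecule {m.name!r} has no label")

    kept: list[Molecule] = []
    rejected: list[Rejection] = []
    survivors: list[tuple[Molecule, str]] = []
    for m in molecules:
        if m.n_components() != 1:
            rejected.append(Rejection(m, "disconnected"))
        elif any(a.element not in ALLOWED_ELEMENTS for a in m.atoms):
            rejected.append(Rejection(m, "element"))
        else:
            survivors.append((m, structure_key(m)))

    labels_by_key: dict[str, set[str]] = {}
    for m, key in survivors:
        labels_by_key.setdefault(key, set()).add(m.label)  # type: ignore[arg-type]
    conflicted = {k for k, labs in labels_by_key.items() if len(labs) > 1}

    seen: set[str] = set()
    for m, key in survivors:
        if key in conflicted:
            rejected.append(Rejection(m, "conflicting label"))
        elif key in seen:
            rejected.append(Rejection(m, "duplicate"))
        else:
            seen.add(key)
            kept.append(m)
    return kept, rejected


# ---------------------------------------------------------------------------
# Physicochemical counts
# ---------------------------------------------------------------------------

def mol_counts(mol: Molecule) -> tuple[float, int, int]:
    """(molecular weight incl. implicit H, H-bond donors, H-bond acceptors).

    Donor/acceptor use simple Lipinski counting: donors are O/N atoms bearing
    at least one hydrogen; acceptors are all O and N atoms.
    """
    mw = sum(ATOMIC_MASS[a.element] + a.attached_h * ATOMIC_MASS["H"] for a in mol.atoms)
    n_hbd = sum(1 for a in mol.atoms if a.element in ("O", "N") and a.attached_h >= 1)
    n_hba = sum(1 for a in mol.atoms if a.element in ("O", "N"))
    return (mw, n_hbd, n_hba)


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path, base_dir: str | Path | None = None) -> list[Molecule]:
    """Load a delimited manifest of (id, path-or-smiles, label Y/N) rows."""
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    molecules = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.lower().startswith("id\t"):
            continue
        ident, source, label_tok = [tok.strip() for tok in ln.split("\t")[:3]]
        label = {"Y": "bitter", "N": "non-bitter"}[label_tok.upper()]
        candidate = base / source
        if candidate.exists():
            mols = read_mol2(candidate)
            if len(mols) != 1:
                raise ParseError(f"{source}: expected one molecule per file")
            mol = mols[0]
            mol.name, mol.label = ident, label
        else:
            mol = read_smiles(source, name=ident, label=label)
        molecules.append(mol)
    return molecules
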