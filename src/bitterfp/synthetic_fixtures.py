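"""Labeled toy molecule libraries with a planted structure-label rule.

The generator emulates the shape of a bitter/non-bitter training corpus:
random small heavy-atom graphs (3-12 atoms, common organic elements,
connected, valence-consistent) in which the bitter class carries a planted
thioamide-like motif (N-C=S) and the non-bitter class never contains
sulfur, so the motif's fingerprint bits separate the classes perfectly
before label noise. Independent label flips with a configurable probability
then add the kind of annotation noise real taste panels produce.

Because every bitter molecule shares the terminal =S atom environment, the
radius-0 sulfur bit is a known ground-truth feature against which feature
importance and attribution can be validated (`motif_reference_bit`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fingerprint import _hash32
from .molecule_io import Atom, Bond, Molecule, curate, structure_key, write_mol2

__all__ = [
    "FixtureSpec",
    "generate_library",
    "write_fixture",
    "motif_reference_bit",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ORDER_VAL = {"single": 1, "double": 2, "triple": 3}
#: background element palette (no sulfur: sulfur marks the planted motif)
_BACKGROUND = ["C", "C", "C", "C", "N", "O"]


@dataclass
class FixtureSpec:
    n_per_class: int = 200
    label_noise: float = 0.05
    seed: int = 0
    min_atoms: int = 3
    max_atoms: int = 12

    def __post_init__(self):
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n_per_class < 5:
            raise ValueError("n_per_class must be >= 5")
        if self.max_atoms < self.min_atoms or self.max_atoms < 4:
            raise ValueError("motif (3 atoms + attachment) does not fit max_atoms")


def motif_reference_bit(k: int) -> int:
    """Folded bit of the planted motif's terminal sulfur environment.

    The =S atom of the motif always has degree 1, no hydrogens, no charge,
    no ring, Sybyl type S.2 — a constant radius-0 identifier across every
    bitter molecule.
    """
    return _hash32("init", 16, 1, 0, 0, 0, "S.2") % k


def _sybyl(element: str, orders: list[str]) -> str:
    if element == "S":
        return "S.2"
    if any(o in ("double", "triple") for o in orders):
        return f"{element}.2"
    return f"{element}.3"


def _assemble(elements: list[str], bonds: list[tuple[int, int, str]]) -> Molecule:
    per_atom_orders: list[list[str]] = [[] for _ in elements]
    used = [0] * len(elements)
    for a, b, order in bonds:
        per_atom_orders[a].append(order)
        per_atom_orders[b].append(order)
        used[a] += _ORDER_VAL[order]
        used[b] += _ORDER_VAL[order]
    atoms = [
        Atom(
            index=i,
            element=el,
            sybyl_type=_sybyl(el, per_atom_orders[i]),
            attached_h=max(_VALENCE[el] - used[i], 0),
        )
        for i, el in enumerate(elements)
    ]
    bond_objs = [Bond(a, b, order) for a, b, order in bonds]
    from .molecule_io import _mark_rings

    atoms = _mark_rings(atoms, bond_objs)
    return Molecule(name="", atoms=atoms, bonds=bond_objs)


def _random_graph(rng: np.random.Generator, n_atoms: int, with_motif: bool) -> Molecule:
    """A random connected valence-consistent heavy-atom graph."""
    elements: list[str] = []
    bonds: list[tuple[int, int, str]] = []

    if with_motif:
        # motif: C(=S)-N; the carbon is the attachment point
        elements += ["C", "S", "N"]
        bonds += [(0, 1, "double"), (0, 2, "single")]
        n_background = max(n_atoms - 3, 1)
    else:
        n_background = n_atoms

    offset = len(elements)
    for i in range(n_background):
        elements.append(str(rng.choice(_BACKGROUND)))
    # random spanning tree over background atoms
    for i in range(offset + 1, len(elements)):
        free = [
            j for j in range(offset, i)
            if _free_valence(elements, bonds, j) >= 1
        ]
        parent = int(rng.choice(free)) if free else offset
        bonds.append((parent, i, "single"))
    if with_motif:
        # attach motif carbon to a background atom with free valence
        free = [
            j for j in range(offset, len(elements))
            if _free_valence(elements, bonds, j) >= 1
        ]
        bonds.append((0, int(rng.choice(free)) if free else offset, "single"))
    # occasional ring closure
    if len(elements) - offset >= 4 and rng.random() < 0.35:
        cand = [
            j for j in range(offset, len(elements))
            if _free_valence(elements, bonds, j) >= 1
        ]
        rng.shuffle(cand)
        existing = {(min(a, b), max(a, b)) for a, b, _ in bonds}
        for a, b in zip(cand, cand[1:]):
            if (min(a, b), max(a, b)) not in existing and a != b:
                bonds.append((a, b, "single"))
                break
    # occasional double bond upgrade on a C-C edge
    if rng.random() < 0.3:
        for idx, (a, b, order) in enumerate(bonds):
            if (
                order == "single"
                and a >= offset and b >= offset
                and elements[a] == "C" and elements[b] == "C"
                and _free_valence(elements, bonds, a) >= 1
                and _free_valence(elements, bonds, b) >= 1
            ):
                bonds[idx] = (a, b, "double")
                break
    return _assemble(elements, bonds)


def _free_valence(elements, bonds, j) -> int:
    used = sum(
        _ORDER_VAL[o] for a, b, o in bonds if j in (a, b)
    )
    return _VALENCE[elements[j]] - used


def generate_library(spec: FixtureSpec) -> list[Molecule]:
    """Generate ``2 * n_per_class`` labeled molecules, deterministic in seed.

    Structure keys are unique across the library (collisions are re-rolled),
    so the library passes curation without losses; labels are then flipped
    independently with probability ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    library: list[Molecule] = []
    for cls, label in ((1, "bitter"), (0, "non-bitter")):
        made = 0
        attempts = 0
        while made < spec.n_per_class:
            attempts += 1
            if attempts > 200 * spec.n_per_class:
                raise RuntimeError("could not generate enough unique structures")
            n_atoms = int(rng.integers(max(spec.min_atoms, 4 if cls else spec.min_atoms),
                                       spec.max_atoms + 1))
            mol = _random_graph(rng, n_atoms, with_motif=bool(cls))
            key = structure_key(mol)
            if key in seen:
                continue
            seen.add(key)
            mol.name = f"{'B' if cls else 'N'}{made:04d}"
            mol.label = label
            library.append(mol)
            made += 1
    # independent label flips
    for mol in library:
        if rng.random() < spec.label_noise:
            mol.label = "non-bitter" if mol.label == "bitter" else "bitter"
    return library


def write_fixture(library: list[Molecule], directory: str | Path) -> Path:
    """Write one MOL2 file per molecule plus a tab-delimited manifest.

    Returns the manifest path. The files round-trip through the MOL2 reader
    (identical structure keys and labels).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["id\tpath\tlabel"]
    for mol in library:
        fname = f"{mol.name}.mol2"
        (directory / fname).write_text(write_mol2([mol]))
        rows.append(f"{mol.name}\t{fname}\t{'Y' if mol.label == 'bitter' else 'N'}")
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
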