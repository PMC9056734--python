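"""Molecular geometry, bond graphs and rigid-fragment rotation.

This module is the geometric engine behind every torsion scan: it holds a
molecule as an ordered list of atoms plus an undirected bond graph, infers
bonds from covalent radii when no explicit list is given, partitions the
graph at a chosen bond into a fixed and a rotating side, and applies
rigid-body rotations of the moving side about the bond axis.

Conventions
-----------
* Coordinates are in Angstrom throughout.
* Angles are in degrees; rotations follow the right-hand rule looking from
  the pivot atom towards the partner atom of the bond.
* The two bond atoms lie on the rotation axis and are therefore invariant;
  the "rotating side" is the connected component containing the partner
  atom (the partner itself is included for bookkeeping — rotating a point
  on the axis is the identity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import yaml
from scipy.spatial.transform import Rotation

SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "S"})


class XYZParseError(ValueError):
    """Malformed XYZ input; message names the offending line."""


class NonRotatableBondError(ValueError):
    """The bond lies on a cycle (or is absent): no two-way partition exists."""


def covalent_radii() -> dict[str, float]:
    """Return the shipped single-bond covalent radius table (Angstrom)."""
    text = resources.files("spinbarrier.data").joinpath("covalent_radii.yaml").read_text()
    return {k: float(v) for k, v in yaml.safe_load(text)["radii"].items()}


@dataclass
class Atom:
    """One atom: element symbol, Cartesian position (Angstrom), potential class.

    ``atom_class`` keys into a non-bonded parameter table; by default it is
    the element symbol itself.
    """

    element: str
    position: np.ndarray
    atom_class: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        if not self.atom_class:
            self.atom_class = self.element


@dataclass
class Molecule:
    """An ordered atom list plus an undirected bond graph (index pairs)."""

    atoms: list[Atom]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    comment: str = ""
    multi_fragment: bool = False

    def __post_init__(self) -> None:
        n = len(self.atoms)
        canon = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
            canon.add((min(i, j), max(i, j)))
        self.bonds = canon

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def atom_classes(self) -> list[str]:
        return [a.atom_class for a in self.atoms]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from(self.bonds)
        return g

    def with_positions(self, pos: np.ndarray) -> "Molecule":
        """Copy with replaced coordinates (same elements, classes, bonds)."""
        pos = np.asarray(pos, dtype=float)
        atoms = [Atom(a.element, p, a.atom_class) for a, p in zip(self.atoms, pos)]
        return Molecule(atoms, set(self.bonds), self.comment, self.multi_fragment)


@dataclass(frozen=True)
class RotatableBond:
    """A bond whose removal splits the molecule in two.

    ``axis_atoms`` is the ordered (pivot, partner) pair; ``rotating_side``
    is the set of atom indices moved by :func:`rotate_fragment` (the
    connected component of the partner atom, partner included).
    """

    axis_atoms: tuple[int, int]
    rotating_side: frozenset[int]


def read_xyz(path: str | Path) -> Molecule:
    """Read a standard XYZ file (count line, comment line, `El x y z` rows).

    Atom order is preserved; the comment line is kept as metadata. No bonds
    are assigned — follow with :func:`infer_bonds` or :func:`read_bonds`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}:1: count line is not an integer: {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    rows = [ln for ln in lines[2:] if ln.strip()]
    if len(rows) < count:
        raise XYZParseError(
            f"{path}: count line says {count} atoms but only {len(rows)} atom rows found"
        )
    atoms: list[Atom] = []
    for k in range(count):
        lineno = 3 + k
        parts = rows[k].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}:{lineno}: expected 'El x y z', got {rows[k]!r}")
        el = parts[0]
        if el not in SUPPORTED_ELEMENTS:
            raise XYZParseError(f"{path}:{lineno}: unknown element {el!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}:{lineno}: non-numeric coordinate in {rows[k]!r}") from None
        atoms.append(Atom(el, np.array(xyz)))
    return Molecule(atoms, comment=comment)


def write_xyz(molecule: Molecule, path: str | Path) -> None:
    """Write a Molecule in XYZ format (bonds are not representable in XYZ)."""
    path = Path(path)
    lines = [str(len(molecule)), molecule.comment]
    for a in molecule.atoms:
        x, y, z = a.position
        lines.append(f"{a.element} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(lines) + "\n")


def read_bonds(path: str | Path) -> set[tuple[int, int]]:
    """Read a sidecar bond list: one '<i> <j>' 0-based pair per line."""
    pairs = set()
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.split("#")[0].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two indices, got {ln!r}")
        i, j = int(parts[0]), int(parts[1])
        pairs.add((min(i, j), max(i, j)))
    return pairs


def infer_bonds(molecule: Molecule, scale: float = 1.2) -> Molecule:
    """Assign bonds by the covalent-radius criterion.

    Pair (i, j) is bonded iff d(i,j) <= scale * (r_i + r_j). An explicitly
    supplied bond list should be preferred over inference for toy fragments
    (see :func:`read_bonds`).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    radii = covalent_radii()
    pos = molecule.positions
    n = len(molecule)
    bonds: set[tuple[int, int]] = set()
    if n >= 2:
        r = np.array([radii[a.element] for a in molecule.atoms])
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        cutoff = scale * (r[:, None] + r[None, :])
        ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
        bonds = {(int(i), int(j)) for i, j in zip(ii, jj)}
    return Molecule(list(molecule.atoms), bonds, molecule.comment, molecule.multi_fragment)


def partition_by_bond(molecule: Molecule, bond: tuple[int, int]) -> RotatableBond:
    """Split the molecule at ``bond`` = (pivot, partner).

    Deleting the bond must disconnect the graph into exactly two components
    (otherwise the bond lies on a ring and a rigid torsion is undefined).
    The rotating side is the component containing the partner atom.
    """
    i, j = bond
    key = (min(i, j), max(i, j))
    if key not in molecule.bonds:
        raise KeyError(f"bond ({i},{j}) not present in the molecule")
    g = molecule.graph()
    g.remove_edge(i, j)
    if nx.has_path(g, i, j):
        raise NonRotatableBondError(f"bond ({i},{j}) lies on a cycle: non-rotatable bond")
    rotating = frozenset(nx.node_connected_component(g, j))
    return RotatableBond(axis_atoms=(i, j), rotating_side=rotating)


def rotate_fragment(molecule: Molecule, bond: RotatableBond, angle_deg: float) -> Molecule:
    """Rotate the bond's rotating side by ``angle_deg`` about the bond axis.

    Right-hand rule looking from pivot to partner; atoms outside the
    rotating side are untouched. Rigid-body: all distances within the
    rotating side (and within the fixed side) are preserved.
    """
    i, j = bond.axis_atoms
    pos = molecule.positions
    axis = pos[j] - pos[i]
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate bond axis (coincident atoms)")
    rot = Rotation.from_rotvec(math.radians(angle_deg) * axis / norm)
    idx = sorted(bond.rotating_side)
    pos[idx] = rot.apply(pos[idx] - pos[i]) + pos[i]
    return molecule.with_positions(pos)
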