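"""Atom-atom exp-6 potential, torsion landscapes and their analysis.

The steric energy of a conformation is approximated as a sum of empirical
pairwise Buckingham terms

    E(r_ij) = -A_ij * r_ij**-6 + B_ij * exp(-C_ij * r_ij)

over all non-excluded atom pairs, with per-atom-class constants combined by
the geometric rule for A and B and the arithmetic rule for C. Rotating a
fragment about a single bond on a uniform angle grid and evaluating the sum
at each step yields a torsion landscape, from which barrier heights, minima
structure and thermally accessible angular windows are read off.

Sign convention: the r**-6 term is attractive (negative). Tables written in
the repulsive-first ``+A/r^6`` dialect are rejected explicitly via the
``convention`` field of the parameter file rather than silently reinterpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

from .structures import Molecule, NonRotatableBondError, RotatableBond, rotate_fragment


class ParameterisationError(KeyError):
    """An atom class present in the molecule has no parameter entry."""


@dataclass
class PotentialParameters:
    """Per-atom-class exp-6 constants.

    ``table`` maps atom_class -> (A, B, C) with A in kJ mol^-1 A^6,
    B in kJ mol^-1, C in A^-1. A, B >= 0 and C > 0 are enforced.
    """

    table: dict[str, tuple[float, float, float]]
    source: str = "user"

    def __post_init__(self) -> None:
        for cls, (a, b, c) in self.table.items():
            if a < 0 or b < 0:
                raise ValueError(f"{cls}: A and B must be non-negative")
            if c <= 0:
                raise ValueError(f"{cls}: C must be positive")

    def __contains__(self, atom_class: str) -> bool:
        return atom_class in self.table

    def __getitem__(self, atom_class: str) -> tuple[float, float, float]:
        try:
            return self.table[atom_class]
        except KeyError:
            raise ParameterisationError(
                f"no exp-6 parameters for atom class {atom_class!r}"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PotentialParameters":
        doc = yaml.safe_load(Path(path).read_text())
        if doc.get("convention", "exp6-attractive") not in ("exp6-attractive",):
            raise ValueError(
                "parameter file declares a repulsive-first (+A/r^6) convention; "
                "convert the table to E = -A r^-6 + B exp(-C r) before use"
            )
        tab = {k: (float(v["A"]), float(v["B"]), float(v["C"]))
               for k, v in doc["parameters"].items()}
        return cls(tab, source=str(path))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PotentialParameters":
        df = pd.read_csv(path, comment="#")
        tab = {str(r.atom_class): (float(r.A), float(r.B), float(r.C))
               for r in df.itertuples()}
        return cls(tab, source=str(path))


def default_parameters() -> PotentialParameters:
    """The shipped representative Williams-type exp-6 table (H,C,N,O,F,S).

    A documented stand-in for qualitative work; see the data file header.
    """
    text = resources.files("spinbarrier.data").joinpath("exp6_params.yaml").read_text()
    doc = yaml.safe_load(text)
    tab = {k: (float(v["A"]), float(v["B"]), float(v["C"]))
           for k, v in doc["parameters"].items()}
    return PotentialParameters(tab, source="spinbarrier builtin (representative stand-in)")


def combine_params(
    class_i: str, class_j: str, table: PotentialParameters
) -> tuple[float, float, float]:
    """Mixed-pair constants: geometric mean for A and B, arithmetic for C."""
    ai, bi, ci = table[class_i]
    aj, bj, cj = table[class_j]
    return (float(np.sqrt(ai * aj)), float(np.sqrt(bi * bj)), (ci + cj) / 2.0)


def pair_energy(r, pair_constants: tuple[float, float, float]):
    """exp-6 energy at separation r (Angstrom), kJ/mol. Vectorised over r."""
    a, b, c = pair_constants
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    e = -a * r**-6 + b * np.exp(-c * r)
    return float(e) if e.ndim == 0 else e


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which bonded neighbours to drop from the non-bonded sum.

    Pairs separated by <= ``max_separation`` bonds are excluded; the default
    (2) drops 1-2 and 1-3 pairs and keeps 1-4 and beyond, the usual
    convention of the atom-atom potential method.
    """

    max_separation: int = 2


def _excluded_pairs(molecule: Molecule, policy: ExclusionPolicy) -> set[tuple[int, int]]:
    if policy.max_separation < 1 or not molecule.bonds:
        return set()
    g = molecule.graph()
    out: set[tuple[int, int]] = set()
    for i, dists in nx.all_pairs_shortest_path_length(g, cutoff=policy.max_separation):
        for j, d in dists.items():
            if i < j and d >= 1:
                out.add((i, j))
    return out


def total_energy(
    molecule: Molecule,
    table: PotentialParameters | None = None,
    exclusion: ExclusionPolicy = ExclusionPolicy(),
) -> float:
    """Sum of exp-6 pair energies over all non-excluded unordered pairs, kJ/mol."""
    if table is None:
        table = default_parameters()
    n = len(molecule)
    if n < 2:
        return 0.0
    classes = molecule.atom_classes
    pos = molecule.positions
    excl = _excluded_pairs(molecule, exclusion)
    # group pairs by class pair so distances evaluate vectorised
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            key = tuple(sorted((classes[i], classes[j])))
            by_pair.setdefault(key, []).append((i, j))
    total = 0.0
    for (ci, cj), pairs in by_pair.items():
        consts = combine_params(ci, cj, table)
        idx = np.array(pairs)
        r = np.linalg.norm(pos[idx[:, 0]] - pos[idx[:, 1]], axis=1)
        total += float(np.sum(pair_energy(r, consts)))
    return total


@dataclass
class TorsionLandscape:
    """Potential energy (kJ/mol) versus rotation angle (deg) for one bond.

    Energies are stored relative to the landscape minimum (min = 0); the
    grid is uniform and strictly increasing.
    """

    bond: RotatableBond | None
    angles: np.ndarray
    energies: np.ndarray
    reference: str = "min=0"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.size != self.energies.size:
            raise ValueError("angles and energies must have equal length")
        if self.angles.size >= 2:
            steps = np.diff(self.angles)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-9):
                raise ValueError("angle grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")

    @property
    def step(self) -> float:
        return float(self.angles[1] - self.angles[0])

    def is_full_period(self) -> bool:
        """True if the grid spans exactly 360 deg endpoint-inclusive."""
        return bool(np.isclose(self.angles[-1] - self.angles[0], 360.0, atol=1e-9))

    def periodic_view(self) -> tuple[np.ndarray, np.ndarray]:
        """Angles/energies with a duplicated 360-deg endpoint dropped."""
        if self.is_full_period():
            return self.angles[:-1], self.energies[:-1]
        return self.angles, self.energies

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"angle_deg": self.angles, "energy_kJ_per_mol": self.energies}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TorsionLandscape":
        df = pd.read_csv(path)
        return cls(None, df["angle_deg"].to_numpy(), df["energy_kJ_per_mol"].to_numpy())


def torsion_scan(
    molecule: Molecule,
    bond: RotatableBond,
    start: float = -180.0,
    stop: float = 180.0,
    step: float = 1.0,
    table: PotentialParameters | None = None,
    exclusion: ExclusionPolicy = ExclusionPolicy(),
) -> TorsionLandscape:
    """Rotate the fragment over [start, stop] in ``step``-deg increments and
    evaluate the total steric energy at each grid point.

    The landscape is reported relative to its minimum. Pair exclusions are
    topology-based and hence angle-independent.
    """
    n_steps = (stop - start) / step
    if not np.isclose(n_steps, round(n_steps)):
        raise ValueError("step must divide (stop - start)")
    angles = start + step * np.arange(int(round(n_steps)) + 1)
    energies = np.empty_like(angles)
    for k, theta in enumerate(angles):
        rotated = rotate_fragment(molecule, bond, float(theta))
        energies[k] = total_energy(rotated, table, exclusion)
    energies -= energies.min()
    return TorsionLandscape(bond, angles, energies)


def barrier_height(landscape: TorsionLandscape) -> float:
    """max(E) - min(E) over the landscape, kJ/mol."""
    if landscape.energies.size == 0:
        raise ValueError("empty landscape")
    return float(landscape.energies.max() - landscape.energies.min())


def find_minima(
    landscape: TorsionLandscape, prominence: float = 0.1
) -> list[tuple[float, float]]:
    """Local minima on the periodic angle grid, sorted by angle.

    ``prominence`` (kJ/mol) filters noise wells; plateau minima report the
    plateau's central grid point. Returns (angle_deg, energy) pairs; a
    constant landscape yields an empty list.
    """
    if prominence < 0:
        raise ValueError("prominence must be non-negative")
    ang, ene = landscape.periodic_view()
    n = ene.size
    if n < 3:
        return []
    if np.ptp(ene) == 0:
        return []
    # tile three periods so wrap-around minima are seen with full context
    tiled = np.concatenate([ene, ene, ene])
    peaks, _ = find_peaks(-tiled, prominence=prominence, plateau_size=1)
    out = []
    for p in peaks:
        if n <= p < 2 * n:
            k = p - n
            out.append((float(ang[k]), float(ene[k])))
    out.sort(key=lambda t: t[0])
    return out


def accessible_range(
    landscape: TorsionLandscape, threshold: float
) -> list[tuple[float, float, float]]:
    """Maximal contiguous periodic angular intervals with E - min(E) <= threshold.

    Returns (start_deg, end_deg, width_deg) triples sorted by start angle;
    an interval wrapping the grid boundary has end < start and its width
    accounts for the wrap. A threshold above the global barrier yields a
    single 360-deg interval.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ang, ene = landscape.periodic_view()
    step = landscape.step
    mask = (ene - ene.min()) <= threshold
    n = mask.size
    if mask.all():
        return [(float(ang[0]), float(ang[0]) + 360.0 - step, 360.0)]
    if not mask.any():
        return []
    # contiguous runs on the circle
    runs = []
    idx = np.flatnonzero(mask)
    start = prev = idx[0]
    for k in idx[1:]:
        if k == prev + 1:
            prev = k
        else:
            runs.append((start, prev))
            start = prev = k
    runs.append((start, prev))
    # merge wrap-around: run ending at n-1 joins run starting at 0
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n - 1:
        s, _ = runs[-1]
        _, e = runs[0]
        runs = runs[1:-1] + [(s, e + n)]
    out = []
    for s, e in runs:
        a0 = float(ang[s % n])
        a1 = float(ang[e % n])
        width = (e - s) * step
        out.append((a0, a1, float(width)))
    out.sort(key=lambda t: t[0])
    return out


def contains_angle(interval: tuple[float, float, float], angle: float) -> bool:
    """Whether a periodic (start, end, width) interval covers ``angle``."""
    a0, _, width = interval
    delta = (angle - a0) % 360.0
    return delta <= width + 1e-9
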