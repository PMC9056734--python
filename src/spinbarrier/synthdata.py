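"""Deterministic generators for every input the pipeline consumes.

No reference geometry of the rosuvastatin anion is publicly deposited, so
the geometric stages are exercised on toy fragments built from internal
coordinates: an ideal tetrahedral methyl rotor, an ethane-like two-rotor
molecule, an isopropyl group on a small scaffold whose contacts can be made
deliberately asymmetric (mimicking the very different barriers of the two
isopropyl methyls in the E isomer), and the two-proton spin pair of a water
molecule. Relaxation datasets and CW derivative line shapes are generated
from stated model parameters with seeded multiplicative noise.

Every generator is pure given (parameters, seed): repeated calls are
bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

from .relaxation import BPPProcess, FieldSettings, RelaxationDataset, total_t1
from .spin_m2 import MotionGroup, MotionModel, SpinSystem
from .structures import Atom, Molecule

TETRAHEDRAL_ANGLE_DEG = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...

#: Literature-reported activation parameters for methyl reorientation in
#: amorphous rosuvastatin calcium (two-process fit of the proton T1 curve
#: at 25 MHz). C in s^-2, tau0 in s, EA in kJ/mol.
METHYL_MEDIUM_PROCESS = BPPProcess(C=9.64e8, tau0=1.69e-11, EA=6.84)
METHYL_LOW_PROCESS = BPPProcess(C=2.29e8, tau0=58.70e-11, EA=1.23)

#: Pulse-spectrometer field of the reference T1 measurements.
DEFAULT_FIELD = FieldSettings(larmor_frequency_mhz=25.0)

#: Scaffold-probe tilt/swing (deg) of the shipped asymmetric isopropyl
#: fixture, chosen once at fixture creation so the two methyl barriers
#: differ by about a factor of four (the E-isomer signature). Do not retune.
DEFAULT_ISOPROPYL_ASYMMETRY = 26.0

#: Fixture truth, frozen at creation: methyl-barrier ratio of the default
#: asymmetric toy on a 1-deg grid with the shipped parameter table.
ISOPROPYL_FIXTURE_BARRIER_RATIO = 3.9652

#: Energy threshold (kJ/mol) at which the symmetric ("Z-like") isopropyl
#: fixture shows a single wide accessible window (> 80 deg) around 0 deg
#: on the central-bond torsion landscape. Pinned at fixture creation.
Z_WINDOW_THRESHOLD_KJ_MOL = 13.0


def _ring_directions(polar_deg: float, azimuths_deg) -> np.ndarray:
    """Unit vectors at a common polar angle from +z, given azimuths (deg)."""
    th = math.radians(polar_deg)
    out = []
    for az in azimuths_deg:
        ph = math.radians(az)
        out.append([math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)])
    return np.array(out)


def build_methyl(
    r_ch: float = 1.09,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    stem: bool = False,
) -> tuple[Molecule, SpinSystem, MotionModel]:
    """Ideal C3-symmetric tetrahedral methyl rotor.

    The carbon sits at the origin with the (implicit) attachment direction
    along ``axis``; the three hydrogens lie at the tetrahedral angle from
    the axis, so the H-H distance is r_CH * sqrt(8/3) (= 1.780 A for the
    default 1.09 A bond). ``stem=True`` adds a bare carbon along the axis
    so the rotor has an explicit rotatable bond. The returned SpinSystem
    holds the three protons in one group and the MotionModel gives that
    group a ``c3_jump`` about the axis.
    """
    if not 1.0 <= r_ch <= 1.2:
        raise ValueError("r_CH outside the chemically sane 1.0-1.2 A range")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # build along +z then rotate the frame onto the requested axis
    h_dirs = _ring_directions(TETRAHEDRAL_ANGLE_DEG, [0.0, 120.0, 240.0])
    frame = _frame_onto(axis)
    atoms = [Atom("C", np.zeros(3))]
    bonds = set()
    for d in h_dirs:
        atoms.append(Atom("H", r_ch * (frame @ d)))
        bonds.add((0, len(atoms) - 1))
    if stem:
        atoms.append(Atom("C", 1.52 * axis))
        bonds.add((0, len(atoms) - 1))
    mol = Molecule(atoms, bonds, comment="ideal tetrahedral methyl rotor")
    spins = SpinSystem(
        np.array([a.position for a in mol.atoms if a.element == "H"]),
        ["methyl"] * 3,
    )
    motion = MotionModel(
        {"methyl": MotionGroup("c3_jump", axis_point=np.zeros(3), axis_direction=axis)}
    )
    return mol, spins, motion


def _frame_onto(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``axis`` (identity when already +z)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_ethane_like(r_cc: float = 1.526, r_ch: float = 1.09) -> Molecule:
    """Staggered ethane: two coupled methyl rotors, exact C3 scan symmetry."""
    if not 1.0 <= r_ch <= 1.2:
        raise ValueError("r_CH outside the chemically sane 1.0-1.2 A range")
    c0 = np.zeros(3)
    c1 = np.array([0.0, 0.0, r_cc])
    atoms = [Atom("C", c0), Atom("C", c1)]
    bonds = {(0, 1)}
    # C0 hydrogens point away from C1 (polar angle 109.47 from +z)
    for d in _ring_directions(TETRAHEDRAL_ANGLE_DEG, [0.0, 120.0, 240.0]):
        atoms.append(Atom("H", c0 + r_ch * d))
        bonds.add((0, len(atoms) - 1))
    # C1 hydrogens point away from C0, staggered by 60 deg
    for d in _ring_directions(180.0 - TETRAHEDRAL_ANGLE_DEG, [60.0, 180.0, 300.0]):
        atoms.append(Atom("H", c1 + r_ch * d))
        bonds.add((1, len(atoms) - 1))
    return Molecule(atoms, bonds, comment="staggered ethane-like two-rotor toy")


def build_isopropyl_toy(
    asymmetry: float = 0.0,
    scaffold: bool = True,
) -> Molecule:
    """Isopropyl group on a small rigid scaffold, with tunable asymmetry.

    Atom indices: 0 = CH carbon (the isopropyl apex), 1 = scaffold carbon
    (the rotation axis partner: the bond (1, 0) is the analogue of the
    scaffold-isopropyl axis), 2 = apex H, 3/4 = the two methyl carbons,
    5-7 / 8-10 their hydrogens, then the scaffold substituents (two oxygen
    probes and a hydrogen on the scaffold carbon).

    ``asymmetry`` tilts one oxygen probe towards one methyl (degrees of
    polar tilt): 0 keeps the two methyl environments exactly mirror
    equivalent (the "Z-like" case), positive values crowd the second methyl
    so its torsion barrier rises (the "E-like" case). ``scaffold=False``
    omits the probes, leaving the rotors in an empty environment.
    """
    if asymmetry < 0:
        raise ValueError("asymmetry must be non-negative")
    r_cc, r_ch, r_co = 1.52, 1.09, 1.43
    apex = np.zeros(3)
    scaf = np.array([0.0, 0.0, -r_cc])
    atoms = [Atom("C", apex), Atom("C", scaf)]
    bonds = {(0, 1)}
    # apex substituents at tetrahedral angle from the apex->scaffold bond;
    # mirror plane is xz (azimuths +-60 swap under y -> -y)
    sub_dirs = _ring_directions(180.0 - TETRAHEDRAL_ANGLE_DEG, [180.0, 120.0, -120.0])
    atoms.append(Atom("H", apex + r_ch * sub_dirs[0]))
    bonds.add((0, 2))
    me_centres = []
    for d in sub_dirs[1:]:
        atoms.append(Atom("C", apex + r_cc * d))
        me_centres.append((len(atoms) - 1, d))
        bonds.add((0, len(atoms) - 1))
    # methyl hydrogens: staggered about each apex->methyl axis, built for
    # methyl 1 and mirrored (y -> -y) for methyl 2 so asymmetry=0 is exact
    first_h = []
    ci, d = me_centres[0]
    frame = _frame_onto(d)
    # C-H bonds make the tetrahedral angle with the methyl->apex direction,
    # i.e. 180 - 109.47 deg from the apex->methyl axis (pointing outward)
    for hd in _ring_directions(180.0 - TETRAHEDRAL_ANGLE_DEG, [60.0, 180.0, 300.0]):
        pos = atoms[ci].position + r_ch * (frame @ hd)
        atoms.append(Atom("H", pos))
        first_h.append(pos)
        bonds.add((ci, len(atoms) - 1))
    cj, _ = me_centres[1]
    for pos in first_h:
        mirrored = pos * np.array([1.0, -1.0, 1.0])
        atoms.append(Atom("H", mirrored))
        bonds.add((cj, len(atoms) - 1))
    if scaffold:
        # scaffold substituents point away from the apex (below the xy plane
        # through the scaffold carbon): a mirror pair of O probes and one H
        probe_polar = TETRAHEDRAL_ANGLE_DEG  # away from the apex (+z) bond
        d1 = _ring_directions(probe_polar, [60.0])[0]
        # asymmetry tilts the second probe up towards the rotor and swings
        # it azimuthally towards the second methyl, crowding that rotor only
        d2 = _ring_directions(probe_polar - asymmetry, [-60.0 - asymmetry])[0]
        dh = _ring_directions(probe_polar, [180.0])[0]
        for d, el, r in ((d1, "O", r_co), (d2, "O", r_co), (dh, "H", r_ch)):
            atoms.append(Atom(el, scaf + r * d))
            bonds.add((1, len(atoms) - 1))
    return Molecule(
        atoms, bonds,
        comment=f"isopropyl-on-scaffold toy fragment, asymmetry={asymmetry:g}",
    )


ISOPROPYL_METHYL_BONDS = ((0, 3), (0, 4))
ISOPROPYL_CENTRAL_BOND = (1, 0)


def build_water_pair(tumbling: bool = False) -> tuple[SpinSystem, MotionModel]:
    """The two protons of one water molecule, 1.5 A apart.

    ``tumbling=True`` attaches an isotropic motion model (fast molecular
    tumbling), under which the pair's dipolar contribution averages to zero;
    otherwise the pair is static (rigid water below the motional regime).
    """
    spins = SpinSystem(
        np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
        ["water", "water"],
    )
    kind = "isotropic" if tumbling else "static"
    model = MotionModel(
        {"water": MotionGroup(kind, axis_point=np.array([0.75, 0.0, 0.0]))}
    )
    return spins, model


def simulate_t1_dataset(
    processes: list[BPPProcess] | None = None,
    field: FieldSettings = DEFAULT_FIELD,
    t_grid: np.ndarray | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    sample: str = "synthetic",
) -> RelaxationDataset:
    """Synthetic T1(T) dataset from a multi-process BPP model.

    Defaults emulate the reference two-process methyl relaxation of
    amorphous rosuvastatin calcium at 25 MHz on a 30-300 K grid in 2 K
    steps, with 5% multiplicative log-normal noise. The noise has zero mean
    in log space (the median curve is the model curve) and is bit-
    reproducible given the seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if processes is None:
        processes = [METHYL_LOW_PROCESS, METHYL_MEDIUM_PROCESS]
    if t_grid is None:
        t_grid = np.arange(30.0, 300.0 + 1.0, 2.0)
    t_grid = np.asarray(t_grid, dtype=float)
    t1 = total_t1(t_grid, processes, field)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        t1 = t1 * np.exp(sigma * rng.standard_normal(t_grid.size))
    return RelaxationDataset(t_grid, t1, field, kind="T1", sample=sample)


def simulate_flank_dataset(
    ea: float = 15.8,
    t_window: tuple[float, float] = (260.0, 344.0),
    n_points: int = 20,
    t1_at_window_start: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    field: FieldSettings = DEFAULT_FIELD,
    flank: str = "high",
) -> RelaxationDataset:
    """Single-flank Arrhenius dataset: ln T1 linear in 1000/T with slope
    set by ``ea`` (kJ/mol), plus multiplicative log-normal noise.

    Emulates the high-temperature flank of the water-coupled process, whose
    activation energy is estimated from the slope of ln T1 vs 1000/T.
    """
    from scipy.constants import R

    if flank not in ("high", "low"):
        raise ValueError("flank must be 'high' or 'low'")
    lo, hi = t_window
    T = np.linspace(lo, hi, n_points)
    # ln T1 = intercept + s * (1000/T) with |s| = EA / R (EA kJ/mol, R J/mol/K):
    # the slope per unit 1000/T is EA*1000/R divided by 1000
    sign = -1.0 if flank == "high" else 1.0
    s = sign * ea / (R * 1e-3) / 1000.0
    x = 1000.0 / T
    ln_t1 = math.log(t1_at_window_start) + s * (x - x[0])
    t1 = np.exp(ln_t1)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        t1 = t1 * np.exp(sigma * rng.standard_normal(T.size))
    return RelaxationDataset(T, t1, field, kind="T1", sample=f"flank EA={ea}")


def simulate_lineshape(
    components: list[tuple[float, float]],
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First-derivative CW line shape of a Gaussian absorption mixture.

    ``components`` is a list of (weight, sigma_G); the absorption line is
    sum_k w_k * Normal(0, sigma_k) and the returned curve is its analytic
    derivative on ``grid`` (default +-8 sigma_max, 4001 points). The exact
    mixture second moment is sum(w sigma^2)/sum(w).
    """
    if not components:
        raise ValueError("at least one component required")
    for w, s in components:
        if w <= 0 or s <= 0:
            raise ValueError("weights and widths must be positive")
    if grid is None:
        smax = max(s for _, s in components)
        grid = np.linspace(-8.0 * smax, 8.0 * smax, 4001)
    grid = np.asarray(grid, dtype=float)
    deriv = np.zeros_like(grid)
    for w, s in components:
        pdf = np.exp(-0.5 * (grid / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
        deriv += w * (-grid / s**2) * pdf
    return grid, deriv


def mixture_m2(components: list[tuple[float, float]]) -> float:
    """Exact second moment of a Gaussian mixture: sum(w sigma^2)/sum(w)."""
    wsum = sum(w for w, _ in components)
    return sum(w * s**2 for w, s in components) / wsum
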