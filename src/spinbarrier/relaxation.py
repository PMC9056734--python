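"""BPP relaxometry: recovery fits, multi-process T1/T1rho models, Arrhenius
slopes and the E/Z isomer-fraction inference.

The spin-lattice relaxation rate of protons relaxed by a thermally
activated reorientation with correlation time tau_c = tau0 * exp(EA / R T)
follows the Bloembergen-Purcell-Pound (BPP) form

    1/T1 = C * [ tau/(1 + w0^2 tau^2) + 4 tau/(1 + 4 w0^2 tau^2) ]

with C the relaxation constant (s^-2, proportional to the dipolar second
moment of the protons participating in the motion), and w0 the Larmor
angular frequency. Independent motions add rates. In the rotating frame
(spin-lock field B1, w1 = gamma*B1):

    1/T1rho = C * [ (3/2) tau/(1 + 4 w1^2 tau^2)
                  + (5/2) tau/(1 + w0^2 tau^2) + tau/(1 + 4 w0^2 tau^2) ]

Because C counts the protons taking part in a motion, the ratio of the C
constants of the low- and medium-temperature methyl processes measures the
E/Z isomer composition: an E anion contributes 1 low-barrier + 3
medium-barrier methyls, a Z anion 4 medium-barrier methyls, so with
rho = C_low/C_med the E fraction solves f/(4 - f) = rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats
from scipy.constants import R as GAS_CONSTANT  # J mol^-1 K^-1
from scipy.optimize import minimize_scalar
from scipy.signal import argrelmin

from .spin_m2 import CONSTANTS

#: w0*tau at the single-process T1 minimum (root of the stationarity condition)
OMEGA_TAU_AT_MIN = 0.6157951469617562

#: 1/T1 at the minimum equals BPP_MIN_FACTOR * C / w0 for a single process
BPP_MIN_FACTOR = 1.4251757190865015


@dataclass(frozen=True)
class BPPProcess:
    """One thermally activated relaxation process.

    C: relaxation constant, s^-2 (dimensional analysis of the BPP equation;
    some tables print it as 1/s). tau0: pre-exponential correlation time, s.
    EA: activation energy, kJ/mol.
    """

    C: float
    tau0: float
    EA: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.tau0 <= 0 or self.EA <= 0:
            raise ValueError("C, tau0 and EA must all be strictly positive")

    def correlation_time(self, T) -> np.ndarray:
        """tau_c = tau0 * exp(EA / R T); T in K, result in s.

        May overflow to inf for extreme EA/T combinations explored by the
        fitter; the rate expressions below are written so an infinite tau
        yields a zero rate rather than NaN.
        """
        T = np.asarray(T, dtype=float)
        with np.errstate(over="ignore"):
            return self.tau0 * np.exp(self.EA * 1e3 / (GAS_CONSTANT * T))


@dataclass(frozen=True)
class FieldSettings:
    """Static-field Larmor frequency and (optionally) the spin-lock field."""

    larmor_frequency_mhz: float
    b1_gauss: float = 0.0

    def __post_init__(self) -> None:
        if self.larmor_frequency_mhz <= 0:
            raise ValueError("Larmor frequency must be positive")
        if self.b1_gauss < 0:
            raise ValueError("B1 must be non-negative")

    @property
    def omega0(self) -> float:
        """Laboratory-frame angular frequency, rad/s."""
        return 2.0 * np.pi * self.larmor_frequency_mhz * 1e6

    @property
    def omega1(self) -> float:
        """Rotating-frame angular frequency w1 = gamma * B1, rad/s."""
        return CONSTANTS.gamma * self.b1_gauss / CONSTANTS.gauss_per_tesla


@dataclass
class RelaxationDataset:
    """Temperatures (K) versus relaxation times (s) with field metadata."""

    temperatures: np.ndarray
    times: np.ndarray
    field: FieldSettings
    kind: str = "T1"  # or "T1rho"
    sample: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.temperatures.size != self.times.size:
            raise ValueError("temperatures and times must have equal length")
        if np.any(self.temperatures <= 0) or np.any(self.times <= 0):
            raise ValueError("temperatures and times must be positive")
        if self.kind not in ("T1", "T1rho"):
            raise ValueError("kind must be 'T1' or 'T1rho'")


@dataclass
class RecoveryCurve:
    """Inversion/saturation delays (s) versus longitudinal magnetization."""

    delays: np.ndarray
    magnetizations: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.magnetizations = np.asarray(self.magnetizations, dtype=float)
        if self.delays.size < 4:
            raise ValueError("at least 4 recovery points required")
        if np.any(self.delays < 0) or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be non-negative and strictly increasing")


@dataclass
class FitResult:
    """Fitted processes (EA ascending), uncertainties and diagnostics."""

    processes: list[BPPProcess]
    stderr: list[dict]
    residual_norm: float
    converged: bool
    init_record: dict = field(default_factory=dict)


def recovery_magnetization(t, m0: float, t1: float) -> np.ndarray:
    """Inversion-recovery law M(t) = M0 (1 - 2 exp(-t/T1))."""
    return m0 * (1.0 - 2.0 * np.exp(-np.asarray(t, dtype=float) / t1))


def fit_recovery(curve: RecoveryCurve) -> tuple[float, float]:
    """Least-squares (T1, M0) from an inversion-recovery curve."""
    t, m = curve.delays, curve.magnetizations
    model = lmfit.Model(recovery_magnetization, independent_vars=["t"])
    m0_guess = float(np.max(np.abs(m)))
    # crude T1 guess: delay nearest the zero crossing is ~ T1 * ln 2
    k = int(np.argmin(np.abs(m)))
    t1_guess = max(t[k] / np.log(2.0), 1e-6) if t[k] > 0 else max(t[-1] / 3, 1e-6)
    params = model.make_params(m0=m0_guess, t1=t1_guess)
    params["t1"].min = 1e-12
    result = model.fit(m, params, t=t)
    if not result.success:
        raise RuntimeError(f"recovery fit did not converge: {result.message}")
    return float(result.params["t1"].value), float(result.params["m0"].value)


def bpp_rate(T, process: BPPProcess, field: FieldSettings) -> np.ndarray:
    """Laboratory-frame relaxation rate 1/T1 of one process, s^-1."""
    tau = process.correlation_time(T)
    w0 = field.omega0
    # tau/(1+w^2 tau^2) written as 1/(1/tau + w^2 tau): safe as tau -> inf
    with np.errstate(over="ignore", divide="ignore"):
        return process.C * (
            1.0 / (1.0 / tau + w0**2 * tau) + 4.0 / (1.0 / tau + 4.0 * w0**2 * tau)
        )


def total_t1(T, processes: list[BPPProcess], field: FieldSettings) -> np.ndarray:
    """T1 of the sum of independent processes (rates add), s."""
    if not processes:
        raise ValueError("at least one process required")
    rate = sum(bpp_rate(T, p, field) for p in processes)
    return 1.0 / rate


def t1rho_rate(T, process: BPPProcess, field: FieldSettings) -> np.ndarray:
    """Rotating-frame relaxation rate 1/T1rho, s^-1 (like-spin dipolar form)."""
    if field.b1_gauss <= 0:
        raise ValueError("rotating-frame rate requires B1 > 0")
    tau = process.correlation_time(T)
    w0, w1 = field.omega0, field.omega1
    with np.errstate(over="ignore", divide="ignore"):
        return process.C * (
            1.5 / (1.0 / tau + 4.0 * w1**2 * tau)
            + 2.5 / (1.0 / tau + w0**2 * tau)
            + 1.0 / (1.0 / tau + 4.0 * w0**2 * tau)
        )


def total_t1rho(T, processes: list[BPPProcess], field: FieldSettings) -> np.ndarray:
    if not processes:
        raise ValueError("at least one process required")
    rate = sum(t1rho_rate(T, p, field) for p in processes)
    return 1.0 / rate


def t1_minimum(
    processes: list[BPPProcess],
    field: FieldSettings,
    t_range: tuple[float, float] = (80.0, 350.0),
) -> tuple[float, float]:
    """Locate the global T1 minimum on ``t_range``: (T_at_min K, T1_min s).

    Coarse 1 K scan followed by bounded scalar minimisation to 0.01 K.
    Raises if the coarse minimum sits on the range boundary (monotone curve).
    """
    lo, hi = t_range
    grid = np.arange(lo, hi + 0.5, 1.0)
    vals = total_t1(grid, processes, field)
    k = int(np.argmin(vals))
    if k == 0 or k == grid.size - 1:
        raise ValueError("no interior minimum: T1 is monotone on the range")
    res = minimize_scalar(
        lambda T: float(total_t1(T, processes, field)),
        bounds=(grid[k - 1], grid[k + 1]),
        method="bounded",
        options={"xatol": 0.005},
    )
    return float(res.x), float(res.fun)


def single_process_t1_minimum(process: BPPProcess, field: FieldSettings) -> tuple[float, float]:
    """Closed-form single-process minimum: w0*tau = 0.6158, T1min = w0/(1.4252 C)."""
    w0 = field.omega0
    tau_min = OMEGA_TAU_AT_MIN / w0
    t_at_min = process.EA * 1e3 / (GAS_CONSTANT * np.log(tau_min / process.tau0))
    return float(t_at_min), float(w0 / (BPP_MIN_FACTOR * process.C))


def arrhenius_ea(
    dataset: RelaxationDataset,
    window: tuple[float, float],
    flank: str = "high",
) -> tuple[float, float]:
    """Activation energy from the slope of ln T1 versus 1000/T in a window.

    Returns (EA, stderr) in kJ/mol. On the high-temperature flank of a
    minimum (extreme narrowing) ln T1 falls with 1000/T, on the low-
    temperature flank it rises; ``flank`` declares which side the window
    is on and a sign mismatch or non-monotone window triggers a warning
    with the regression R^2.
    """
    if flank not in ("high", "low"):
        raise ValueError("flank must be 'high' or 'low'")
    lo, hi = min(window), max(window)
    sel = (dataset.temperatures >= lo) & (dataset.temperatures <= hi)
    if np.count_nonzero(sel) < 4:
        raise ValueError("need at least 4 points inside the window")
    x = 1000.0 / dataset.temperatures[sel]
    y = np.log(dataset.times[sel])
    fit = stats.linregress(x, y)
    order = np.argsort(x)
    diffs = np.diff(y[order])
    if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        warnings.warn(
            f"window is not single-flank monotone (R^2 = {fit.rvalue**2:.4f})",
            stacklevel=2,
        )
    expected_sign = -1.0 if flank == "high" else 1.0
    if np.sign(fit.slope) not in (0.0, expected_sign):
        warnings.warn(
            f"slope sign is inconsistent with a {flank}-temperature flank",
            stacklevel=2,
        )
    ea = abs(fit.slope) * GAS_CONSTANT  # slope per (1000/T) -> kJ/mol
    err = fit.stderr * GAS_CONSTANT
    return float(ea), float(err)


def expected_c_ratio(f_e: float) -> float:
    """Predicted C_low/C_med for an E-isomer fraction f_e (methyl-count model)."""
    if not 0.0 <= f_e <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return f_e / (4.0 - f_e)


def isomer_fraction(c_low: float, c_medium: float) -> float:
    """E-isomer fraction from the low/medium relaxation-constant ratio.

    Methyl-count model: per anion, E contributes 1 low-barrier and 3
    medium-barrier methyls, Z contributes 4 medium-barrier methyls, so
    rho = C_low/C_med = f/(4 - f) and f_E = 4 rho/(1 + rho). The result is
    clipped to [0, 1] with a warning when the ratio falls outside the model.
    """
    if c_low <= 0 or c_medium <= 0:
        raise ValueError("relaxation constants must be positive")
    rho = c_low / c_medium
    f = 4.0 * rho / (1.0 + rho)
    if f > 1.0:
        warnings.warn(
            f"C ratio {rho:.3f} exceeds the pure-E limit 1/3; fraction clipped to 1",
            stacklevel=2,
        )
        f = 1.0
    return f


def round_fraction_to_percent(f: float, step: float = 5.0) -> float:
    """Convenience formatter: fraction -> percentage rounded to ``step``."""
    return round(100.0 * f / step) * step


# ---------------------------------------------------------------------------
# multi-process fitting


def _process_from_minimum(
    t_min: float, t1_min: float, ea: float, w0: float
) -> BPPProcess:
    """Process whose T1 minimum sits at (t_min, t1_min) with slope ea."""
    c = w0 / (BPP_MIN_FACTOR * t1_min)
    tau_min = OMEGA_TAU_AT_MIN / w0
    tau0 = tau_min / np.exp(ea * 1e3 / (GAS_CONSTANT * t_min))
    return BPPProcess(C=c, tau0=max(tau0, 1e-20), EA=ea)


def _auto_init(
    dataset: RelaxationDataset, n_processes: int
) -> list[BPPProcess]:
    """Deterministic starting parameters from the data's minima structure.

    Each detected T1 minimum seeds one process: C from the minimum depth
    (C = w0 / (1.4252 * T1min)), tau0 from requiring w0*tau = 0.6158 at the
    minimum with an EA guessed from the low-temperature flank slope (falling
    back to a generic 10 kJ/mol when the flank is too short).
    """
    order = np.argsort(dataset.temperatures)
    T = dataset.temperatures[order]
    y = np.log(dataset.times[order])
    w0 = dataset.field.omega0
    # smooth lightly so noise does not spawn spurious minima
    if y.size >= 11:
        kernel = np.ones(5) / 5.0
        ys = np.convolve(y, kernel, mode="same")
        ys[:2], ys[-2:] = y[:2], y[-2:]
    else:
        ys = y
    cand = list(argrelmin(ys, order=max(3, y.size // 20))[0])
    cand.sort(key=lambda k: ys[k])
    minima = []
    for k in cand:
        if all(abs(T[k] - T[m]) > 20.0 for m in minima):
            minima.append(k)
    minima = minima[:n_processes]
    # pad: place extra processes on the cold side of the coldest minimum
    while len(minima) < n_processes:
        coldest = min(minima) if minima else y.size // 2
        minima.append(max(coldest // 2, 1))
    procs = []
    for k in sorted(minima, key=lambda k: T[k]):
        t_min, t1_min = T[k], float(np.exp(ys[k]))
        c = w0 / (BPP_MIN_FACTOR * t1_min)
        # EA from the low-T flank below this minimum (steepest available slope)
        lo_sel = (T < t_min) & (T > t_min - 40.0)
        if np.count_nonzero(lo_sel) >= 4:
            sl = stats.linregress(1000.0 / T[lo_sel], y[lo_sel]).slope
            ea = max(abs(sl) * GAS_CONSTANT, 0.5)
        else:
            ea = 10.0
        tau_min = OMEGA_TAU_AT_MIN / w0
        tau0 = tau_min / np.exp(ea * 1e3 / (GAS_CONSTANT * t_min))
        procs.append(BPPProcess(C=c, tau0=max(tau0, 1e-20), EA=ea))
    return procs


def _auto_init_candidates(
    dataset: RelaxationDataset, n_processes: int
) -> list[list[BPPProcess]]:
    """A small deterministic family of starting points.

    The detection-based init of :func:`_auto_init` is first; for two-process
    fits it is followed by fallbacks that anchor one process at the global
    T1 minimum and sweep plausible positions and slopes for the shallower
    process, which on noisy data may not show as a clean local minimum.
    """
    cands = [_auto_init(dataset, n_processes)]
    if n_processes != 2:
        return cands
    order = np.argsort(dataset.temperatures)
    T = dataset.temperatures[order]
    t1 = dataset.times[order]
    w0 = dataset.field.omega0
    k = int(np.argmin(t1))
    t_glob, t1_glob = float(T[k]), float(t1[k])
    for frac in (0.4, 0.55, 0.7):
        for ea_lo in (1.0, 3.0):
            t_lo = max(t_glob * frac, float(T[0]) + 5.0)
            main = _process_from_minimum(t_glob, t1_glob, ea_lo * 5.0, w0)
            shallow = _process_from_minimum(t_lo, t1_glob * 4.0, ea_lo, w0)
            cands.append([shallow, main])
    return cands


def fit_bpp(
    dataset: RelaxationDataset,
    n_processes: int = 2,
    init: list[BPPProcess] | str = "auto",
) -> FitResult:
    """Weighted least squares of the multi-process BPP model on ln T1.

    Fitting is done on ln T1 versus temperature with equal weights, in
    log10 parameters for C and tau0 so the optimiser moves in natural
    scale. Deterministic given (data, init); ``init='auto'`` derives
    starting values from the minima structure of the data.
    """
    if n_processes < 1:
        raise ValueError("need at least one process")
    if isinstance(init, str):
        if init != "auto":
            raise ValueError("init must be 'auto' or a list of BPPProcess")
        candidates = _auto_init_candidates(dataset, n_processes)
        results = [
            _fit_bpp_single(dataset, n_processes, c, record="auto") for c in candidates
        ]
        best = min(results, key=lambda r: r.residual_norm)
    else:
        if len(init) != n_processes:
            raise ValueError("init length must equal n_processes")
        best = _fit_bpp_single(dataset, n_processes, list(init), record="user")
    if best.init_record.get("at_bound"):
        warnings.warn(
            f"parameters at bounds: {best.init_record['at_bound']}", stacklevel=2
        )
    return best


def _fit_bpp_single(
    dataset: RelaxationDataset,
    n_processes: int,
    init_procs: list[BPPProcess],
    record: str,
) -> FitResult:
    T = dataset.temperatures
    y = np.log(dataset.times)
    fld = dataset.field
    rate_fn = t1rho_rate if dataset.kind == "T1rho" else bpp_rate

    params = lmfit.Parameters()
    for k, p in enumerate(init_procs):
        params.add(f"logC_{k}", value=np.log10(p.C), min=0.0, max=20.0)
        params.add(f"logtau0_{k}", value=np.log10(p.tau0), min=-20.0, max=-3.0)
        params.add(f"ea_{k}", value=p.EA, min=0.05, max=200.0)

    def unpack(pars) -> list[BPPProcess]:
        return [
            BPPProcess(
                C=10.0 ** pars[f"logC_{k}"].value,
                tau0=10.0 ** pars[f"logtau0_{k}"].value,
                EA=pars[f"ea_{k}"].value,
            )
            for k in range(n_processes)
        ]

    def residual(pars):
        procs = unpack(pars)
        rate = sum(rate_fn(T, p, fld) for p in procs)
        # equals -(ln model T1 - ln data T1); sign is immaterial to leastsq.
        # floor keeps ln finite when a trial process freezes out entirely
        return np.log(np.maximum(rate, 1e-300)) + y

    out = lmfit.minimize(residual, params, method="leastsq")
    procs = unpack(out.params)
    order = np.argsort([p.EA for p in procs])
    procs = [procs[k] for k in order]

    at_bound = []
    for name, par in out.params.items():
        if par.vary and par.value is not None:
            span = par.max - par.min
            if span > 0 and (par.value - par.min < 1e-9 * span or par.max - par.value < 1e-9 * span):
                at_bound.append(name)

    stderr = []
    for k in order:
        pc, pt, pe = (out.params[f"logC_{k}"], out.params[f"logtau0_{k}"], out.params[f"ea_{k}"])
        c_val, t_val = 10.0**pc.value, 10.0**pt.value
        ln10 = np.log(10.0)
        stderr.append(
            {
                "C": c_val * ln10 * pc.stderr if pc.stderr else None,
                "tau0": t_val * ln10 * pt.stderr if pt.stderr else None,
                "EA": pe.stderr,
            }
        )
    return FitResult(
        processes=procs,
        stderr=stderr,
        residual_norm=float(np.linalg.norm(out.residual)),
        converged=bool(out.success) and not at_bound,
        init_record={"init": record,
                     "start": [(p.C, p.tau0, p.EA) for p in init_procs],
                     "at_bound": at_bound},
    )
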