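"""Pipeline orchestration: configuration, reports and the three analyses.

Ties the stages together into the three study-level workflows:

* landscape analysis — torsion scans of selected bonds, summarised as
  barrier heights, minima structure and accessible angular windows;
* second-moment analysis — rigid, motionally averaged and proton-count
  composite M2 values, plus M2 read back from a CW derivative line shape;
* relaxometry — multi-process BPP fit of a T1(T) dataset, minimum location,
  flank activation energies and the E/Z isomer fraction.

Reports are plain YAML/CSV with units embedded in the field names; every
report records the config hash, seeds and package version so identical
inputs produce identical reports.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .relaxation import (
    BPPProcess,
    FieldSettings,
    RelaxationDataset,
    arrhenius_ea,
    fit_bpp,
    isomer_fraction,
    round_fraction_to_percent,
    t1_minimum,
)
from .spin_m2 import (
    MotionModel,
    SpinSystem,
    composite_m2,
    m2_from_lineshape,
    mc_m2,
    rigid_m2_powder,
)
from .steric import (
    ExclusionPolicy,
    PotentialParameters,
    accessible_range,
    barrier_height,
    default_parameters,
    find_minima,
    torsion_scan,
)
from .structures import Molecule, partition_by_bond


class ValidationError(ValueError):
    """Configuration or input failed validation (CLI exit code 2)."""


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (canonical YAML, sha256)."""
    canon = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _report_header(config: dict, seed: int | None = None) -> dict:
    hdr = {
        "package": "spinbarrier",
        "version": __version__,
        "config_sha256_16": config_hash(config),
    }
    if seed is not None:
        hdr["seed"] = seed
    return hdr


def run_landscape_analysis(
    molecule: Molecule,
    bonds: list[tuple[int, int]],
    out_dir: str | Path | None = None,
    start: float = -180.0,
    stop: float = 180.0,
    step: float = 1.0,
    table: PotentialParameters | None = None,
    exclusion: ExclusionPolicy = ExclusionPolicy(),
    prominence: float = 0.1,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Scan each bond and summarise barrier, minima and accessible windows.

    Returns one row per bond (barrier_kJ_per_mol, n_minima, minima spacing,
    widest accessible window); when ``out_dir`` is given, writes per-bond
    landscape CSVs and the summary CSV there. Deterministic.
    """
    if table is None:
        table = default_parameters()
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, j in bonds:
        rb = partition_by_bond(molecule, (i, j))
        scape = torsion_scan(molecule, rb, start, stop, step, table, exclusion)
        minima = find_minima(scape, prominence)
        spacings = (
            np.diff([a for a, _ in minima]).tolist() if len(minima) >= 2 else []
        )
        row = {
            "bond": f"{i}-{j}",
            "barrier_kJ_per_mol": barrier_height(scape),
            "n_minima": len(minima),
            "minima_deg": [a for a, _ in minima],
            "minima_spacing_deg": spacings,
        }
        if threshold is not None:
            windows = accessible_range(scape, threshold)
            row["threshold_kJ_per_mol"] = threshold
            row["n_windows"] = len(windows)
            row["widest_window_deg"] = max((w for *_, w in windows), default=0.0)
        rows.append(row)
        if out_dir is not None:
            scape.to_csv(out_dir / f"landscape_bond_{i}_{j}.csv")
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        summary.to_csv(out_dir / "landscape_summary.csv", index=False)
    return summary


def run_m2_analysis(
    spins: SpinSystem,
    scenarios: dict[str, MotionModel],
    n_orientations: int = 100_000,
    seed: int = 0,
    composite_extra: list[tuple[float, float]] | None = None,
    lineshape: tuple[np.ndarray, np.ndarray] | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Second-moment table: rigid value, one MC row per motional scenario,
    optional proton-count composite and optional line-shape read-back.

    ``composite_extra`` lists (proton_count, M2_G2) components added to the
    anion value (e.g. water protons); ``lineshape`` is (offsets_G,
    derivative amplitudes). Returns the report dict; writes YAML when
    ``out_path`` is given.
    """
    report: dict = {"rigid_M2_G2": rigid_m2_powder(spins).value, "scenarios": {}}
    for name, motion in scenarios.items():
        res = mc_m2(spins, motion, n_orientations=n_orientations, seed=seed)
        report["scenarios"][name] = {
            "M2_G2": res.value,
            "stderr_G2": res.stderr,
            "n_orientations": res.n_orientations,
        }
        if composite_extra:
            n_anion = float(len(spins))
            comps = [(n_anion, res.value)] + list(composite_extra)
            report["scenarios"][name]["composite_M2_G2"] = composite_m2(comps)
    if lineshape is not None:
        offsets, deriv = lineshape
        report["lineshape_M2_G2"] = m2_from_lineshape(offsets, deriv)
    report = {**_report_header({"n_orientations": n_orientations}, seed), **report}
    if out_path is not None:
        Path(out_path).write_text(yaml.safe_dump(report, sort_keys=False))
    return report


def run_relaxometry(
    dataset: RelaxationDataset,
    n_processes: int = 2,
    t_range: tuple[float, float] | None = None,
    ea_windows: list[tuple[float, float, str]] | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Full relaxometry chain: fit, minimum, flank slopes, isomer fraction.

    ``ea_windows`` lists (T_lo, T_hi, flank) for Arrhenius slope estimates.
    The isomer fraction uses the two lowest-EA fitted processes (low/medium
    methyl processes). Stage failures are recorded in the report rather
    than aborting later stages.
    """
    if dataset.kind == "T1rho" and dataset.field.b1_gauss <= 0:
        raise ValidationError("T1rho analysis requested but field.b1_gauss is not set")
    report: dict = _report_header(
        {"n_processes": n_processes, "kind": dataset.kind,
         "larmor_MHz": dataset.field.larmor_frequency_mhz}
    )
    fit = fit_bpp(dataset, n_processes=n_processes)
    report["fit"] = {
        "converged": fit.converged,
        "residual_norm": fit.residual_norm,
        "processes": [
            {
                "C_per_s2": p.C,
                "tau0_s": p.tau0,
                "EA_kJ_per_mol": p.EA,
                "stderr": {k: (float(v) if v is not None else None) for k, v in e.items()},
            }
            for p, e in zip(fit.processes, fit.stderr)
        ],
    }
    if t_range is None:
        t_range = (float(dataset.temperatures.min()), float(dataset.temperatures.max()))
    try:
        t_at_min, t1_min = t1_minimum(fit.processes, dataset.field, t_range)
        report["minimum"] = {"T_K": t_at_min, "T1_s": t1_min}
    except ValueError as exc:
        report["minimum"] = {"error": str(exc)}
    if ea_windows:
        report["arrhenius_EA_kJ_per_mol"] = []
        for lo, hi, flank in ea_windows:
            try:
                ea, err = arrhenius_ea(dataset, (lo, hi), flank)
                report["arrhenius_EA_kJ_per_mol"].append(
                    {"window_K": [lo, hi], "flank": flank, "EA": ea, "stderr": err}
                )
            except ValueError as exc:
                report["arrhenius_EA_kJ_per_mol"].append(
                    {"window_K": [lo, hi], "flank": flank, "error": str(exc)}
                )
    if len(fit.processes) >= 2:
        low, med = fit.processes[0], fit.processes[1]
        rho = low.C / med.C
        f_e = isomer_fraction(low.C, med.C)
        report["isomers"] = {
            "C_ratio_low_over_medium": rho,
            "f_E": round(f_e, 3),
            "percent_E_nearest_5": round_fraction_to_percent(f_e),
            "percent_Z_nearest_5": 100.0 - round_fraction_to_percent(f_e),
        }
    if out_path is not None:
        Path(out_path).write_text(yaml.safe_dump(report, sort_keys=False))
    return report


def load_dataset_csv(
    csv_path: str | Path, sidecar_yaml: str | Path | None = None
) -> RelaxationDataset:
    """Read a dataset CSV (temperature_K, time_s[, kind]) plus field sidecar.

    The sidecar YAML provides larmor_frequency_MHz, optional B1_G and a
    sample label; it defaults to '<csv stem>.yaml' next to the CSV.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("temperature_K", "time_s"):
        if col not in df.columns:
            raise ValidationError(f"{csv_path}: missing required column {col!r}")
    if sidecar_yaml is None:
        cand = csv_path.with_suffix(".yaml")
        if not cand.exists():
            raise ValidationError(f"no field sidecar found at {cand}")
        sidecar_yaml = cand
    meta = yaml.safe_load(Path(sidecar_yaml).read_text())
    if "larmor_frequency_MHz" not in meta:
        raise ValidationError(f"{sidecar_yaml}: missing larmor_frequency_MHz")
    field = FieldSettings(
        larmor_frequency_mhz=float(meta["larmor_frequency_MHz"]),
        b1_gauss=float(meta.get("B1_G", 0.0)),
    )
    kind = str(df["kind"].iloc[0]) if "kind" in df.columns else "T1"
    return RelaxationDataset(
        df["temperature_K"].to_numpy(),
        df["time_s"].to_numpy(),
        field,
        kind=kind,
        sample=str(meta.get("sample", "")),
    )


def save_dataset_csv(
    dataset: RelaxationDataset, csv_path: str | Path
) -> None:
    """Write a dataset as CSV + field sidecar YAML (inverse of load)."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "temperature_K": dataset.temperatures,
            "time_s": dataset.times,
            "kind": dataset.kind,
        }
    ).to_csv(csv_path, index=False)
    meta = {
        "larmor_frequency_MHz": dataset.field.larmor_frequency_mhz,
        "B1_G": dataset.field.b1_gauss,
        "sample": dataset.sample,
    }
    csv_path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
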