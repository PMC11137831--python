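"""File formats: TRIPOS mol2 subset, TSV time series, window manifests,
PMF/landmark output, TOML parameter tables, and the packaged target tables.

Everything is plain text (TSV/CSV/JSON/TOML/mol2); numeric presentation in
written files follows the field's reporting conventions (free energies to
2 decimals, λ nodes to 5 decimals) while JSON results keep full precision.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .potentials import AtomType, PairParams, ParameterTable
from .sampling import RestraintSpec, TimeSeries
from .wham import LandmarkSet, PMFProfile, Window

logger = logging.getLogger(__name__)

__all__ = [
    "Mol2Record",
    "read_mol2",
    "write_mol2",
    "write_timeseries",
    "read_timeseries",
    "write_window_manifest",
    "read_windows",
    "write_pmf",
    "read_pmf",
    "write_landmarks",
    "load_parameter_table",
    "load_binding_table",
    "load_hydration_table",
    "load_extrapolation_line",
]


# --------------------------------------------------------------------------
# mol2 (TRIPOS subset)

@dataclass
class Mol2Record:
    """Parsed @<TRIPOS>ATOM content: names, coordinates (Å), charges, types."""

    names: list[str]
    coordinates: np.ndarray
    charges: np.ndarray
    types: list[str]
    molecule_name: str = ""


def read_mol2(path: str | Path) -> Mol2Record:
    """Minimal TRIPOS mol2 reader: MOLECULE and ATOM sections only.

    Unsupported record types are skipped with a logged warning; a missing
    ATOM section is a :class:`FormatError` naming the line where parsing
    stopped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    section = None
    mol_name = ""
    names, types, coords, charges = [], [], [], []
    saw_molecule = False
    saw_atoms = False
    mol_header_row = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            if section == "MOLECULE":
                saw_molecule = True
                mol_header_row = 0
            elif section == "ATOM":
                saw_atoms = True
            elif section not in ("MOLECULE", "ATOM"):
                logger.warning(
                    "%s:%d: skipping unsupported mol2 section %s",
                    path.name, lineno, section,
                )
            continue
        if section == "MOLECULE":
            if mol_header_row == 0:
                mol_name = line
            mol_header_row += 1
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(
                    f"{path.name}:{lineno}: malformed ATOM record: {line!r}"
                )
            names.append(parts[1])
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
            types.append(parts[5])
            charges.append(float(parts[8]) if len(parts) >= 9 else 0.0)
    if not saw_molecule:
        raise FormatError(
            f"{path.name}: missing @<TRIPOS>MOLECULE section "
            f"(scanned {len(lines)} lines)"
        )
    if not saw_atoms:
        raise FormatError(
            f"{path.name}: missing @<TRIPOS>ATOM section "
            f"(scanned {len(lines)} lines)"
        )
    return Mol2Record(
        names=names,
        coordinates=np.asarray(coords, dtype=float),
        charges=np.asarray(charges, dtype=float),
        types=types,
        molecule_name=mol_name,
    )


def write_mol2(
    path: str | Path,
    names: Sequence[str],
    coordinates: np.ndarray,
    charges: Sequence[float],
    types: Sequence[str] | None = None,
    molecule_name: str = "LJ1264",
) -> None:
    """Write a minimal TRIPOS mol2 file with USER_CHARGES."""
    coordinates = np.asarray(coordinates, dtype=float)
    types = list(types) if types is not None else list(names)
    out = [
        "@<TRIPOS>MOLECULE",
        molecule_name,
        f"{len(names)} 0 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, (nm, xyz, tp, q) in enumerate(
        zip(names, coordinates, types, charges), start=1
    ):
        out.append(
            f"{i:>4} {nm:<4} {xyz[0]:>10.4f} {xyz[1]:>10.4f} {xyz[2]:>10.4f} "
            f"{tp:<6} 1 RES1 {q:>9.4f}"
        )
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# time series / window manifests / PMF

def write_timeseries(path: str | Path, ts: TimeSeries) -> None:
    """Two-column TSV (step, value) with a # header carrying the metadata."""
    meta = " ".join(f"{k}={v}" for k, v in sorted(ts.metadata.items()))
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        fh.write("# step\tvalue\n")
        for i, v in enumerate(ts.values):
            fh.write(f"{i}\t{v:.10g}\n")


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def read_timeseries(path: str | Path) -> TimeSeries:
    """Inverse of :func:`write_timeseries`."""
    meta: dict = {}
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = _coerce(v)
                continue
            parts = line.split("\t")
            values.append(float(parts[-1]))
    return TimeSeries(np.asarray(values), meta)


def write_window_manifest(
    path: str | Path, restraints: Sequence[RestraintSpec], series_paths: Sequence[str]
) -> None:
    """CSV manifest (window_id, r0, k_rest, path) locating per-window TSVs."""
    df = pd.DataFrame(
        {
            "window_id": range(len(restraints)),
            "r0": [r.r0 for r in restraints],
            "k_rest": [r.k_rest for r in restraints],
            "path": list(series_paths),
        }
    )
    df.to_csv(path, index=False)


def read_windows(manifest_path: str | Path) -> list[Window]:
    """Load umbrella windows from a manifest CSV plus its per-window TSVs."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    windows = []
    for _, row in df.iterrows():
        ts = read_timeseries(manifest_path.parent / str(row["path"]))
        rs = RestraintSpec(k_rest=float(row["k_rest"]), r0=float(row["r0"]))
        windows.append(Window(rs, ts))
    return windows


def write_pmf(path: str | Path, pmf: PMFProfile, temperature: float | None = None) -> None:
    """TSV profile (bin_center, delta_G, n_eff); ΔG printed to 2 decimals."""
    with open(path, "w") as fh:
        if temperature is not None:
            fh.write(f"# temperature={temperature}\n")
        fh.write("# bin_center\tdelta_G\tn_eff\n")
        for c, g, n in zip(pmf.bin_centers, pmf.free_energy, pmf.n_eff):
            g_txt = "nan" if not np.isfinite(g) else f"{g:.2f}"
            fh.write(f"{c:.4f}\t{g_txt}\t{int(n)}\n")


def read_pmf(path: str | Path) -> PMFProfile:
    """Inverse of :func:`write_pmf`."""
    centers, gs, ns = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, g, n = line.split("\t")
            centers.append(float(c))
            gs.append(float(g))
            ns.append(float(n))
    return PMFProfile(
        bin_centers=np.asarray(centers),
        free_energy=np.asarray(gs),
        n_eff=np.asarray(ns),
    )


def write_landmarks(path: str | Path, landmarks: LandmarkSet) -> None:
    """JSON dump of labelled PMF landmarks."""
    payload = {
        "minima": [{"r": r, "delta_G": g} for r, g in landmarks.minima],
        "barriers": [{"r": r, "delta_G": g} for r, g in landmarks.barriers],
        "labels": [
            {"label": lab, "kind": kind, "r": r, "delta_G": g}
            for lab, kind, r, g in landmarks.labels
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# --------------------------------------------------------------------------
# parameter tables

def load_parameter_table(
    toml_path: str | Path, pairs_csv: str | Path | None = None
) -> ParameterTable:
    """Atom types from TOML plus optional explicit pair overrides from CSV.

    TOML schema::

        [atom_types.M]
        charge = 2.0
        c12 = 53144.1
        c6 = 145.8
        alpha0 = 0.0

    CSV columns: type_i, type_j, C12, C6, C4.
    """
    with open(toml_path, "rb") as fh:
        doc = tomllib.load(fh)
    table = ParameterTable()
    for name, entry in doc.get("atom_types", {}).items():
        table.add_type(
            AtomType(
                name=name,
                Q=float(entry.get("charge", 0.0)),
                C12=float(entry.get("c12", 0.0)),
                C6=float(entry.get("c6", 0.0)),
                alpha0=float(entry.get("alpha0", 0.0)),
            )
        )
    if pairs_csv is not None:
        df = pd.read_csv(pairs_csv)
        for _, row in df.iterrows():
            table.set_pair(
                str(row["type_i"]),
                str(row["type_j"]),
                PairParams(
                    C12=float(row["C12"]), C6=float(row["C6"]), C4=float(row["C4"])
                ),
            )
    return table


# --------------------------------------------------------------------------
# packaged target tables (experimental free energies and fitted C4 columns)

def _data_path(name: str):
    return resources.files("lj1264").joinpath("data", name)


def load_binding_table() -> pd.DataFrame:
    """Metal–phosphate binding targets: experimental ΔG_bind, three calculated
    replicates and the refined per-pair C4 values."""
    with resources.as_file(_data_path("binding_replicates.csv")) as p:
        return pd.read_csv(p)


def load_hydration_table() -> pd.DataFrame:
    """Phosphate hydration-free-energy targets (experimental vs calculated)
    and the fitted phosphate-oxygen/water-oxygen C4 values."""
    with resources.as_file(_data_path("hydration_targets.csv")) as p:
        return pd.read_csv(p)


def load_extrapolation_line():
    """The published linear extrapolation used to fill in the missing
    experimental hydration free energy, as a :class:`~lj1264.fitting.RegressionLine`."""
    from .fitting import RegressionLine

    with resources.as_file(_data_path("hydration_extrapolation.json")) as p:
        doc = json.loads(Path(p).read_text())
    return RegressionLine(slope=doc["slope"], intercept=doc["intercept"])
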