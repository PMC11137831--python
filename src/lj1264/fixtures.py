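"""Deterministic fixture generation: everything the pipelines consume can be
produced offline from a :class:`FixtureSpec` (same spec → byte-identical files).

Kinds:

* ``phosphate_mol2`` — a synthetic 5-site phosphate-like geometry (central
  phosphorus + 4 tetrahedral oxygens) with charges summing exactly to −1,
  −2 or −3 depending on the protonation state; a stand-in for
  quantum-chemistry-derived mol2 inputs.
* ``doublewell_us`` / ``ion_pair_us`` — umbrella-window manifests plus
  per-window biased time series sampled from the corresponding toy system.
* ``harmonic_ti`` — per-node dU/dλ series for the harmonic spring-constant
  switch plus the λ schedule as JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .io import write_mol2, write_timeseries, write_window_manifest
from .sampling import LinearMixPath, SamplerConfig, sample_dudl
from .systems import DoubleWell1D, Harmonic1D, IonPairContinuum
from .ti import gauss_legendre_unit
from .wham import plan_windows, run_umbrella

__all__ = ["FixtureSpec", "make_fixture"]

#: net charge by protonation state of the phosphate-like fixture
_PHOSPHATE_CHARGES = {
    "h2po4": -1.0,
    "hpo4": -2.0,
    "po4": -3.0,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Which fixture to generate, with its parameters and the seed."""

    kind: str
    seed: int = 0
    parameters: dict = field(default_factory=dict)


def _make_phosphate_mol2(spec: FixtureSpec, outdir: Path) -> list[Path]:
    state = spec.parameters.get("state", "h2po4")
    if state not in _PHOSPHATE_CHARGES:
        raise ConfigurationError(
            f"unknown phosphate state {state!r}; choose from {sorted(_PHOSPHATE_CHARGES)}"
        )
    net = _PHOSPHATE_CHARGES[state]
    # central site + 4 oxygens on a tetrahedron of radius 1.6 Å
    r = 1.6
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / math.sqrt(3.0)
    coords = np.vstack([[0.0, 0.0, 0.0], r * verts])
    q_center = 1.0
    q_oxygen = (net - q_center) / 4.0  # exact by construction
    names = ["P", "O1", "O2", "O3", "O4"]
    types = ["p5", "o", "o", "o", "o"]
    charges = [q_center] + [q_oxygen] * 4
    path = outdir / f"{state}_synthetic.mol2"
    write_mol2(path, names, coords, charges, types, molecule_name=f"{state}_synthetic")
    return [path]


def _make_umbrella(spec: FixtureSpec, outdir: Path) -> list[Path]:
    if spec.kind == "doublewell_us":
        system = DoubleWell1D(**spec.parameters.get("system", {}))
        r_min, r_max = 2.0, 9.0
    else:
        system = IonPairContinuum(**spec.parameters.get("system", {}))
        r_min, r_max = 2.0, 11.0
    spacing = spec.parameters.get("spacing", 0.5)
    k_rest = spec.parameters.get("k_rest", 10.0)
    n_steps = spec.parameters.get("n_steps", 22_000)
    restraints = plan_windows(
        spec.parameters.get("r_min", r_min),
        spec.parameters.get("r_max", r_max),
        spacing,
        k_rest,
    )
    cfg = SamplerConfig(n_steps=n_steps, burn_in=n_steps // 10, thin=1, seed=spec.seed)
    windows = run_umbrella(system, restraints, cfg, seed=spec.seed)
    paths = []
    series_names = []
    for i, w in enumerate(windows):
        name = f"window_{i:02d}.tsv"
        write_timeseries(outdir / name, w.series)
        paths.append(outdir / name)
        series_names.append(name)
    manifest = outdir / "windows.csv"
    write_window_manifest(manifest, restraints, series_names)
    paths.append(manifest)
    return paths


def _make_harmonic_ti(spec: FixtureSpec, outdir: Path) -> list[Path]:
    k_from = spec.parameters.get("k_from", 1.0)
    k_to = spec.parameters.get("k_to", 4.0)
    order = spec.parameters.get("order", 12)
    n_steps = spec.parameters.get("n_steps", 22_000)
    schedule = gauss_legendre_unit(order)
    sys_a = Harmonic1D(k=k_from)
    path = LinearMixPath(Harmonic1D(k=k_to))
    paths = []
    for i, lam in enumerate(schedule.nodes):
        cfg = SamplerConfig(
            n_steps=n_steps,
            burn_in=n_steps // 10,
            thin=1,
            seed=int(
                np.random.SeedSequence([spec.seed, 31, i]).generate_state(1)[0]
                % 2**31
            ),
        )
        ts = sample_dudl(sys_a, path, float(lam), cfg)
        name = f"dudl_node_{i:02d}.tsv"
        write_timeseries(outdir / name, ts)
        paths.append(outdir / name)
    sched_path = outdir / "schedule.json"
    sched_path.write_text(
        json.dumps(
            {
                "nodes": schedule.nodes.tolist(),
                "weights": schedule.weights.tolist(),
            },
            indent=2,
        )
        + "\n"
    )
    paths.append(sched_path)
    return paths


_MAKERS = {
    "phosphate_mol2": _make_phosphate_mol2,
    "doublewell_us": _make_umbrella,
    "ion_pair_us": _make_umbrella,
    "harmonic_ti": _make_harmonic_ti,
}


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> list[Path]:
    """Generate the fixture files for ``spec`` under ``outdir``; returns the paths."""
    try:
        maker = _MAKERS[spec.kind]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture kind {spec.kind!r}; choose from {sorted(_MAKERS)}"
        ) from None
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return maker(spec, outdir)
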