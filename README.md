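# lj1264

Free-energy-based parametrization of the **12-6-4 Lennard-Jones nonbonded
model** for ion–ligand interactions, at desk scale.

Divalent metal ions such as Ca²⁺ and Mg²⁺ coordinate phosphate groups in
DNA/RNA backbones, nucleotides and phospholipids, but fixed-point-charge
12-6 LJ force fields cannot describe these contacts well because they lack
polarization. The 12-6-4 model adds an ion–induced-dipole term:

    U(r) = C12/r¹² − C6/r⁶ − C4/r⁴ + k_C·Q_i·Q_j/(ε·r)

where the per-pair **C4** coefficient is the tunable polarization
cross-term (positive = attractive). Parametrizing C4 means solving an
inverse problem: adjust C4 until a simulated free energy — a hydration
free energy from thermodynamic integration (TI), or a binding free energy
from an umbrella-sampling potential of mean force (PMF) — matches an
experimental target.

`lj1264` implements that entire workflow as a self-contained, exactly
seedable toolkit for method development and validation:

* **potentials** — 12-6-4 + Coulomb pair energies, forces, parameter
  tables, and the λ-dependent soft-core form used for alchemical
  decoupling;
* **sampling** — Metropolis Monte Carlo on built-in toy systems (harmonic,
  double well, ion pair in a dielectric continuum, periodic
  micro-solvation box), bit-reproducible from a single seed;
* **ti** — Gauss–Legendre λ schedules (the familiar 12-window list
  0.00922 … 0.99078), TI assembly with blocked standard errors, and
  one-step / split-leg (vdW → polarization → electrostatics) solvation
  cycles;
* **wham** — umbrella-window planning, overlap diagnostics, a log-space
  WHAM solver, binding-ΔG extraction (well minimum minus unbound plateau)
  and labelled PMF landmark detection;
* **fitting** — bisection on C4 with common random numbers against target
  free energies, replicate statistics (mean ± sample std), Ka → ΔG
  conversion, and the linear-regression extrapolation used for missing
  experimental hydration values;
* **io / cli** — mol2 (TRIPOS subset), TSV series, CSV manifests,
  TOML parameter tables, deterministic fixture generators, and a
  `lj1264` command-line tool (`gen-lambda`, `run-ti`, `run-us`, `wham`,
  `pmf`, `fit-c4`, `make-fixture`).

Every estimator is validated against an analytic oracle (closed-form
harmonic free energies, an exact double-well PMF, Gaussian window-overlap
integrals, quadrature exactness) and against independent estimators
(exponential averaging vs TI; one-step vs two-step state-function
agreement). See `docs/methods.md` for the models, defaults and
limitations.

## Worked example: fit C4 to a binding free energy

Fit the ion-pair toy system's C4 so its umbrella-sampling binding free
energy matches a target of −3.70 kcal/mol (the experimental scale for a
divalent-metal/phosphate pair), with three replicate seeds:

```python
import lj1264 as lj

system = lj.IonPairContinuum()          # M²⁺ / phosphate-like site, ε = 78.4
target = lj.FitTarget(target_dG=-3.70, observable="binding_pmf")
result = lj.fit_c4(system, target, bracket=(-300.0, 200.0), seeds=(1, 2, 3))
print(f"C4 = {result.C4_fit:.2f} kcal·Å⁴/mol")
print(f"dG = {result.mean:.2f} ± {result.std:.2f} kcal/mol "
      f"({result.n_evaluations} pipeline evaluations)")
print([round(v, 2) for v in result.replicate_values])
```

Output:

```
C4 = 43.75 kcal·Å⁴/mol
dG = -3.47 ± 0.02 kcal/mol (6 pipeline evaluations)
[-3.44, -3.48, -3.48]
```

Each of the six evaluations ran 19 umbrella windows (2–11 Å, 0.5 Å
spacing, 5×10⁴ samples each), solved WHAM for the PMF, and read off the
bound-well depth relative to the unbound plateau. The replicate mean
−3.47 kcal/mol is within the 0.30 kcal/mol binding tolerance of the
target, and ±0.02 is the sample standard deviation across the three
seeds. The same call with `observable="hfe_ti"` on a
`MicroSolvationBox` fits C4 against a TI solvation free energy at a
0.05 kcal/mol tolerance.

From the shell, the λ schedule used by the TI pipeline is:

```sh
$ lj1264 gen-lambda --n 12 | head -3
0.00922	0.02359
0.04794	0.05347
0.11505	0.08004
```

## Scope

The package validates the *procedure* on toy systems with analytic
oracles. Production explicit-water simulations (PME, NPT, SHAKE, GAFF
topologies, QM charge derivation) and the absolute published C4 values
that depend on them are out of scope; the packaged data tables carry the
published experimental targets and fitted values as inputs and test
fixtures.
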