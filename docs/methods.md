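# Methods

This note documents the models, numerical choices and limitations behind
`lj1264`. It is the companion to the API documentation: everything here is
either implemented and tested in the package or explicitly listed as out of
scope.

## The 12-6-4 nonbonded model

The pair energy between atoms *i* and *j* is

    U(r) = C12/r¹² − C6/r⁶ − C4/r⁴ + k_C·Q_i·Q_j/(ε·r)

in kcal/mol with r in Å, charges in units of the elementary charge,
k_C = 332.0637 kcal·Å/(mol·e²), and R = 1.9872×10⁻³ kcal/(mol·K) wherever a
gas constant is needed. The r⁻⁴ term models the ion–induced-dipole
(polarization) attraction that a fixed-point-charge 12-6 model cannot
express; C4 enters the energy as −C4/r⁴, so positive C4 is attractive and a
negative tabulated C4 is a repulsive correction.

C4 is a *per-pair* quantity and the primary fitted parameter of the whole
toolkit. No combining rule is ever applied to it. The helper
`c4_from_polarizability` implements the ion–induced-dipole convention
C4 = k_C·Q²·α₀/2 (a point charge Q produces the field E = Q/r², and the
induced-dipole energy −α₀E²/2 contributes −C4/r⁴). The proportionality
constant is a modelling convention of this package: fitted C4 values are
used directly, and this relation serves for initial guesses and for
converting a fitted C4 back to an effective polarizability.

Configuration energies use plain truncation at the configured cutoff
(default 12 Å) with the minimum-image convention for periodic systems. No
Ewald/PME, no switching function, no long-range correction, no bonded
terms: the simplest fully reproducible contract.

## Soft-core decoupling

Alchemically growing or removing a particle with the plain potential
diverges at the end points ("end-point catastrophe"). The package uses the
standard soft-core modification of the 12-6 part,

    U_sc(λ, r) = λ·4ε·[ (α(1−λ) + (r/σ)⁶)⁻² − (α(1−λ) + (r/σ)⁶)⁻¹ ],

with α = 0.5, ε = C6²/(4·C12) and σ = (C12/C6)^(1/6) the distance at which
the unmodified potential crosses zero. U_sc is exactly the plain 12-6
energy at λ = 1, exactly zero at λ = 0, and finite at r = 0 for λ < 1.

The C4 and Coulomb components are scaled linearly by their own coupling
parameter, but evaluated at the soft-core effective distance

    r_sc⁶ = α·(1−λ_vdW)·σ⁶ + r⁶.

When the vdW coupling is full (λ_vdW = 1) this reduces exactly to the plain
−C4/r⁴ and Coulomb terms, so the split-leg protocol below sees plain linear
scaling. On the one-step path, where all components share one λ, the
softened distance is essential: scaling the bare r⁻⁴ and r⁻¹ attractions
linearly against a softened repulsion lets solvent collapse onto the solute
at small λ and the free energy diverges. (We observed exactly this failure
mode before adopting the softened-distance pathway.)

## Thermodynamic integration

Free-energy differences are computed as ΔG = ∫₀¹ ⟨dU/dλ⟩ dλ, evaluated
with an n-point Gauss–Legendre rule mapped to [0,1] (default n = 12; the
familiar 12-window λ list 0.00922 … 0.99078 is this rule printed to five
decimals). The rule is exact for polynomial integrands up to degree 2n−1;
weights sum to one on the unit interval; rounding happens only at
presentation.

Two solvation protocols are implemented, both paths between the same end
states (decoupled ↔ fully coupled solute):

* **one-step** — soft-core vdW, C4 and Coulomb all follow a single λ;
* **two-step** (split legs) — (1) grow the soft-core vdW cavity with C4 and
  charges off, (2) switch on C4, (3) switch on the charges. This order
  avoids any state with bare charges and no repulsive core. The component
  order is this package's choice; only the fact that the components are
  scaled separately is inherited from the protocol being modelled.

Because free energy is a state function the two protocols must agree within
statistical error; this is tested, and is the strongest internal
consistency check the package has.

dU/dλ is evaluated analytically for linear parameter mixing
(U_B − U_A) and by a central difference in λ (h = 10⁻⁴) for the nonlinear
soft-core legs. The gas-phase reference leg of the closed solvation cycle
is exactly zero for a single-bead solute (no intramolecular terms), so it
is taken analytically rather than simulated with a huge cutoff.

Per-node standard errors use block averaging. The block size defaults to
n/50 (minimum 100) so that blocks stay longer than the sampler's
autocorrelation time as chains grow; a fixed small block underestimates
the error of slowly decorrelating observables several-fold. The SE of the
quadrature sum is sqrt(Σ w_i²·se_i²), and leg SEs add in quadrature.

## Monte Carlo sampling

All observables here depend only on the equilibrium Boltzmann
distribution, so Metropolis Monte Carlo replaces molecular dynamics: it is
simpler, exactly seedable, and needs no thermostat or barostat. Proposals
are single-particle uniform displacements with per-system default step
sizes chosen to keep acceptance in a healthy band (guarded by a test at
0.2–0.8). All randomness is pre-drawn from one numpy Generator per chain,
so identical seed + configuration gives bit-identical output, independent
of the compiled kernel's internals.

The solvation box additionally uses uniform-reinsertion ("teleport")
proposals for a fraction (default 0.15) of the moves. These are symmetric
proposals, so the plain Metropolis acceptance rule applies; they cut the
autocorrelation time of the solvent composition around the solute by about
an order of magnitude, which is what makes honest error bars affordable at
desk scale.

Chain defaults: burn-in 10% of the chain, thinning 10 for coordinate
sampling. The dU/dλ and umbrella pipelines record every post-burn-in step
(thinning 1) and leave correlation handling to block averaging, which is
cheaper than discarding samples.

## Toy systems

* **harmonic1d** (½k(x−x₀)², k = 0 gives a flat line) — closed-form
  moments: ⟨x²⟩ = k_BT/k, ΔF(k₁→k₂) = ½k_BT·ln(k₂/k₁). The oracle for the
  sampler and for TI.
* **doublewell1d** — U = h((x−c)²−w²)²/w⁴ with minima at c±w (defaults:
  barrier 4 kcal/mol at 5.5 Å, minima at 3.5 and 7.5 Å, hard walls at 1.5
  and 9.5 Å). The analytic oracle for umbrella sampling + WHAM.
* **ion_pair_continuum** — a divalent cation against a singly charged
  phosphate-like site along their distance, screened by a dielectric
  continuum (ε = 78.4), 12-6 parameters giving a contact well near 3 Å
  (C12 = 53144.1, C6 = 145.8) and a tunable C4 (default 60). Energy scale:
  a binding well of a few kcal/mol, matching the magnitudes of aqueous
  metal–phosphate association. The binding free energy is monotone
  non-increasing in C4 over the fitted bracket, the property the fitting
  module relies on.
* **micro_solvation_box** — one solute ion among 15 Lennard-Jones solvent
  beads (Rmin 3.2 Å, ε 0.12) carrying small alternating ±0.02 e charges
  (net zero) in a 10 Å periodic cube with a 4.9 Å cutoff, NVT only. The
  solute (q = +0.5, 12-6 cross parameters Rmin ≈ 3.1 Å / ε ≈ 0.12, C4
  default 40) couples through the switchable terms above. These conditions
  were chosen once so that the solvation free energy is ≈ −4 kcal/mol with
  kT-scale fluctuations, letting 10⁵ samples per node support a ±0.05
  kcal/mol fit criterion. The box emulates the *role* of an explicit-water
  box in the workflow — it is not water: no hydrogen-bond network, no
  dielectric response, fixed density, no NPT.

## Umbrella sampling and WHAM

Windows are planned on an even grid (defaults: 0.5 Å spacing, force
constant 10 kcal/(mol·Å²), giving ~0.25 Å window widths at 300 K and
healthy neighbour overlap). `check_overlap` computes the histogram overlap
coefficient Σ min(p_i, p_j) per adjacent pair and flags pairs below 0.05 —
the quantitative form of the "neighbouring windows must overlap" rule of
thumb used when restraint constants are tuned by hand.

WHAM iterates the standard self-consistent equations in log space
(logsumexp throughout) until the largest change in any window offset falls
below the tolerance (default 10⁻⁷ kcal/mol; bin width 0.05 Å, fine enough
to resolve sub-Å PMF structure; iteration cap 10⁵ with the residual
reported on failure). Bins with fewer than 10 counts are flagged as gaps,
never interpolated. The stored PMF is referenced to its sampled minimum.

The binding free energy is read off the profile as

    ΔG_bind = min G(r ≤ r_bound) − mean G(plateau),

with the plateau defaulting to the outermost 15% of the sampled range and
a flatness check (warning if |slope| > 0.1 kcal/mol/Å). A one-dimensional
standard-state-style correction, −k_BT·ln(∫_bound e^(−βG′) dr / 1 Å), is
computed and reported separately but never silently added: calculated
profile depths are compared directly to experimental binding free
energies, so the default definition must remain the raw depth.

Landmark detection (labelled minima/barriers A, B, C, … along r) smooths
with a 3-bin moving average *only* for the extremum search — reported ΔG
values come from the unsmoothed profile — enforces strict alternation, and
ignores behaviour at the sampling boundaries.

## Fitting C4

`fit_c4` solves ΔG(C4) = target by bisection with common random numbers:
every objective evaluation runs the full pipeline (TI solvation or
umbrella + WHAM binding) with the same fixed replicate seeds, making the
objective deterministic in C4. Three replicate seeds are the default; the
fit criterion is the replicate mean, and results report mean ± sample
(n−1) standard deviation, rounded to two decimals only at presentation.
Default tolerances are 0.05 kcal/mol for TI solvation targets and 0.30
kcal/mol for umbrella-sampling binding targets — the agreement levels the
two pipelines support. If the bracket collapses before the tolerance is
met, the error reports the best achievable deviation (the noise floor).

A monotonicity pre-scan (5 points across the bracket, compared within 3×
replicate noise) is available via `scan_points`; it is off by default
because each scan point costs a full replicate pipeline evaluation, and
the bracket-end straddle check already catches gross non-monotonicity.
Whether to spend ~70% more pipeline time on the guard is left to the
caller.

`ka_to_dg` converts association constants (ΔG = −RT·ln Ka, default
T = 298 K); `fit_regression`/`extrapolate` provide the ordinary
least-squares line used to fill in a missing experimental hydration value
from quantum-chemistry calculations (the packaged line is
y = 1.0763·x − 22.984).

## What desk scale does and does not show

The packaged data tables carry the published experimental/calculated free
energies and fitted C4 values for the metal–phosphate systems; they are
inputs and aggregation-test fixtures. The toolkit does **not** attempt to
reproduce those absolute C4 values: they belong to multi-ns explicit-water
simulations. What the toy systems validate is the *machinery* — schedule
construction, estimator correctness against closed forms, state-function
consistency, WHAM fidelity, and the convergence behaviour of the fitting
loop at its stated tolerances. Passing here means the procedure is
implemented correctly; transferring a fitted C4 to a real force field
still requires the full-scale simulations this package deliberately leaves
out (explicit water, PME, NPT, SHAKE, GAFF topologies, QM charge
derivation).

## Problem sizes used in validation

Validation runs use 12-node schedules with 10⁵ samples per node (TI), 15–19
umbrella windows with 5×10⁴ samples per window (WHAM/binding), and 3
replicate seeds per fit evaluation — sizes at which every stated tolerance
is met with margin on a single CPU in minutes.
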