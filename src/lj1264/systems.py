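"""Built-in toy systems: the desk-scale stand-ins for explicit-solvent MD.

Every observable this toolkit computes (free-energy differences, potentials
of mean force) depends only on the equilibrium Boltzmann distribution, so
small exactly-seedable Metropolis Monte Carlo systems stand in for the
production molecular-dynamics boxes of a real parametrization campaign:

* :class:`Harmonic1D` — a harmonic (or, with k=0, flat) 1-D coordinate with
  closed-form moments; the oracle system for TI and sampler statistics.
* :class:`DoubleWell1D` — a quartic double well with analytic minima and
  barrier; the oracle system for umbrella sampling + WHAM.
* :class:`IonPairContinuum` — a divalent cation and a phosphate-like charged
  site interacting through the 12-6-4 potential in a dielectric continuum;
  the distance coordinate plays the role of the metal–phosphorus reaction
  coordinate, and its binding free energy is monotone in C4 (the basis of
  the fitting module).
* :class:`MicroSolvationBox` — a single ion solvated by ≤ 32 neutral-total
  Lennard-Jones beads (alternating small ± charges) in a periodic cube; the
  system on which the alchemical hydration-free-energy cycles run.

Default parameters are chosen once to mimic the energy scales of aqueous
metal–phosphate systems (well depths of a few kcal/mol, Å-scale structure)
and are documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import ClassVar

import numpy as np

from .constants import COULOMB_CONSTANT
from .errors import DomainError
from .potentials import PairParams

__all__ = [
    "ToySystem",
    "Harmonic1D",
    "DoubleWell1D",
    "IonPairContinuum",
    "MicroSolvationBox",
    "make_system",
]


@dataclass(frozen=True)
class ToySystem:
    """Base class: a named toy system with a finite energy on its domain."""

    kind: ClassVar[str] = "abstract"
    #: default Metropolis displacement half-width (Å), tuned per system so
    #: acceptance stays in a healthy band
    default_step: ClassVar[float] = 0.5

    @property
    def parameters(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class Harmonic1D(ToySystem):
    """U(x) = ½·k·(x − x0)²; k = 0 gives a flat potential."""

    k: float = 1.0
    x0: float = 0.0

    kind: ClassVar[str] = "harmonic1d"
    default_step: ClassVar[float] = 1.2

    def __post_init__(self) -> None:
        if self.k < 0:
            raise DomainError("harmonic k must be non-negative")

    def energy(self, x: float) -> float:
        return 0.5 * self.k * (x - self.x0) ** 2

    def kernel_params(self) -> tuple[int, np.ndarray]:
        return 0, np.array([self.k, self.x0], dtype=float)

    def initial_state(self) -> float:
        return self.x0


@dataclass(frozen=True)
class DoubleWell1D(ToySystem):
    """Quartic double well U(x) = h·((x−c)² − w²)²/w⁴ with hard walls.

    Minima at c ± w (U = 0), barrier of height h at x = c.
    """

    barrier: float = 4.0
    center: float = 5.5
    half_width: float = 2.0
    wall_lo: float = 1.5
    wall_hi: float = 9.5

    kind: ClassVar[str] = "doublewell1d"
    default_step: ClassVar[float] = 0.45

    def __post_init__(self) -> None:
        if self.barrier <= 0 or self.half_width <= 0:
            raise DomainError("double well requires positive barrier and half_width")
        if not self.wall_lo < self.center - self.half_width < self.center + self.half_width < self.wall_hi:
            raise DomainError("walls must enclose both wells")

    def energy(self, x: float) -> float:
        if x < self.wall_lo or x > self.wall_hi:
            return math.inf
        d = (x - self.center) ** 2 - self.half_width**2
        return self.barrier * d * d / self.half_width**4

    @property
    def minima(self) -> tuple[float, float]:
        return (self.center - self.half_width, self.center + self.half_width)

    def kernel_params(self) -> tuple[int, np.ndarray]:
        return 1, np.array(
            [self.barrier, self.center, self.half_width, self.wall_lo, self.wall_hi],
            dtype=float,
        )

    def initial_state(self) -> float:
        return self.center - self.half_width


@dataclass(frozen=True)
class IonPairContinuum(ToySystem):
    """A cation–anion pair in a dielectric continuum along their distance r.

    U(r) = C12/r¹² − C6/r⁶ − C4/r⁴ + k_C·q_ion·q_site/(ε·r), with hard walls
    confining the coordinate.  Defaults model a divalent metal against a
    singly charged phosphate-like oxygen site screened by water (ε ≈ 78.4):
    a contact well a few kcal/mol deep near r ≈ 3 Å and a nearly flat tail
    at 10–12 Å.
    """

    pair: PairParams = field(
        default_factory=lambda: PairParams(C12=53144.1, C6=145.8, C4=60.0)
    )
    q_ion: float = 2.0
    q_site: float = -1.0
    dielectric: float = 78.4
    wall_lo: float = 1.8
    wall_hi: float = 12.0

    kind: ClassVar[str] = "ion_pair_continuum"
    default_step: ClassVar[float] = 0.35

    def __post_init__(self) -> None:
        if self.dielectric < 1:
            raise DomainError("dielectric must be >= 1")
        if not 0 < self.wall_lo < self.wall_hi:
            raise DomainError("walls must satisfy 0 < wall_lo < wall_hi")

    def energy(self, r: float) -> float:
        if r <= 0 or r < self.wall_lo or r > self.wall_hi:
            return math.inf
        p = self.pair
        return (
            p.C12 / r**12
            - p.C6 / r**6
            - p.C4 / r**4
            + COULOMB_CONSTANT * self.q_ion * self.q_site / (self.dielectric * r)
        )

    def with_c4(self, c4: float) -> "IonPairContinuum":
        return replace(self, pair=replace(self.pair, C4=c4))

    def kernel_params(self) -> tuple[int, np.ndarray]:
        p = self.pair
        return 2, np.array(
            [
                p.C12,
                p.C6,
                p.C4,
                self.q_ion * self.q_site,
                self.dielectric,
                self.wall_lo,
                self.wall_hi,
            ],
            dtype=float,
        )

    def initial_state(self) -> float:
        return 3.0


@dataclass(frozen=True)
class MicroSolvationBox(ToySystem):
    """One solute ion among LJ solvent beads in a periodic cube (NVT).

    Solvent beads interact through a plain 12-6 potential plus Coulomb terms
    from small alternating ± charges (net zero); the solute couples to every
    solvent bead through the λ-switchable soft-core vdW, C4 polarization and
    Coulomb terms.  The density is fixed by construction (no barostat).
    """

    n_particles: int = 16
    box_edge: float = 10.0
    cutoff: float = 4.9
    solvent_rmin: float = 3.2
    solvent_eps: float = 0.12
    solvent_charge: float = 0.02
    solute_pair: PairParams = field(
        default_factory=lambda: PairParams(C12=87480.0, C6=204.12, C4=40.0)
    )
    solute_charge: float = 0.5
    alpha_sc: float = 0.5
    dielectric: float = 1.0
    #: fraction of Monte Carlo proposals that are uniform reinsertions
    #: (symmetric teleport moves that decorrelate the solvation structure)
    jump_fraction: float = 0.15

    kind: ClassVar[str] = "micro_solvation_box"
    default_step: ClassVar[float] = 0.65

    def __post_init__(self) -> None:
        if not 2 <= self.n_particles <= 32:
            raise DomainError("micro-solvation box supports 2..32 particles")
        if self.cutoff * 2 > self.box_edge:
            raise DomainError("cutoff must not exceed half the box edge")

    @property
    def solvent_c12(self) -> float:
        return self.solvent_eps * self.solvent_rmin**12

    @property
    def solvent_c6(self) -> float:
        return 2.0 * self.solvent_eps * self.solvent_rmin**6

    def with_c4(self, c4: float) -> "MicroSolvationBox":
        return replace(self, solute_pair=replace(self.solute_pair, C4=c4))

    def charges(self) -> np.ndarray:
        """Solute charge followed by alternating ±solvent_charge beads."""
        q = np.empty(self.n_particles)
        q[0] = self.solute_charge
        n_solv = self.n_particles - 1
        for i in range(n_solv):
            q[i + 1] = self.solvent_charge if i % 2 == 0 else -self.solvent_charge
        if n_solv % 2 == 1:  # keep the solvent net-neutral
            q[-1] = 0.0
        return q

    def initial_positions(self) -> np.ndarray:
        """Deterministic cubic-lattice start covering the box."""
        per_side = math.ceil(self.n_particles ** (1.0 / 3.0))
        spacing = self.box_edge / per_side
        pos = np.empty((self.n_particles, 3))
        n = 0
        for i in range(per_side):
            for j in range(per_side):
                for k in range(per_side):
                    if n == self.n_particles:
                        break
                    pos[n] = (
                        (i + 0.5) * spacing,
                        (j + 0.5) * spacing,
                        (k + 0.5) * spacing,
                    )
                    n += 1
        return pos


_SYSTEMS = {
    cls.kind: cls
    for cls in (Harmonic1D, DoubleWell1D, IonPairContinuum, MicroSolvationBox)
}


def make_system(kind: str, **params) -> ToySystem:
    """Construct a built-in toy system by kind name."""
    try:
        cls = _SYSTEMS[kind]
    except KeyError:
        raise DomainError(
            f"unknown toy system {kind!r}; choose from {sorted(_SYSTEMS)}"
        ) from None
    return cls(**params)
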