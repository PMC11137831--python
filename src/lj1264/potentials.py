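"""Pairwise 12-6-4 Lennard-Jones + Coulomb energies and the soft-core form.

The 12-6-4 nonbonded model augments the familiar 12-6 LJ potential with an
r⁻⁴ term that captures the ion–induced-dipole (polarization) attraction that
point-charge models miss::

    U(r) = C12/r¹² − C6/r⁶ − C4/r⁴ + k_C·Q_i·Q_j/(ε·r)

Sign convention: C4 enters the energy as ``−C4/r⁴``, so a *positive* C4 is
attractive and a negative tabulated C4 is a repulsive correction.  Pair
coefficients are stored explicitly per pair; no combining rule is ever
applied to C4, because C4 is the per-pair quantity this toolkit fits.

The λ-dependent soft-core variant of the 12-6 part removes the r→0
singularity at intermediate coupling ("end-point catastrophe") and is exactly
the plain 12-6 potential at λ=1 and exactly zero at λ=0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import COULOMB_CONSTANT
from .errors import ConfigurationError, ContractError, DomainError

__all__ = [
    "AtomType",
    "PairParams",
    "SoftCoreSpec",
    "Configuration",
    "ParameterTable",
    "lj124_pair_energy",
    "coulomb_pair_energy",
    "c4_from_polarizability",
    "lj_sigma",
    "lj124_pair_dudr",
    "softcore_vdw",
    "total_energy",
    "total_forces",
]


@dataclass(frozen=True)
class AtomType:
    """A nonbonded atom type: partial charge, self 12-6 coefficients, polarizability.

    ``alpha0`` (Å³) may be any real number — it is a tuned quantity in this
    model and a negative fitted value simply encodes a repulsive correction.
    """

    name: str
    Q: float = 0.0
    C12: float = 0.0
    C6: float = 0.0
    alpha0: float = 0.0

    def __post_init__(self) -> None:
        if self.C12 < 0 or self.C6 < 0:
            raise DomainError(
                f"atom type {self.name!r}: C12 and C6 must be non-negative"
            )


@dataclass(frozen=True)
class PairParams:
    """Explicit pair coefficients C12 (kcal·Å¹²/mol), C6 (kcal·Å⁶/mol), C4 (kcal·Å⁴/mol).

    C4 is signed; C12 and C6 must be non-negative.
    """

    C12: float = 0.0
    C6: float = 0.0
    C4: float = 0.0

    def __post_init__(self) -> None:
        if self.C12 < 0 or self.C6 < 0:
            raise DomainError("pair parameters: C12 and C6 must be non-negative")


@dataclass(frozen=True)
class SoftCoreSpec:
    """Soft-core coupling state: λ ∈ [0,1], softness α (default 0.5), optional σ.

    ``sigma`` is the distance at which the unmodified 12-6 potential crosses
    zero; when omitted it is derived from the pair coefficients as
    (C12/C6)^(1/6).
    """

    lam: float
    alpha_sc: float = 0.5
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise DomainError(f"lambda must be in [0,1], got {self.lam}")
        if self.alpha_sc <= 0:
            raise DomainError(f"alpha_sc must be positive, got {self.alpha_sc}")
        if self.sigma is not None and self.sigma <= 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")


@dataclass
class Configuration:
    """Particle positions (Å) with per-particle atom-type labels.

    ``box`` is an optional cubic edge length; when present the minimum-image
    convention applies to pair distances.
    """

    coordinates: np.ndarray
    types: Sequence[str]
    box: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ContractError(
                f"coordinates must have shape (N, 3), got {self.coordinates.shape}"
            )
        if len(self.types) != len(self.coordinates):
            raise DomainError("coordinates and types must have equal length")
        if self.box is not None and self.box <= 0:
            raise DomainError("box edge must be positive")

    def __len__(self) -> int:
        return len(self.coordinates)


class ParameterTable:
    """Atom types plus explicit pair coefficients.

    Same-type pairs default to the atom type's own (C12, C6) with C4 = 0;
    cross pairs must be entered explicitly (the C4 cross-term is the fitted
    quantity of this model and is never produced by a combining rule).
    """

    def __init__(
        self,
        atom_types: Iterable[AtomType] = (),
        pairs: Mapping[tuple[str, str], PairParams] | None = None,
    ):
        self.atom_types: dict[str, AtomType] = {t.name: t for t in atom_types}
        self.pairs: dict[tuple[str, str], PairParams] = {}
        for (a, b), p in (pairs or {}).items():
            self.set_pair(a, b, p)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_type(self, t: AtomType) -> None:
        self.atom_types[t.name] = t

    def set_pair(self, a: str, b: str, p: PairParams) -> None:
        self.pairs[self._key(a, b)] = p

    def charge(self, name: str) -> float:
        try:
            return self.atom_types[name].Q
        except KeyError:
            raise ConfigurationError(f"unknown atom type {name!r}") from None

    def pair(self, a: str, b: str) -> PairParams:
        key = self._key(a, b)
        if key in self.pairs:
            return self.pairs[key]
        if a == b and a in self.atom_types:
            t = self.atom_types[a]
            return PairParams(C12=t.C12, C6=t.C6, C4=0.0)
        raise ConfigurationError(
            f"no pair parameters for pair ({a!r}, {b!r}); "
            "cross pairs must be listed explicitly"
        )


def lj124_pair_energy(r: float, p: PairParams) -> float:
    """12-6-4 pair energy C12/r¹² − C6/r⁶ − C4/r⁴ in kcal/mol (r in Å)."""
    if r <= 0:
        raise DomainError(f"pair distance must be positive, got {r}")
    r2 = r * r
    r4 = r2 * r2
    r6 = r4 * r2
    return p.C12 / (r6 * r6) - p.C6 / r6 - p.C4 / r4


def coulomb_pair_energy(
    r: float, qi: float, qj: float, dielectric: float = 1.0
) -> float:
    """Coulomb pair energy k_C·Q_i·Q_j/(ε·r) in kcal/mol."""
    if r <= 0:
        raise DomainError(f"pair distance must be positive, got {r}")
    if dielectric < 1:
        raise DomainError(f"dielectric must be >= 1, got {dielectric}")
    return COULOMB_CONSTANT * qi * qj / (dielectric * r)


def c4_from_polarizability(alpha0: float, q_partner: float) -> float:
    """Ion–induced-dipole C4 = k_C·Q²·α₀/2 in kcal·Å⁴/mol.

    A point charge Q at distance r produces a field E = Q/r² (in e/Å²); the
    induced-dipole energy −α₀E²/2 then contributes −C4/r⁴ with
    C4 = k_C·Q²·α₀/2.  The proportionality constant is a modelling
    convention of this toolkit: in practice C4 is the directly fitted
    per-pair quantity and this relation is used for initial guesses and for
    converting a fitted C4 back to an effective polarizability.
    """
    return 0.5 * COULOMB_CONSTANT * q_partner * q_partner * alpha0


def lj_sigma(p: PairParams) -> float:
    """Zero-crossing distance σ = (C12/C6)^(1/6) of the unmodified 12-6 form."""
    if p.C12 <= 0 or p.C6 <= 0:
        raise DomainError("sigma requires strictly positive C12 and C6")
    return (p.C12 / p.C6) ** (1.0 / 6.0)


def softcore_vdw(r: float, sc: SoftCoreSpec, p: PairParams) -> float:
    """λ-dependent soft-core 12-6 energy, finite at r=0 for λ<1.

    Form: U_sc = λ·4ε·[(α(1−λ) + (r/σ)⁶)⁻² − (α(1−λ) + (r/σ)⁶)⁻¹] with
    ε = C6²/(4·C12) and σ the 12-6 zero crossing, so that U_sc(λ=1) is exactly
    the plain 12-6 energy and U_sc(λ=0) ≡ 0.  Applies to the 12-6 part only;
    C4 and Coulomb terms are scaled linearly by λ in their own legs.

    Degenerate coefficients (C12 or C6 zero) fall back to linear λ-scaling of
    whatever 12-6 part remains, preserving both endpoint identities.
    """
    if r < 0:
        raise DomainError(f"distance must be non-negative, got {r}")
    lam = sc.lam
    if lam == 0.0:
        return 0.0
    if p.C12 <= 0.0 and p.C6 <= 0.0:
        return 0.0
    if p.C12 <= 0.0 or p.C6 <= 0.0:
        if r == 0.0:
            raise DomainError("degenerate soft-core fallback requires r > 0")
        r6 = r**6
        return lam * (p.C12 / (r6 * r6) - p.C6 / r6)
    sigma = sc.sigma if sc.sigma is not None else lj_sigma(p)
    eps4 = p.C6 * p.C6 / p.C12  # 4·ε
    d = sc.alpha_sc * (1.0 - lam) + (r / sigma) ** 6
    return lam * eps4 * (1.0 / (d * d) - 1.0 / d)


def lj124_pair_dudr(
    r: float, p: PairParams, qi: float = 0.0, qj: float = 0.0, dielectric: float = 1.0
) -> float:
    """Radial derivative dU/dr of the 12-6-4 + Coulomb pair energy."""
    if r <= 0:
        raise DomainError(f"pair distance must be positive, got {r}")
    r2 = r * r
    r4 = r2 * r2
    r6 = r4 * r2
    du = (
        -12.0 * p.C12 / (r6 * r6 * r)
        + 6.0 * p.C6 / (r6 * r)
        + 4.0 * p.C4 / (r4 * r)
    )
    if qi != 0.0 and qj != 0.0:
        du -= COULOMB_CONSTANT * qi * qj / (dielectric * r2)
    return du


def _pair_vectors(cfg: Configuration) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique-pair index arrays and minimum-image displacement vectors."""
    n = len(cfg)
    ii, jj = np.triu_indices(n, k=1)
    d = cfg.coordinates[jj] - cfg.coordinates[ii]
    if cfg.box is not None:
        d -= cfg.box * np.round(d / cfg.box)
    return ii, jj, d


def total_energy(
    cfg: Configuration,
    table: ParameterTable,
    cutoff: float = 12.0,
    dielectric: float = 1.0,
) -> float:
    """Sum of 12-6-4 + Coulomb energies over unique pairs within the cutoff.

    Plain truncation at the cutoff; minimum-image convention when the
    configuration is periodic.  Deterministic.
    """
    if len(cfg) < 2:
        return 0.0
    ii, jj, d = _pair_vectors(cfg)
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    e = 0.0
    for a, b, rij in zip(ii, jj, r):
        if rij > cutoff:
            continue
        ta, tb = cfg.types[a], cfg.types[b]
        p = table.pair(ta, tb)
        e += lj124_pair_energy(rij, p)
        qa, qb = table.charge(ta), table.charge(tb)
        if qa != 0.0 and qb != 0.0:
            e += coulomb_pair_energy(rij, qa, qb, dielectric)
    return e


def total_forces(
    cfg: Configuration,
    table: ParameterTable,
    cutoff: float = 12.0,
    dielectric: float = 1.0,
) -> np.ndarray:
    """Analytic forces −∇U for the truncated pair sum, shape (N, 3)."""
    forces = np.zeros_like(cfg.coordinates)
    if len(cfg) < 2:
        return forces
    ii, jj, d = _pair_vectors(cfg)
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    for a, b, vec, rij in zip(ii, jj, d, r):
        if rij > cutoff:
            continue
        ta, tb = cfg.types[a], cfg.types[b]
        p = table.pair(ta, tb)
        dudr = lj124_pair_dudr(
            rij, p, table.charge(ta), table.charge(tb), dielectric
        )
        # vec points from a to b; force on b is −dU/dr · r̂
        f = -dudr * vec / rij
        forces[b] += f
        forces[a] -= f
    return forces
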