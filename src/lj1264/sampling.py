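"""Canonical-ensemble Metropolis Monte Carlo sampling of the toy systems.

The sampler targets exp(−(U + U_bias)/k_BT) with single-particle
uniform-displacement proposals.  All randomness is drawn from a single
numpy Generator seeded from the configuration, so identical seed + config
gives bit-identical output.

dU/dλ observables are evaluated analytically for linear parameter mixing
(U_B − U_A) and by a central difference in λ (h = 1e−4) for the nonlinear
soft-core coupling of the solvation box.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _kernels
from .constants import kt
from .errors import ContractError, DomainError, SamplerError
from .systems import MicroSolvationBox, ToySystem

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "RestraintSpec",
    "TimeSeries",
    "LinearMixPath",
    "CouplingLeg",
    "sample_canonical",
    "sample_dudl",
    "dudl_finite_difference",
]

_BOX_RECORD_MODES = {"vdw": 1, "pol": 2, "ele": 3, "total": 4}


@dataclass(frozen=True)
class SamplerConfig:
    """Chain-length and ensemble settings for one Monte Carlo run.

    ``burn_in`` defaults to 10% of ``n_steps``; ``thin`` keeps every
    ``thin``-th post-burn-in state.  The recorded series has exactly
    ``(n_steps − burn_in) // thin`` entries.
    """

    n_steps: int
    temperature: float = 300.0
    step_size: float | None = None
    seed: int = 0
    burn_in: int | None = None
    thin: int = 10

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")
        if self.thin < 1:
            raise DomainError("thin must be >= 1")
        if self.burn_in is not None and not 0 <= self.burn_in < self.n_steps:
            raise DomainError("need n_steps > burn_in >= 0")
        if self.n_steps < 1:
            raise DomainError("n_steps must be positive")

    @property
    def effective_burn_in(self) -> int:
        return self.n_steps // 10 if self.burn_in is None else self.burn_in

    @property
    def n_samples(self) -> int:
        return (self.n_steps - self.effective_burn_in) // self.thin


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic umbrella bias ½·k_rest·(r − r0)² on a distance coordinate.

    ``offset`` is an additive constant on the bias (physically irrelevant to
    the unbiased profile; exposed to exercise WHAM's translation invariance).
    """

    k_rest: float
    r0: float
    coordinate: str = "r"
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.k_rest <= 0:
            raise DomainError("k_rest must be positive")
        if self.r0 < 0:
            raise DomainError("r0 must be non-negative")

    def energy(self, r: float) -> float:
        return 0.5 * self.k_rest * (r - self.r0) ** 2 + self.offset


@dataclass
class TimeSeries:
    """Ordered scalar observations plus provenance metadata."""

    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ContractError("TimeSeries values must be 1-D")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def acceptance_rate(self) -> float | None:
        return self.metadata.get("acceptance_rate")


@dataclass(frozen=True)
class LinearMixPath:
    """Alchemical path U(λ) = (1−λ)·U_A + λ·U_B between two same-kind systems."""

    end_system: ToySystem


@dataclass(frozen=True)
class CouplingLeg:
    """One λ-coupled component of the solvation cycle: vdw | pol | ele | total."""

    component: str

    def __post_init__(self) -> None:
        if self.component not in _BOX_RECORD_MODES:
            raise DomainError(
                f"unknown coupling component {self.component!r}; "
                f"choose from {sorted(_BOX_RECORD_MODES)}"
            )


def _draws_1d(cfg: SamplerConfig, step: float):
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    disp = rng.uniform(-step, step, cfg.n_steps)
    u01 = rng.random(cfg.n_steps)
    return disp, u01


def _run_1d(
    system: ToySystem,
    cfg: SamplerConfig,
    bias: RestraintSpec | None,
    mix_system: ToySystem | None,
    lam: float,
    record_dudl: bool,
) -> TimeSeries:
    kind, pa = system.kernel_params()
    if mix_system is not None:
        kind_b, pb = mix_system.kernel_params()
        if kind_b != kind:
            raise ContractError("linear mixing requires systems of the same kind")
        mix = True
    else:
        pb = pa
        mix = False
    step = cfg.step_size if cfg.step_size is not None else system.default_step
    bias_k = bias.k_rest if bias is not None else 0.0
    bias_r0 = bias.r0 if bias is not None else 0.0
    x0 = bias.r0 if bias is not None else system.initial_state()
    e0 = system.energy(x0)
    if not math.isfinite(e0):
        raise SamplerError(
            f"non-finite initial energy for {system.kind} at x={x0}"
        )
    disp, u01 = _draws_1d(cfg, step)
    out = np.empty(cfg.n_samples)
    n_acc, x_final = _kernels.chain_1d(
        kind,
        pa,
        pb,
        lam,
        mix,
        bias_k,
        bias_r0,
        float(x0),
        1.0 / kt(cfg.temperature),
        cfg.effective_burn_in,
        cfg.thin,
        disp,
        u01,
        record_dudl,
        out,
    )
    if not np.all(np.isfinite(out)):
        raise SamplerError(
            f"non-finite energy encountered sampling {system.kind} "
            f"(seed={cfg.seed}, final state x={x_final})"
        )
    meta = {
        "seed": cfg.seed,
        "system": system.kind,
        "acceptance_rate": n_acc / cfg.n_steps,
        "temperature": cfg.temperature,
    }
    if record_dudl:
        meta["lambda"] = lam
    if bias is not None:
        meta["r0"] = bias.r0
        meta["k_rest"] = bias.k_rest
    logger.info(
        "sampled %s: %d samples, seed=%d, acceptance=%.3f",
        system.kind,
        len(out),
        cfg.seed,
        meta["acceptance_rate"],
    )
    return TimeSeries(out, meta)


def _run_box(
    system: MicroSolvationBox,
    cfg: SamplerConfig,
    lam_v: float,
    lam_p: float,
    lam_e: float,
    record_mode: int,
) -> TimeSeries:
    step = cfg.step_size if cfg.step_size is not None else system.default_step
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    idx = rng.integers(0, system.n_particles, cfg.n_steps)
    disp = rng.uniform(-1.0, 1.0, (cfg.n_steps, 3))
    u01 = rng.random(cfg.n_steps)
    jump = rng.random(cfg.n_steps) < system.jump_fraction
    out = np.empty(cfg.n_samples)
    p = system.solute_pair
    n_acc, _ = _kernels.chain_box(
        system.initial_positions(),
        system.charges(),
        system.box_edge,
        system.cutoff**2,
        system.solvent_c12,
        system.solvent_c6,
        p.C12,
        p.C6,
        p.C4,
        lam_v,
        lam_p,
        lam_e,
        system.alpha_sc,
        system.dielectric,
        1.0 / kt(cfg.temperature),
        cfg.effective_burn_in,
        cfg.thin,
        step,
        idx,
        disp,
        u01,
        jump,
        record_mode,
        out,
    )
    if not np.all(np.isfinite(out)):
        raise SamplerError(
            f"non-finite observable sampling micro_solvation_box (seed={cfg.seed})"
        )
    meta = {
        "seed": cfg.seed,
        "system": system.kind,
        "acceptance_rate": n_acc / cfg.n_steps,
        "temperature": cfg.temperature,
        "lambda_vdw": lam_v,
        "lambda_pol": lam_p,
        "lambda_ele": lam_e,
    }
    logger.info(
        "sampled micro_solvation_box: %d samples, seed=%d, acceptance=%.3f",
        len(out),
        cfg.seed,
        meta["acceptance_rate"],
    )
    return TimeSeries(out, meta)


def sample_canonical(
    system: ToySystem, cfg: SamplerConfig, bias: RestraintSpec | None = None
) -> TimeSeries:
    """Sample the (optionally biased) canonical distribution of a toy system.

    Returns the recorded coordinate series; the acceptance rate and seed are
    in ``TimeSeries.metadata``.
    """
    if isinstance(system, MicroSolvationBox):
        if bias is not None:
            raise ContractError("distance restraints apply to 1-D systems only")
        return _run_box(system, cfg, 1.0, 1.0, 1.0, record_mode=0)
    return _run_1d(system, cfg, bias, None, 0.0, record_dudl=False)


def sample_dudl(
    system: ToySystem,
    path: "LinearMixPath | CouplingLeg",
    lambda_value: float,
    cfg: SamplerConfig,
) -> TimeSeries:
    """Sample dU/dλ at a fixed λ along an alchemical path.

    ``LinearMixPath`` mixes two same-kind toy systems linearly (analytic
    dU/dλ = U_B − U_A); ``CouplingLeg`` couples one component of the
    micro-solvation box's solute (soft-core vdW via central difference in λ,
    the C4 and Coulomb components analytically).
    """
    if not 0.0 <= lambda_value <= 1.0:
        raise DomainError(f"lambda must be in [0,1], got {lambda_value}")
    if isinstance(path, LinearMixPath):
        return _run_1d(
            system, cfg, None, path.end_system, lambda_value, record_dudl=True
        )
    if not isinstance(system, MicroSolvationBox):
        raise ContractError("CouplingLeg paths require a MicroSolvationBox")
    comp = path.component
    if comp == "vdw":
        lams = (lambda_value, 0.0, 0.0)
    elif comp == "pol":
        lams = (1.0, lambda_value, 0.0)
    elif comp == "ele":
        lams = (1.0, 1.0, lambda_value)
    else:  # total: one-step protocol, everything on one λ
        lams = (lambda_value, lambda_value, lambda_value)
    return _run_box(system, cfg, *lams, record_mode=_BOX_RECORD_MODES[comp])


def dudl_finite_difference(
    u_of_lambda: Callable[[float], float], lam: float, h: float = 1e-4
) -> float:
    """Central-difference dU/dλ of a λ-parametrized energy at fixed coordinates."""
    return (u_of_lambda(lam + h) - u_of_lambda(lam - h)) / (2.0 * h)
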