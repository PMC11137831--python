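"""Umbrella-sampling windows and the WHAM potential of mean force.

Overlapping harmonically restrained windows along a distance coordinate are
combined by self-consistent iteration of the standard WHAM equations

    P(r_m) ∝ Σ_i n_im / Σ_i N_i·exp(β(f_i − b_i(r_m)))
    f_i    = −k_BT·ln Σ_m P(r_m)·exp(−β·b_i(r_m))

until the window offsets f_i stop changing.  The PMF is −k_BT·ln P,
referenced so its sampled minimum is zero.  Low-count bins are reported as
gaps (NaN), never interpolated.

The binding free energy is read off the profile as (bound-basin minimum) −
(unbound-plateau mean); a one-dimensional standard-state correction is
computed and reported separately but never silently added, because
experimental binding values are matched directly to the profile depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .errors import ContractError, ConvergenceError, DomainError
from .sampling import RestraintSpec, SamplerConfig, TimeSeries, sample_canonical
from .systems import ToySystem

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "WHAMConfig",
    "PMFProfile",
    "LandmarkSet",
    "BindingResult",
    "OverlapReport",
    "plan_windows",
    "run_umbrella",
    "check_overlap",
    "wham_solve",
    "binding_dg_from_pmf",
    "find_landmarks",
]


@dataclass
class Window:
    """One umbrella window: its restraint and the sampled coordinate series."""

    restraint: RestraintSpec
    series: TimeSeries

    def __post_init__(self) -> None:
        if len(self.series) == 0:
            raise ContractError("window series must be non-empty")


@dataclass(frozen=True)
class WHAMConfig:
    """WHAM solver settings (bin width Å, offset tolerance kcal/mol)."""

    bin_width: float = 0.05
    tolerance: float = 1e-7
    max_iterations: int = 100_000
    temperature: float = 300.0
    min_count: int = 10

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.tolerance <= 0:
            raise DomainError("bin_width and tolerance must be positive")


@dataclass
class PMFProfile:
    """Binned free-energy profile; unsampled/low-count bins are NaN-flagged gaps."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    n_eff: np.ndarray
    reference: str = "min-zero"
    min_count: int = 10

    @property
    def well_sampled(self) -> np.ndarray:
        """Mask of bins with enough counts to trust."""
        return np.isfinite(self.free_energy) & (self.n_eff >= self.min_count)

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class LandmarkSet:
    """Alternating minima and barriers along r, labelled A, B, C, … by position."""

    minima: tuple[tuple[float, float], ...]
    barriers: tuple[tuple[float, float], ...]
    labels: tuple[tuple[str, str, float, float], ...]  # (label, kind, r, dG)


@dataclass(frozen=True)
class BindingResult:
    """Binding free energy plus the separately reported standard-state term."""

    delta_g: float
    bound_minimum: float
    plateau_mean: float
    plateau_slope: float
    standard_state_correction: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class OverlapReport:
    """Adjacent-pair histogram overlap coefficients and the poorly-overlapping pairs."""

    fractions: tuple[float, ...]
    low_pairs: tuple[tuple[int, int], ...]


def plan_windows(
    r_min: float, r_max: float, spacing: float, k_default: float
) -> list[RestraintSpec]:
    """Evenly spaced umbrella restraints covering [r_min, r_max].

    A spacing wider than the range degenerates to a single window at the
    midpoint.  Per-window force constants can be adjusted afterwards.
    """
    if r_min >= r_max:
        raise DomainError(f"need r_min < r_max, got [{r_min}, {r_max}]")
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    if spacing > r_max - r_min:
        return [RestraintSpec(k_rest=k_default, r0=0.5 * (r_min + r_max))]
    n = int(round((r_max - r_min) / spacing)) + 1
    centers = r_min + spacing * np.arange(n)
    centers = centers[centers <= r_max + 1e-9]
    return [RestraintSpec(k_rest=k_default, r0=float(c)) for c in centers]


def _window_seed(base_seed: int, window_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), 7919, window_index])
    return int(ss.generate_state(1)[0] % 2**31)


def run_umbrella(
    system: ToySystem,
    restraints: Sequence[RestraintSpec],
    cfg: SamplerConfig,
    seed: int | None = None,
) -> list[Window]:
    """Sample every umbrella window (seeds derived per window) and collect them."""
    base = cfg.seed if seed is None else seed
    windows = []
    for i, rs in enumerate(restraints):
        cfg_i = replace(cfg, seed=_window_seed(base, i))
        windows.append(Window(rs, sample_canonical(system, cfg_i, bias=rs)))
    return windows


def check_overlap(
    windows: Sequence[Window], bin_width: float = 0.05, warn_below: float = 0.05
) -> OverlapReport:
    """Histogram-overlap coefficient Σ_m min(p_i, p_j) for each adjacent pair."""
    if len(windows) < 2:
        raise ContractError("overlap check needs at least two windows")
    for w in windows:
        if len(w.series) == 0:
            raise ContractError("overlap check requires non-empty window series")
    lo = min(w.series.values.min() for w in windows)
    hi = max(w.series.values.max() for w in windows)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    fractions = []
    low_pairs = []
    for i in range(len(windows) - 1):
        p, _ = np.histogram(windows[i].series.values, bins=edges)
        q, _ = np.histogram(windows[i + 1].series.values, bins=edges)
        ovl = float(np.minimum(p / p.sum(), q / q.sum()).sum())
        fractions.append(ovl)
        if ovl < warn_below:
            low_pairs.append((i, i + 1))
            logger.warning(
                "windows %d and %d overlap poorly (%.3f < %.2f)",
                i, i + 1, ovl, warn_below,
            )
    return OverlapReport(tuple(fractions), tuple(low_pairs))


def wham_solve(windows: Sequence[Window], cfg: WHAMConfig | None = None) -> PMFProfile:
    """Self-consistent WHAM solution of the unbiased PMF from biased windows.

    Deterministic given its inputs; raises :class:`ConvergenceError` carrying
    the residual if the offsets have not settled within ``max_iterations``.
    """
    cfg = cfg or WHAMConfig()
    if len(windows) == 0:
        raise ContractError("wham_solve needs at least one window")
    beta = 1.0 / kt(cfg.temperature)
    pooled_lo = min(w.series.values.min() for w in windows)
    pooled_hi = max(w.series.values.max() for w in windows)
    first = np.floor(pooled_lo / cfg.bin_width) * cfg.bin_width
    n_bins = max(1, int(np.ceil((pooled_hi - first) / cfg.bin_width)))
    edges = first + cfg.bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack(
        [np.histogram(w.series.values, bins=edges)[0] for w in windows]
    ).astype(float)
    n_tot = counts.sum(axis=0)
    n_win = counts.sum(axis=1)

    bias = np.stack([
        0.5 * w.restraint.k_rest * (centers - w.restraint.r0) ** 2
        + w.restraint.offset
        for w in windows
    ])
    log_e = -beta * bias  # (n_windows, n_bins)
    with np.errstate(divide="ignore"):
        ln_ntot = np.log(n_tot)
        ln_nwin = np.log(n_win)

    f = np.zeros(len(windows))
    for iteration in range(cfg.max_iterations):
        ln_den = logsumexp(ln_nwin[:, None] + beta * f[:, None] + log_e, axis=0)
        ln_p = ln_ntot - ln_den
        ln_p -= logsumexp(ln_p[np.isfinite(ln_p)])
        ln_z = logsumexp(ln_p[None, :] + log_e, axis=1)
        f_new = -kt(cfg.temperature) * ln_z
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < cfg.tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {cfg.max_iterations} iterations "
            f"(residual {delta:.3e} kcal/mol)",
            residual=delta,
        )
    logger.info("WHAM converged in %d iterations (residual %.2e)", iteration + 1, delta)

    with np.errstate(divide="ignore", invalid="ignore"):
        g = -kt(cfg.temperature) * ln_p
    g[n_tot == 0] = np.nan
    sampled = np.isfinite(g)
    g -= np.nanmin(g[sampled]) if sampled.any() else 0.0
    return PMFProfile(
        bin_centers=centers,
        free_energy=g,
        n_eff=n_tot,
        reference="min-zero",
        min_count=cfg.min_count,
    )


def binding_dg_from_pmf(
    pmf: PMFProfile,
    bound_max_r: float,
    plateau_range: tuple[float, float] | None = None,
    temperature: float = 300.0,
    slope_warn: float = 0.1,
) -> BindingResult:
    """ΔG_bind = (bound-basin minimum) − (unbound-plateau mean).

    ``plateau_range`` defaults to the outermost 15% of the sampled range.
    A non-flat plateau (|slope| > 0.1 kcal/mol/Å) attaches a warning; an
    unsampled plateau is an error.  The 1-D standard-state correction
    −k_BT·ln(∫_bound exp(−βG')dr / 1 Å), with G' referenced to the plateau,
    is reported separately and never added to ``delta_g``.
    """
    ok = pmf.well_sampled
    if not ok.any():
        raise ContractError("PMF has no well-sampled bins")
    r = pmf.bin_centers
    g = pmf.free_energy
    r_lo, r_hi = r[ok].min(), r[ok].max()
    if plateau_range is None:
        plateau_range = (r_hi - 0.15 * (r_hi - r_lo), r_hi)
    p_mask = ok & (r >= plateau_range[0]) & (r <= plateau_range[1])
    if p_mask.sum() == 0:
        raise ContractError(
            f"plateau range {plateau_range} contains no well-sampled bins"
        )
    warnings: list[str] = []
    if p_mask.sum() >= 2:
        slope = float(np.polyfit(r[p_mask], g[p_mask], 1)[0])
    else:
        slope = 0.0
        warnings.append("plateau has a single bin; flatness not testable")
    if abs(slope) > slope_warn:
        warnings.append(
            f"plateau is not flat: |slope| = {abs(slope):.3f} kcal/mol/Å "
            f"> {slope_warn}"
        )
    plateau_mean = float(g[p_mask].mean())
    b_mask = ok & (r <= bound_max_r)
    if b_mask.sum() == 0:
        raise ContractError(f"no well-sampled bins at r <= {bound_max_r}")
    bound_min = float(g[b_mask].min())
    beta = 1.0 / kt(temperature)
    g_rel = g[b_mask] - plateau_mean
    integral = float(np.sum(np.exp(-beta * g_rel)) * pmf.bin_width)
    correction = -kt(temperature) * np.log(integral / 1.0)
    return BindingResult(
        delta_g=bound_min - plateau_mean,
        bound_minimum=bound_min,
        plateau_mean=plateau_mean,
        plateau_slope=slope,
        standard_state_correction=float(correction),
        warnings=tuple(warnings),
    )


def find_landmarks(pmf: PMFProfile, smooth_window: int = 3) -> LandmarkSet:
    """Locate alternating minima/barriers of a PMF after light smoothing.

    Smoothing (moving average, default 3 bins) is applied only for the
    extremum search; reported ΔG values are read from the *unsmoothed*
    profile at the landmark bins.  Labels run A, B, C, … in increasing r.
    """
    ok = np.isfinite(pmf.free_energy)
    if ok.sum() < 5:
        return LandmarkSet((), (), ())
    idx = np.where(ok)[0]
    r = pmf.bin_centers[idx]
    g = pmf.free_energy[idx]
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    gs = np.convolve(np.pad(g, pad, mode="edge"), kernel, mode="valid")
    # interior extrema of the smoothed profile, away from the boundary bins
    # (the profile's behaviour at the sampling boundary is not a landmark)
    landmarks: list[tuple[str, int]] = []  # (kind, position in idx)
    for i in range(1 + pad, len(gs) - 1 - pad):
        if gs[i] < gs[i - 1] and gs[i] <= gs[i + 1]:
            landmarks.append(("min", i))
        elif gs[i] > gs[i - 1] and gs[i] >= gs[i + 1]:
            landmarks.append(("max", i))
    # enforce strict alternation: of consecutive same-kind landmarks keep the
    # more extreme one (deeper minimum / higher barrier)
    cleaned: list[tuple[str, int]] = []
    for kind, i in landmarks:
        if cleaned and cleaned[-1][0] == kind:
            j = cleaned[-1][1]
            better = (g[i] < g[j]) if kind == "min" else (g[i] > g[j])
            if better:
                cleaned[-1] = (kind, i)
        else:
            cleaned.append((kind, i))
    minima = tuple(
        (float(r[i]), float(g[i])) for kind, i in cleaned if kind == "min"
    )
    barriers = tuple(
        (float(r[i]), float(g[i])) for kind, i in cleaned if kind == "max"
    )
    labels = tuple(
        (chr(ord("A") + n), kind, float(r[i]), float(g[i]))
        for n, (kind, i) in enumerate(cleaned)
    )
    return LandmarkSet(minima=minima, barriers=barriers, labels=labels)
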