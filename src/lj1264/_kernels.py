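"""Numba Metropolis chain kernels.

All randomness is pre-drawn with numpy Generators by the callers and passed
in as arrays (displacements, particle indices, uniform accept draws), so a
chain is a pure function of its inputs and bit-reproducible regardless of
the numba version's internal RNG.

Energies use a large sentinel (1e30) for hard-wall violations; proposals
into a wall are rejected by the Metropolis test since exp(−βΔU) underflows
to zero.

1-D kernel system codes
    0  harmonic:      p = [k, x0]
    1  double well:   p = [h, c, w, wall_lo, wall_hi]   U = h((x−c)²−w²)²/w⁴
    2  ion pair:      p = [C12, C6, C4, Qi·Qj, dielectric, wall_lo, wall_hi]

Box record modes (per-sample observable)
    0  solute–solvent distance of the first solvent bead (diagnostic)
    1  dU/dλ of the soft-core vdW leg (central difference, h = 1e−4)
    2  dU/dλ of the polarization leg (Σ −C4/r⁴ at full coefficient)
    3  dU/dλ of the electrostatic leg (Σ k_C·q_i·q_j/(ε·r) at full coefficient)
    4  dU/dλ of the one-step path (all components scaled by one λ)
"""

import numpy as np
from numba import njit

_KC = 332.0637
_WALL = 1e29
_FD_H = 1e-4


@njit(cache=True)
def _u1d(kind, p, x):
    if kind == 0:
        d = x - p[1]
        return 0.5 * p[0] * d * d
    if kind == 1:
        if x < p[3] or x > p[4]:
            return 1e30
        d = (x - p[1]) * (x - p[1]) - p[2] * p[2]
        w2 = p[2] * p[2]
        return p[0] * d * d / (w2 * w2)
    # kind == 2: 12-6-4 + screened Coulomb along the pair distance
    if x <= 0.0 or x < p[5] or x > p[6]:
        return 1e30
    x2 = x * x
    x4 = x2 * x2
    x6 = x4 * x2
    return p[0] / (x6 * x6) - p[1] / x6 - p[2] / x4 + _KC * p[3] / (p[4] * x)


@njit(cache=True)
def chain_1d(
    kind,
    pa,
    pb,
    lam,
    mix,
    bias_k,
    bias_r0,
    x0,
    beta,
    burn_in,
    thin,
    disp,
    u01,
    record_dudl,
    out,
):
    """Metropolis chain on a 1-D coordinate; returns (n_accepted, final_x).

    With ``mix`` the target is U(λ,x) = (1−λ)·U_A(x) + λ·U_B(x) (+ bias);
    ``record_dudl`` stores U_B(x) − U_A(x) per sample (the analytic dU/dλ of
    a linear mix), otherwise the coordinate itself is stored.
    """
    n_steps = disp.shape[0]
    x = x0
    ua = _u1d(kind, pa, x)
    ub = _u1d(kind, pb, x) if mix else 0.0
    e = (1.0 - lam) * ua + lam * ub if mix else ua
    e += 0.5 * bias_k * (x - bias_r0) * (x - bias_r0)
    n_acc = 0
    m = 0
    for s in range(n_steps):
        xn = x + disp[s]
        uan = _u1d(kind, pa, xn)
        ubn = _u1d(kind, pb, xn) if mix else 0.0
        en = (1.0 - lam) * uan + lam * ubn if mix else uan
        en += 0.5 * bias_k * (xn - bias_r0) * (xn - bias_r0)
        de = en - e
        if de <= 0.0 or (en < _WALL and u01[s] < np.exp(-beta * de)):
            x = xn
            ua = uan
            ub = ubn
            e = en
            n_acc += 1
        if s >= burn_in and (s - burn_in) % thin == thin - 1:
            if m < out.shape[0]:
                if record_dudl:
                    out[m] = (_u1d(kind, pb, x) if not mix else ub) - ua
                else:
                    out[m] = x
                m += 1
    return n_acc, x


@njit(cache=True)
def _sc_vdw(r6, c12, c6, lam, alpha):
    """Soft-core 12-6 pair energy as a function of r⁶ (handles degenerate C12/C6)."""
    if lam == 0.0:
        return 0.0
    if c12 <= 0.0 and c6 <= 0.0:
        return 0.0
    if c6 <= 0.0:
        return lam * c12 / (r6 * r6)
    if c12 <= 0.0:
        return -lam * c6 / r6
    sig6 = c12 / c6
    eps4 = c6 * c6 / c12
    d = alpha * (1.0 - lam) + r6 / sig6
    return lam * eps4 * (1.0 / (d * d) - 1.0 / d)


@njit(cache=True)
def _solute_pair_u(r6, qj, q0, c12, c6, c4, lam_v, lam_p, lam_e, alpha, diel):
    """λ-coupled solute–solvent pair energy as a function of r⁶.

    The C4 and Coulomb terms are scaled linearly by their own λ but evaluated
    at the soft-core effective distance r_sc⁶ = α(1−λ_vdW)·σ⁶ + r⁶, so they
    stay finite wherever the softened repulsion lets particles overlap.  With
    the vdW coupling full (λ_vdW = 1) this is exactly the plain 12-6-4 +
    Coulomb pair energy.
    """
    e = _sc_vdw(r6, c12, c6, lam_v, alpha)
    if lam_p == 0.0 and lam_e == 0.0:
        return e
    if c12 > 0.0 and c6 > 0.0:
        r6_sc = alpha * (1.0 - lam_v) * (c12 / c6) + r6
    else:
        r6_sc = r6
    if r6_sc <= 0.0:
        return e
    if lam_p != 0.0:
        r4_sc = r6_sc ** (2.0 / 3.0)
        e -= lam_p * c4 / r4_sc
    if lam_e != 0.0:
        r_sc = r6_sc ** (1.0 / 6.0)
        e += lam_e * _KC * q0 * qj / (diel * r_sc)
    return e


@njit(cache=True)
def _box_particle_energy(
    pos, q, p, xyz, L, cutoff2, css12, css6, cx12, cx6, cx4, lam_v, lam_p, lam_e, alpha, diel
):
    """Interaction energy of particle ``p`` (at trial position xyz) with all others.

    Particle 0 is the solute; solute–solvent pairs carry the λ-coupled
    soft-core vdW, polarization (C4) and electrostatic terms, solvent–solvent
    pairs the plain 12-6 + Coulomb.  Plain truncation at the cutoff.
    """
    n = pos.shape[0]
    e = 0.0
    for j in range(n):
        if j == p:
            continue
        dx = xyz[0] - pos[j, 0]
        dy = xyz[1] - pos[j, 1]
        dz = xyz[2] - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cutoff2:
            continue
        r6 = r2 * r2 * r2
        if p == 0 or j == 0:
            qj = q[j] if p == 0 else q[p]
            e += _solute_pair_u(
                r6, qj, q[0], cx12, cx6, cx4, lam_v, lam_p, lam_e, alpha, diel
            )
        else:
            e += css12 / (r6 * r6) - css6 / r6
            r = np.sqrt(r2)
            e += _KC * q[p] * q[j] / (diel * r)
    return e


@njit(cache=True)
def _solute_coupling_u(pos, q, L, cutoff2, cx12, cx6, cx4, lam_v, lam_p, lam_e, alpha, diel):
    """Total λ-coupled solute–solvent energy (truncated at the cutoff)."""
    n = pos.shape[0]
    e = 0.0
    for j in range(1, n):
        dx = pos[0, 0] - pos[j, 0]
        dy = pos[0, 1] - pos[j, 1]
        dz = pos[0, 2] - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cutoff2:
            continue
        r6 = r2 * r2 * r2
        e += _solute_pair_u(
            r6, q[j], q[0], cx12, cx6, cx4, lam_v, lam_p, lam_e, alpha, diel
        )
    return e


@njit(cache=True)
def _solute_dudl(pos, q, L, cutoff2, cx12, cx6, cx4, lam, alpha, diel, record_mode):
    """Per-sample dU/dλ of one coupling leg at the current configuration.

    Modes: 1 vdW leg (central difference of the soft-core sum, other
    components off), 2 polarization leg (analytic Σ −C4/r⁴ at full vdW),
    3 electrostatic leg (analytic Coulomb sum at full vdW), 4 one-step
    (central difference of the full coupling energy with all components on
    the same λ).
    """
    if record_mode == 1:
        up = _solute_coupling_u(
            pos, q, L, cutoff2, cx12, cx6, cx4, lam + _FD_H, 0.0, 0.0, alpha, diel
        )
        um = _solute_coupling_u(
            pos, q, L, cutoff2, cx12, cx6, cx4, lam - _FD_H, 0.0, 0.0, alpha, diel
        )
        return (up - um) / (2.0 * _FD_H)
    if record_mode == 4:
        lp = lam + _FD_H
        lm = lam - _FD_H
        up = _solute_coupling_u(
            pos, q, L, cutoff2, cx12, cx6, cx4, lp, lp, lp, alpha, diel
        )
        um = _solute_coupling_u(
            pos, q, L, cutoff2, cx12, cx6, cx4, lm, lm, lm, alpha, diel
        )
        return (up - um) / (2.0 * _FD_H)
    # analytic sums at plain distances (vdW coupling is full on these legs)
    n = pos.shape[0]
    acc = 0.0
    for j in range(1, n):
        dx = pos[0, 0] - pos[j, 0]
        dy = pos[0, 1] - pos[j, 1]
        dz = pos[0, 2] - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cutoff2 or r2 <= 0.0:
            continue
        if record_mode == 2:
            acc -= cx4 / (r2 * r2)
        else:
            acc += _KC * q[0] * q[j] / (diel * np.sqrt(r2))
    return acc


@njit(cache=True)
def chain_box(
    pos0,
    q,
    L,
    cutoff2,
    css12,
    css6,
    cx12,
    cx6,
    cx4,
    lam_v,
    lam_p,
    lam_e,
    alpha,
    diel,
    beta,
    burn_in,
    thin,
    step,
    idx,
    disp,
    u01,
    jump,
    record_mode,
    out,
):
    """Metropolis chain on the periodic micro-solvation box.

    Single-particle uniform-cube displacements of half-width ``step``; steps
    flagged in ``jump`` propose a uniform reinsertion anywhere in the box
    instead (a symmetric proposal, so the plain Metropolis rule applies) —
    these teleport moves decorrelate the solvent composition around the
    solute far faster than local displacements alone.
    Returns (n_accepted, final positions).
    """
    pos = pos0.copy()
    n_steps = idx.shape[0]
    n_acc = 0
    m = 0
    xyz = np.empty(3)
    for s in range(n_steps):
        p = idx[s]
        if jump[s]:
            xyz[0] = 0.5 * (disp[s, 0] + 1.0) * L
            xyz[1] = 0.5 * (disp[s, 1] + 1.0) * L
            xyz[2] = 0.5 * (disp[s, 2] + 1.0) * L
        else:
            xyz[0] = pos[p, 0] + step * disp[s, 0]
            xyz[1] = pos[p, 1] + step * disp[s, 1]
            xyz[2] = pos[p, 2] + step * disp[s, 2]
        e_old = _box_particle_energy(
            pos, q, p, pos[p], L, cutoff2, css12, css6, cx12, cx6, cx4,
            lam_v, lam_p, lam_e, alpha, diel,
        )
        e_new = _box_particle_energy(
            pos, q, p, xyz, L, cutoff2, css12, css6, cx12, cx6, cx4,
            lam_v, lam_p, lam_e, alpha, diel,
        )
        de = e_new - e_old
        if de <= 0.0 or u01[s] < np.exp(-beta * de):
            pos[p, 0] = xyz[0] - L * np.floor(xyz[0] / L)
            pos[p, 1] = xyz[1] - L * np.floor(xyz[1] / L)
            pos[p, 2] = xyz[2] - L * np.floor(xyz[2] / L)
            n_acc += 1
        if s >= burn_in and (s - burn_in) % thin == thin - 1:
            if m < out.shape[0]:
                if record_mode == 0:
                    dx = pos[0, 0] - pos[1, 0]
                    dy = pos[0, 1] - pos[1, 1]
                    dz = pos[0, 2] - pos[1, 2]
                    dx -= L * np.rint(dx / L)
                    dy -= L * np.rint(dy / L)
                    dz -= L * np.rint(dz / L)
                    out[m] = np.sqrt(dx * dx + dy * dy + dz * dz)
                else:
                    lam_leg = lam_v
                    if record_mode == 2:
                        lam_leg = lam_p
                    elif record_mode == 3:
                        lam_leg = lam_e
                    out[m] = _solute_dudl(
                        pos, q, L, cutoff2, cx12, cx6, cx4, lam_leg, alpha, diel,
                        record_mode,
                    )
                m += 1
    return n_acc, pos
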