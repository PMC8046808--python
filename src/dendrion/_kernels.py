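"""Numba-compiled inner loops for energies, forces and Langevin propagation.

All arrays are float64/int64.  Energies are in units of kB*T_room (= epsilon),
lengths in sigma_m, masses 1.  Electrostatics follow the standard Ewald
splitting: erfc-screened real-space pairs here, a reciprocal-space sum over a
precomputed half-space k-vector set, and a constant self term added at the
Python level.

Pair flags select which terms act on a candidate pair:
bit 0 (value 1) -> WCA, bit 1 (value 2) -> Coulomb.  Bonded pairs are part of
the candidate list with flags chosen from the exclusion switches; the FENE or
harmonic bond term itself iterates the bond list separately.
"""

import math

import numpy as np
from numba import njit

TWO_POW_THIRD = 2.0 ** (1.0 / 3.0)
INV_SQRT_PI = 1.0 / math.sqrt(math.pi)

BOND_FENE = 0
BOND_HARMONIC = 1


@njit(cache=True, fastmath=False)
def _mi(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def pair_energy_forces(pos, charges, diam, pairs, pair_flags, L,
                       eps, lambda_B, alpha, r_cut2, forces):
    """Accumulate WCA + screened-Coulomb energy/forces over candidate pairs."""
    e_wca = 0.0
    e_coul = 0.0
    do_coul = lambda_B > 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        flags = pair_flags[p]
        dx = _mi(pos[i, 0] - pos[j, 0], L)
        dy = _mi(pos[i, 1] - pos[j, 1], L)
        dz = _mi(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            continue
        if flags & 1:
            sig = 0.5 * (diam[i] + diam[j])
            if sig > 0.0 and r2 < TWO_POW_THIRD * sig * sig:
                sr2 = sig * sig / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                e_wca += 4.0 * eps * (sr12 - sr6 + 0.25)
                fmag = 24.0 * eps * (2.0 * sr12 - sr6) / r2
                forces[i, 0] += fmag * dx
                forces[i, 1] += fmag * dy
                forces[i, 2] += fmag * dz
                forces[j, 0] -= fmag * dx
                forces[j, 1] -= fmag * dy
                forces[j, 2] -= fmag * dz
        if do_coul and (flags & 2) and r2 < r_cut2:
            qq = charges[i] * charges[j]
            if qq != 0.0:
                r = math.sqrt(r2)
                pref = lambda_B * qq
                er = math.erfc(alpha * r)
                e_coul += pref * er / r
                fmag = pref * (er / r + 2.0 * alpha * INV_SQRT_PI
                               * math.exp(-alpha * alpha * r2)) / r2
                forces[i, 0] += fmag * dx
                forces[i, 1] += fmag * dy
                forces[i, 2] += fmag * dz
                forces[j, 0] -= fmag * dx
                forces[j, 1] -= fmag * dy
                forces[j, 2] -= fmag * dz
    return e_wca, e_coul


@njit(cache=True)
def bond_energy_forces(pos, bonds, L, bond_style, k, R0, r0, forces):
    """FENE (or harmonic) bond terms.

    Returns (energy, fault_index); fault_index is the first overstretched
    bond, or -1 when all bonds are healthy.
    """
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], L)
        dy = _mi(pos[i, 1] - pos[j, 1], L)
        dz = _mi(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if bond_style == BOND_FENE:
            if r2 >= R0 * R0:
                return e, b
            x = 1.0 - r2 / (R0 * R0)
            e += -0.5 * k * R0 * R0 * math.log(x)
            fmag = -k / x  # force = fmag * d  (attractive toward the partner)
        else:
            r = math.sqrt(r2)
            dr = r - r0
            e += 0.5 * k * dr * dr
            fmag = -k * dr / r if r > 0.0 else 0.0
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e, -1


@njit(cache=True)
def ewald_recip_energy_forces(pos, charges, nvecs, kcoef, two_pi_L, nmax,
                              forces):
    """Reciprocal-space Ewald sum over a half-space k-vector set.

    nvecs holds integer reciprocal indices n with k = (2 pi / L) n; kcoef
    already contains the factor 2 for the omitted half space:
    kcoef[m] = 2 * (2 pi lambda_B / V) * exp(-k^2/(4 alpha^2)) / k^2.
    Per-particle phase factors e^{i k_d x_d} are built once per axis by
    recursion, so the inner loops are trig-free.
    """
    n = pos.shape[0]
    idx = np.empty(n, np.int64)
    nq = 0
    for i in range(n):
        if charges[i] != 0.0:
            idx[nq] = i
            nq += 1
    if nq == 0 or nvecs.shape[0] == 0:
        return 0.0
    width = 2 * nmax + 1
    exr = np.empty((3, nq, width))
    exi = np.empty((3, nq, width))
    for d in range(3):
        for a in range(nq):
            ang = two_pi_L * pos[idx[a], d]
            c = math.cos(ang)
            s = math.sin(ang)
            exr[d, a, nmax] = 1.0
            exi[d, a, nmax] = 0.0
            for m in range(1, nmax + 1):
                pr = exr[d, a, nmax + m - 1]
                pim = exi[d, a, nmax + m - 1]
                exr[d, a, nmax + m] = pr * c - pim * s
                exi[d, a, nmax + m] = pr * s + pim * c
                exr[d, a, nmax - m] = exr[d, a, nmax + m]
                exi[d, a, nmax - m] = -exi[d, a, nmax + m]
    e = 0.0
    cr = np.empty(nq)
    ci = np.empty(nq)
    for m in range(nvecs.shape[0]):
        ax = nvecs[m, 0] + nmax
        ay = nvecs[m, 1] + nmax
        az = nvecs[m, 2] + nmax
        sr = 0.0
        si = 0.0
        for a in range(nq):
            xr = exr[0, a, ax]
            xi = exi[0, a, ax]
            yr = exr[1, a, ay]
            yi = exi[1, a, ay]
            zr = exr[2, a, az]
            zi = exi[2, a, az]
            tr = xr * yr - xi * yi
            ti = xr * yi + xi * yr
            pr = tr * zr - ti * zi
            pim = tr * zi + ti * zr
            cr[a] = pr
            ci[a] = pim
            q = charges[idx[a]]
            sr += q * pr
            si += q * pim
        c_k = kcoef[m]
        e += c_k * (sr * sr + si * si)
        kx = two_pi_L * nvecs[m, 0]
        ky = two_pi_L * nvecs[m, 1]
        kz = two_pi_L * nvecs[m, 2]
        for a in range(nq):
            i = idx[a]
            fac = 2.0 * c_k * charges[i] * (ci[a] * sr - cr[a] * si)
            forces[i, 0] += fac * kx
            forces[i, 1] += fac * ky
            forces[i, 2] += fac * kz
    return e


@njit(cache=True)
def compute_forces(pos, charges, diam, pairs, pair_flags, bonds, L,
                   eps, lambda_B, alpha, r_cut2, nvecs, kcoef, two_pi_L, nmax,
                   bond_style, k_bond, R0, r0, forces):
    """Total force field evaluation.  Returns (e_wca, e_bond, e_coul, fault)."""
    forces[:] = 0.0
    e_wca, e_coul = pair_energy_forces(pos, charges, diam, pairs, pair_flags, L,
                                       eps, lambda_B, alpha, r_cut2, forces)
    e_bond, fault = bond_energy_forces(pos, bonds, L, bond_style, k_bond, R0,
                                       r0, forces)
    if fault >= 0:
        return e_wca, e_bond, e_coul, fault
    if lambda_B > 0.0 and nvecs.shape[0] > 0:
        e_coul += ewald_recip_energy_forces(pos, charges, nvecs, kcoef,
                                            two_pi_L, nmax, forces)
    return e_wca, e_bond, e_coul, -1


@njit(cache=True)
def advance_chunk(pos, vel, forces, n_steps, dt, c1, c2, noise,
                  charges, diam, pairs, pair_flags, bonds, L,
                  eps, lambda_B, alpha, r_cut2, nvecs, kcoef, two_pi_L, nmax,
                  bond_style, k_bond, R0, r0):
    """n_steps of BAOAB Langevin splitting with unit masses.

    noise has shape (n_steps, N, 3) and is pre-drawn so determinism lives
    entirely in the caller's RNG.  Returns the within-chunk step index of the
    first fault (overstretch), or -1.  Positions are left unwrapped; forces
    on exit match the final positions.
    """
    n = pos.shape[0]
    h2 = 0.5 * dt
    for s in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += h2 * forces[i, d]          # B
                pos[i, d] += h2 * vel[i, d]             # A
                vel[i, d] = c1 * vel[i, d] + c2 * noise[s, i, d]  # O
                pos[i, d] += h2 * vel[i, d]             # A
        _, _, _, fault = compute_forces(pos, charges, diam, pairs, pair_flags,
                                        bonds, L, eps, lambda_B, alpha, r_cut2,
                                        nvecs, kcoef, two_pi_L, nmax,
                                        bond_style, k_bond, R0, r0, forces)
        if fault >= 0:
            return s
        for i in range(n):
            for d in range(3):
                vel[i, d] += h2 * forces[i, d]          # B
    return -1
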