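"""The three interaction terms in reduced LJ units.

* Excluded volume: truncated-and-shifted LJ 12-6 cut at 2^(1/6) sigma_ab
  (WCA), purely repulsive, with the arithmetic mixing rule
  sigma_ab = (sigma_a + sigma_b)/2.
* Bonds: FENE springs, U = -0.5 k R0^2 ln(1 - r^2/R0^2), with the canonical
  Kremer-Grest parameters k = 30, R0 = 1.5.  The diverging branch at r >= R0
  is signalled as :class:`~dendrion.errors.OverstretchError` rather than
  returned as a non-finite value, so integrator faults are detectable.
* Electrostatics: U/kBT = lambda_B z_i z_j / r between all charged pairs,
  evaluated under periodic boundary conditions by classical Ewald summation
  (real + reciprocal + self term) with an automatic splitting-parameter
  choice from a target relative accuracy.

Bonded pairs feel both FENE and WCA (Kremer-Grest convention) and are not
excluded from Coulomb; both conventions are switchable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .errors import OverstretchError, ParameterError
from .system import ParticleSystem

DEFAULT_K = 30.0
DEFAULT_R0 = 1.5
WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """All interaction parameters in reduced units."""

    epsilon: float = 1.0
    k: float = DEFAULT_K
    R0: float = DEFAULT_R0
    lambda_B: float = 0.0
    ewald_accuracy: float = 1e-4
    r_cut_real: float = 10.0
    bond_style: str = "fene"        # "fene" | "harmonic"
    harmonic_r0: float = 0.0
    wca_exclude_bonded: bool = False
    coulomb_exclude_bonded: bool = False

    def __post_init__(self):
        if self.epsilon <= 0 or self.k <= 0 or self.R0 <= 0:
            raise ParameterError("epsilon, k and R0 must be positive")
        if self.lambda_B < 0:
            raise ParameterError("lambda_B must be non-negative")
        if not 0 < self.ewald_accuracy < 1:
            raise ParameterError("ewald_accuracy must lie in (0, 1)")
        if self.r_cut_real <= 0:
            raise ParameterError("r_cut_real must be positive")
        if self.bond_style not in ("fene", "harmonic"):
            raise ParameterError(f"unknown bond_style {self.bond_style!r}")

    @property
    def bond_style_code(self) -> int:
        return (_kernels.BOND_FENE if self.bond_style == "fene"
                else _kernels.BOND_HARMONIC)

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# analytic pair terms

def mixing_diameter(sigma_a: float, sigma_b: float) -> float:
    """Arithmetic (Lorentz) mixing rule sigma_ab = (sigma_a + sigma_b)/2."""
    if sigma_a <= 0 or sigma_b <= 0:
        raise ParameterError("diameters must be positive")
    return 0.5 * (sigma_a + sigma_b)


def wca_pair(r: float, sigma_ab: float, epsilon: float = 1.0):
    """Truncated-and-shifted repulsive LJ (WCA) energy and force magnitude.

    Returns (energy, -dU/dr); both are exactly zero at and beyond the cutoff
    2^(1/6) sigma_ab, and the energy is continuous there.
    """
    if r <= 0:
        raise ParameterError("r must be positive")
    if r >= WCA_CUTOFF_FACTOR * sigma_ab:
        return 0.0, 0.0
    sr6 = (sigma_ab / r) ** 6
    sr12 = sr6 * sr6
    energy = 4.0 * epsilon * (sr12 - sr6 + 0.25)
    force = 24.0 * epsilon * (2.0 * sr12 - sr6) / r
    return energy, force


def fene_pair(r: float, k: float = DEFAULT_K, R0: float = DEFAULT_R0):
    """FENE bond energy and force magnitude -dU/dr.

    Raises OverstretchError for r >= R0 (the potential's diverging branch).
    """
    if r < 0:
        raise ParameterError("r must be non-negative")
    if r >= R0:
        raise OverstretchError(f"bond length {r} >= R0 = {R0}")
    x = 1.0 - (r / R0) ** 2
    energy = -0.5 * k * R0**2 * math.log(x)
    force = -k * r / x
    return energy, force


def coulomb_pair(r: float, z_i: float, z_j: float, lambda_B: float) -> float:
    """Bare (non-periodic) Coulomb energy lambda_B z_i z_j / r in kBT.

    This is the large-box limit of the Ewald sum and the form used by the
    condensation analysis.
    """
    if r <= 0:
        raise ParameterError("r must be positive")
    return lambda_B * z_i * z_j / r


def bonded_potential_minimum(ff: ForceFieldParams | None = None,
                             sigma: float = 1.0):
    """Location and depth of the combined FENE + WCA bond minimum.

    For the canonical Kremer-Grest parameters this sits near 0.961 sigma.
    """
    ff = ff or ForceFieldParams()
    r = np.linspace(0.7, min(ff.R0 * 0.999, WCA_CUTOFF_FACTOR * sigma), 20001)
    u = np.array([fene_pair(x, ff.k, ff.R0)[0]
                  + wca_pair(x, sigma, ff.epsilon)[0] for x in r])
    i = int(np.argmin(u))
    return float(r[i]), float(u[i])


# ---------------------------------------------------------------------------
# Ewald machinery

@dataclass(frozen=True)
class EwaldSetup:
    """Precomputed splitting parameter and reciprocal vectors for one box."""

    alpha: float
    r_cut: float
    kvecs: np.ndarray   # (n_k, 3) float, half space
    nvecs: np.ndarray   # (n_k, 3) int reciprocal indices, k = 2 pi n / L
    kcoef: np.ndarray   # (n_k,) includes the half-space factor 2
    self_energy: float  # -lambda_B * alpha/sqrt(pi) * sum q_i^2
    two_pi_L: float = 0.0
    n_max: int = 0


def ewald_setup(box_length: float, lambda_B: float, charges: np.ndarray,
                accuracy: float = 1e-4, r_cut_real: float = 10.0,
                max_kvecs: int = 2_000_000) -> EwaldSetup:
    """Choose alpha and the k-vector set for a target relative force error.

    alpha = sqrt(-ln delta)/r_cut makes the real-space error ~delta at the
    cutoff; the reciprocal cutoff k_max = 2 alpha sqrt(-ln delta) balances
    the two error contributions (standard heuristic).
    """
    if box_length <= 0:
        raise ParameterError("box_length must be positive")
    r_cut = min(r_cut_real, 0.499 * box_length)
    s = math.sqrt(-math.log(accuracy))
    alpha = s / r_cut
    k_max = 2.0 * alpha * s
    two_pi_L = 2.0 * math.pi / box_length
    n_max = int(math.ceil(k_max / two_pi_L))
    rng = np.arange(-n_max, n_max + 1)
    nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
    n = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
    # half space: nz > 0, or nz == 0 and ny > 0, or ny == nz == 0 and nx > 0
    half = ((n[:, 2] > 0)
            | ((n[:, 2] == 0) & (n[:, 1] > 0))
            | ((n[:, 2] == 0) & (n[:, 1] == 0) & (n[:, 0] > 0)))
    n = n[half]
    k = n * two_pi_L
    k2 = (k * k).sum(axis=1)
    keep = k2 <= k_max * k_max
    k = k[keep]
    k2 = k2[keep]
    if len(k) > max_kvecs:
        raise ParameterError(
            f"requested accuracy needs {len(k)} k-vectors (> {max_kvecs}); "
            "increase r_cut_real or relax ewald_accuracy")
    nv = n[keep]
    volume = box_length**3
    kcoef = 2.0 * (2.0 * math.pi * lambda_B / volume) * np.exp(-k2 / (4 * alpha**2)) / k2
    self_energy = -lambda_B * alpha / math.sqrt(math.pi) * float((charges**2).sum())
    return EwaldSetup(alpha=alpha, r_cut=r_cut,
                      kvecs=np.ascontiguousarray(k, dtype=np.float64),
                      nvecs=np.ascontiguousarray(nv, dtype=np.int64),
                      kcoef=np.ascontiguousarray(kcoef, dtype=np.float64),
                      self_energy=self_energy, two_pi_L=two_pi_L,
                      n_max=int(np.abs(nv).max(initial=0)))


_EMPTY_K = np.zeros((0, 3))
_EMPTY_N = np.zeros((0, 3), dtype=np.int64)
_EMPTY_C = np.zeros(0)


def candidate_pairs(system: ParticleSystem, ff: ForceFieldParams,
                    r_cut: float | None = None, skin: float = 0.0):
    """All-pairs or cell-list candidate pairs plus per-pair term flags.

    The flag word selects WCA (bit 0) and Coulomb (bit 1) per pair; bonded
    pairs get their bits from the exclusion switches.  The returned set is a
    superset of every pair within the largest cutoff.
    """
    from .simulator import build_cell_list  # deferred, avoids import cycle

    n = system.n_particles
    max_wca = WCA_CUTOFF_FACTOR * float(system.diameters.max(initial=0.0))
    if max_wca == 0.0 and not (r_cut or 0.0) > 0.0:
        # no finite-range interactions at all (e.g. an ideal gas)
        return (np.zeros((0, 2), dtype=np.int64), np.zeros(0, dtype=np.int64))
    cut = max(max_wca, r_cut or 0.0) + skin
    if n <= 400 or cut >= system.box_length / 3.0:
        iu = np.triu_indices(n, 1)
        pairs = np.stack([iu[0], iu[1]], axis=1).astype(np.int64)
    else:
        pairs = build_cell_list(system.positions, system.box_length, cut)
    flags = np.full(len(pairs), 3, dtype=np.int64)
    if len(system.bonds) and (ff.wca_exclude_bonded or ff.coulomb_exclude_bonded):
        bond_flag = ((0 if ff.wca_exclude_bonded else 1)
                     | (0 if ff.coulomb_exclude_bonded else 2))
        keys = pairs.min(axis=1) * n + pairs.max(axis=1)
        bkeys = system.bonds.min(axis=1) * n + system.bonds.max(axis=1)
        flags[np.isin(keys, bkeys)] = bond_flag
    return pairs, flags


def bonded_nonbonded_energy_forces(positions, charges, diameters, bonds,
                                   box_length, ff: ForceFieldParams):
    """WCA + bond energy/forces only (no electrostatics); used by push-off."""
    n = len(positions)
    iu = np.triu_indices(n, 1)
    pairs = np.stack([iu[0], iu[1]], axis=1).astype(np.int64)
    flags = np.full(len(pairs), 1, dtype=np.int64)
    forces = np.zeros((n, 3))
    e_wca, e_bond, _, fault = _kernels.compute_forces(
        np.ascontiguousarray(positions, dtype=np.float64),
        np.ascontiguousarray(charges, dtype=np.float64),
        np.ascontiguousarray(diameters, dtype=np.float64),
        pairs, flags, np.ascontiguousarray(bonds, dtype=np.int64),
        float(box_length), ff.epsilon, 0.0, 0.0, 0.0, _EMPTY_N, _EMPTY_C,
        0.0, 0, ff.bond_style_code, ff.k, ff.R0, ff.harmonic_r0, forces)
    if fault >= 0:
        # push-off works on soft configurations; cap the FENE argument instead
        # of diverging by treating the overstretched bond harmonically
        e_bond = math.inf
    return e_wca + e_bond, forces


def ewald_electrostatics(system: ParticleSystem, ff: ForceFieldParams):
    """Full periodic electrostatic energy and per-particle forces.

    Energy and forces converge to the infinite periodic-image sum (tinfoil
    boundary conditions) as ewald_accuracy -> 0.  The system must be
    electroneutral.
    """
    if abs(system.net_charge) > 1e-9:
        raise ParameterError(f"system has net charge {system.net_charge}; "
                             "Ewald requires electroneutrality")
    if ff.lambda_B == 0.0 or not np.any(system.charges):
        return 0.0, np.zeros((system.n_particles, 3))
    setup = ewald_setup(system.box_length, ff.lambda_B, system.charges,
                        ff.ewald_accuracy, ff.r_cut_real)
    n = system.n_particles
    iu = np.triu_indices(n, 1)
    pairs = np.stack([iu[0], iu[1]], axis=1).astype(np.int64)
    flags = np.full(len(pairs), 2, dtype=np.int64)  # Coulomb only
    forces = np.zeros((n, 3))
    _, e_real = _kernels.pair_energy_forces(
        np.ascontiguousarray(system.positions, dtype=np.float64),
        system.charges, system.diameters, pairs, flags, system.box_length,
        ff.epsilon, ff.lambda_B, setup.alpha, setup.r_cut**2, forces)
    e_recip = _kernels.ewald_recip_energy_forces(
        np.ascontiguousarray(system.positions, dtype=np.float64),
        system.charges, setup.nvecs, setup.kcoef, setup.two_pi_L,
        setup.n_max, forces)
    return e_real + e_recip + setup.self_energy, forces


def total_energy_forces(system: ParticleSystem, ff: ForceFieldParams):
    """Energy decomposition {wca, fene, coulomb} and per-particle forces.

    The Coulomb entry is the full Ewald energy (real + reciprocal + self).
    Raises OverstretchError if any bond is at or beyond R0.
    """
    n = system.n_particles
    if ff.lambda_B > 0.0 and np.any(system.charges):
        if abs(system.net_charge) > 1e-9:
            raise ParameterError("charged system must be electroneutral")
        setup = ewald_setup(system.box_length, ff.lambda_B, system.charges,
                            ff.ewald_accuracy, ff.r_cut_real)
        alpha, r_cut = setup.alpha, setup.r_cut
        nvecs, kcoef, e_self = setup.nvecs, setup.kcoef, setup.self_energy
        two_pi_L, n_max = setup.two_pi_L, setup.n_max
    else:
        alpha = r_cut = 0.0
        nvecs, kcoef, e_self = _EMPTY_N, _EMPTY_C, 0.0
        two_pi_L, n_max = 0.0, 0
    pairs, flags = candidate_pairs(system, ff, r_cut=r_cut)
    forces = np.zeros((n, 3))
    e_wca, e_bond, e_coul, fault = _kernels.compute_forces(
        np.ascontiguousarray(system.positions, dtype=np.float64),
        system.charges, system.diameters, pairs, flags,
        system.bonds, system.box_length, ff.epsilon, ff.lambda_B, alpha,
        r_cut**2, nvecs, kcoef, two_pi_L, n_max, ff.bond_style_code, ff.k,
        ff.R0, ff.harmonic_r0, forces)
    if fault >= 0:
        raise OverstretchError(f"bond {fault} at or beyond R0 = {ff.R0}")
    return {"wca": e_wca, "fene": e_bond, "coulomb": e_coul + e_self}, forces
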