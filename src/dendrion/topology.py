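"""Dendrimer graph construction and counterion mixture composition.

The molecule is a trifunctional bead-spring dendrimer: a core of two bonded
monomers, each of which roots two spacer chains of S bonds; every chain ends
in a branching group that again roots two chains, out to generation G where
the chains end in terminal groups.  Monomer and branching-group counts are

    N    = 2 + 4 S (2^G - 1),
    N_bg = 2^(G+2) - 2.

Mimicking a PAMAM dendrimer at low pH, the two core monomers and every
branching and terminal group carry valence +1; spacer-internal monomers are
neutral.  Global electroneutrality is restored by N_bg monovalent anions, a
binary mixture of "conventional" ions of diameter 1 and "bulky" ions of
diameter sigma_b (2 or 3 by default), mixed at number fraction f_b.

Index layout is deterministic: the core pair occupies indices 0 and 1, then
monomers are appended generation by generation (breadth first), chain by
chain, so fixtures and tests are order-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InitializationError, ParameterError
from .system import ParticleSystem, minimum_image

ROLE_CORE = "core"
ROLE_BRANCHING = "branching"
ROLE_TERMINAL = "terminal"
ROLE_SPACER = "spacer-internal"

#: Roles that carry a +1 valence (protonated amines at low pH).
CHARGED_ROLES = (ROLE_CORE, ROLE_BRANCHING, ROLE_TERMINAL)


def monomer_count(G: int, S: int) -> int:
    """N = 2 + 4 S (2^G - 1)."""
    return 2 + 4 * S * (2**G - 1)


def branching_group_count(G: int) -> int:
    """N_bg = 2^(G+2) - 2 (branching + terminal groups + the core pair)."""
    return 2 ** (G + 2) - 2


@dataclass(frozen=True)
class DendrimerTopology:
    """Bonded tree of a G/S dendrimer with per-monomer role and valence."""

    G: int
    S: int
    bonds: np.ndarray     # (N-1, 2) int, parent < child ordering by construction
    roles: np.ndarray     # (N,) unicode role labels
    charges: np.ndarray   # (N,) int valences in {0, +1}

    @property
    def n_monomers(self) -> int:
        return len(self.roles)

    @property
    def n_charged(self) -> int:
        return int((self.charges > 0).sum())

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_monomers, dtype=int)
        np.add.at(deg, self.bonds.ravel(), 1)
        return deg


def build_dendrimer(G: int, S: int) -> DendrimerTopology:
    """Construct the G/S dendrimer tree with low-pH charge placement.

    Raises
    ------
    ParameterError
        If G or S is not a positive integer.
    """
    if int(G) != G or int(S) != S or G < 1 or S < 1:
        raise ParameterError(f"G and S must be positive integers, got G={G}, S={S}")
    G, S = int(G), int(S)

    roles = [ROLE_CORE, ROLE_CORE]
    bonds = [(0, 1)]
    frontier = [0, 1]  # nodes that each root two chains of the next generation
    for g in range(1, G + 1):
        end_role = ROLE_BRANCHING if g < G else ROLE_TERMINAL
        new_frontier = []
        for parent in frontier:
            for _ in range(2):
                prev = parent
                for s in range(1, S + 1):
                    idx = len(roles)
                    roles.append(end_role if s == S else ROLE_SPACER)
                    bonds.append((prev, idx))
                    prev = idx
                new_frontier.append(prev)
        frontier = new_frontier

    roles = np.array(roles)
    charges = np.isin(roles, CHARGED_ROLES).astype(np.int64)
    topo = DendrimerTopology(G=G, S=S, bonds=np.array(bonds, dtype=np.int64),
                             roles=roles, charges=charges)
    assert topo.n_monomers == monomer_count(G, S)
    assert topo.n_charged == branching_group_count(G)
    return topo


@dataclass(frozen=True)
class IonMixture:
    """Composition of the neutralizing binary counterion mixture."""

    N_c: int
    N_b: int
    sigma_c: float = 1.0
    sigma_b: float = 2.0
    charge: int = -1

    @property
    def n_total(self) -> int:
        return self.N_c + self.N_b

    @property
    def f_b(self) -> float:
        """Realized bulky number fraction N_b / (N_b + N_c)."""
        return self.N_b / self.n_total if self.n_total else 0.0


def compose_ion_mixture(N_bg: int, f_b: float, sigma_b: float = 2.0) -> IonMixture:
    """Split N_bg neutralizing anions into conventional and bulky species.

    N_b = round(f_b * N_bg) with round-half-to-even; for the reference G4S4
    molecule (N_bg = 62) the canonical f_b grid 0, 0.16, ..., 1 maps to
    N_b = 0, 10, 20, 30, 40, 50, 62.
    """
    if not 0.0 <= f_b <= 1.0:
        raise ParameterError(f"f_b must lie in [0, 1], got {f_b}")
    if N_bg < 0:
        raise ParameterError("N_bg must be non-negative")
    if sigma_b <= 0:
        raise ParameterError("sigma_b must be positive")
    N_b = int(round(f_b * N_bg))
    return IonMixture(N_c=N_bg - N_b, N_b=N_b, sigma_b=float(sigma_b))


def neutral_system(topology: DendrimerTopology, positions: np.ndarray,
                   box_length: float) -> ParticleSystem:
    """The neutral analogue: monomers only, all valences zero, no counterions."""
    n_m = topology.n_monomers
    return ParticleSystem(positions=positions, species=np.array(["m"] * n_m),
                          charges=np.zeros(n_m), diameters=np.ones(n_m),
                          bonds=topology.bonds, box_length=box_length,
                          roles=topology.roles)


def assemble_system(topology: DendrimerTopology, ions: IonMixture,
                    positions: np.ndarray, box_length: float) -> ParticleSystem:
    """Bundle monomers (first) and counterions (after) into a ParticleSystem."""
    n_m = topology.n_monomers
    if ions.n_total != topology.n_charged:
        raise ParameterError(
            f"mixture has {ions.n_total} ions but the dendrimer carries "
            f"{topology.n_charged} charges; the system must be electroneutral")
    species = np.array(["m"] * n_m + ["c"] * ions.N_c + ["b"] * ions.N_b)
    charges = np.concatenate([
        topology.charges.astype(float),
        np.full(ions.n_total, float(ions.charge)),
    ])
    diameters = np.concatenate([
        np.ones(n_m),
        np.full(ions.N_c, ions.sigma_c),
        np.full(ions.N_b, ions.sigma_b),
    ])
    return ParticleSystem(positions=positions, species=species, charges=charges,
                          diameters=diameters, bonds=topology.bonds,
                          box_length=box_length, roles=topology.roles)


def _min_separation_ok(pos, candidate, diam, d_cand, L, factor=0.85):
    """True if candidate is at least factor*sigma_ab from every row of pos."""
    if len(pos) == 0:
        return True
    d = minimum_image(pos - candidate, L)
    r = np.sqrt((d * d).sum(axis=1))
    return bool(np.all(r >= factor * 0.5 * (diam + d_cand)))


def embed_initial_configuration(topology: DendrimerTopology,
                                ions: IonMixture | None,
                                L: float, seed: int,
                                max_retries: int = 200) -> ParticleSystem:
    """Place the dendrimer and counterions in the box without hard overlaps.

    The dendrimer is grown as a non-reversal random walk along the tree with
    bond length 0.97 sigma_m, then relaxed by a short displacement-capped
    steepest descent on the bonded + WCA energy (push-off).  Counterions are
    inserted uniformly with rejection.  The returned configuration satisfies
    all bonded distances < R0 and no pair closer than 0.85 sigma_ab.
    Deterministic for a fixed seed.  With ``ions=None`` the neutral analogue
    (monomers only, zero valences) is embedded instead.
    """
    from . import forcefield  # deferred: forcefield does not import topology

    rng = np.random.default_rng(seed)
    n_m = topology.n_monomers
    bond_len = 0.97

    n_ions = 0 if ions is None else ions.n_total
    # crude feasibility guard before burning the retry budget
    occupied = (np.pi / 6.0) * (n_m * 1.0 + (0.0 if ions is None else
                                             ions.N_c * ions.sigma_c**3
                                             + ions.N_b * ions.sigma_b**3))
    if occupied > 0.3 * L**3 or L < 4.0:
        raise InitializationError(
            f"box L={L} too small for {n_m + n_ions} particles")

    diam_m = np.ones(n_m)
    for attempt in range(5):
        pos = np.empty((n_m, 3))
        pos[0] = L / 2.0
        u = _random_unit(rng)
        pos[1] = pos[0] + bond_len * u
        ok = True
        for i, j in topology.bonds[1:]:
            placed = False
            for _ in range(max_retries):
                u = _random_unit(rng)
                cand = pos[i] + bond_len * u
                # non-reversal bias: retry straight back-folds onto the parent bond
                if _min_separation_ok(pos[:j][np.arange(j) != i], cand,
                                      diam_m[:j][np.arange(j) != i], 1.0, L,
                                      factor=0.80):
                    pos[j] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise InitializationError("dendrimer growth failed: box too crowded")

    pos = _push_off(pos, topology.bonds, L)

    # verify the monomer-monomer contract before inserting ions
    if not _all_separated(pos, diam_m, topology.bonds, L):
        raise InitializationError("push-off could not resolve monomer overlaps")

    if ions is None:
        all_pos = pos
        system = neutral_system(topology, all_pos, L)
    else:
        ion_diams = np.concatenate([np.full(ions.N_c, ions.sigma_c),
                                    np.full(ions.N_b, ions.sigma_b)])
        all_pos = pos
        all_diam = diam_m
        for d in ion_diams:
            placed = False
            for _ in range(max_retries * 5):
                cand = rng.uniform(0.0, L, size=3)
                if _min_separation_ok(all_pos, cand, all_diam, d, L):
                    all_pos = np.vstack([all_pos, cand])
                    all_diam = np.append(all_diam, d)
                    placed = True
                    break
            if not placed:
                raise InitializationError(
                    "counterion insertion failed: box too small")
        system = assemble_system(topology, ions, all_pos, L)
    # FENE bonds must all be inside the admissible range
    bd = minimum_image(all_pos[topology.bonds[:, 0]] - all_pos[topology.bonds[:, 1]], L)
    if np.any(np.sqrt((bd * bd).sum(axis=1)) >= forcefield.DEFAULT_R0):
        raise InitializationError("push-off overstretched a bond")
    return system


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _all_separated(pos, diam, bonds, L, factor=0.85):
    n = len(pos)
    d = minimum_image(pos[:, None, :] - pos[None, :, :], L)
    r = np.sqrt((d * d).sum(axis=2))
    sig = 0.5 * (diam[:, None] + diam[None, :])
    iu = np.triu_indices(n, 1)
    return bool(np.all(r[iu] >= factor * sig[iu]))


def _push_off(pos, bonds, L, n_iter=800, max_disp=0.05):
    """Displacement-capped steepest descent on the FENE + WCA energy."""
    from . import forcefield

    ff = forcefield.ForceFieldParams(lambda_B=0.0)
    n = len(pos)
    diam = np.ones(n)
    charges = np.zeros(n)
    for _ in range(n_iter):
        _, forces = forcefield.bonded_nonbonded_energy_forces(
            pos, charges, diam, bonds, L, ff)
        norms = np.linalg.norm(forces, axis=1)
        fmax = norms.max()
        if fmax < 1.0:
            break
        step = forces * (max_disp / max(fmax, 1e-12))
        pos = pos + step
    return pos
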