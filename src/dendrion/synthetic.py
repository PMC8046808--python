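"""Fixture generators with planted, analytically known observable values.

Every generator here produces configurations whose absorbed/condensed
counts, profile supports or stationary statistics are known by construction,
so the analysis stack can be tested without running long simulations.  Each
planted fixture re-verifies its own ground truth with an independent
brute-force distance scan before it is handed out.

The dendrimer conformation used by the static fixtures is a stored reference
coordinate set (produced once by a short neutral relaxation and frozen into
the package data), so analysis tests never depend on the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import InitializationError, ParameterError
from .forcefield import ForceFieldParams
from .simulator import Trajectory
from .system import ParticleSystem, minimum_image, wrap_positions
from .topology import DendrimerTopology, IonMixture, assemble_system

_REFERENCE_FILES = {(2, 2): "g2s2_reference.xyz", (4, 4): "g4s4_reference.xyz"}


def reference_conformation(G: int, S: int) -> np.ndarray:
    """Stored relaxed monomer coordinates for a stock (G, S) dendrimer.

    Coordinates are centred on the origin.  For topologies without a stored
    reference a deterministic embedded conformation is grown instead.
    """
    key = (G, S)
    if key in _REFERENCE_FILES:
        path = resources.files("dendrion.data") / _REFERENCE_FILES[key]
        with path.open() as fh:
            lines = fh.read().splitlines()
        n = int(lines[0])
        coords = np.array([[float(x) for x in ln.split()[1:4]]
                           for ln in lines[2:2 + n]])
    else:
        from .topology import build_dendrimer, embed_initial_configuration
        t = build_dendrimer(G, S)
        sys0 = embed_initial_configuration(t, None, L=100.0, seed=20210414)
        coords = sys0.positions[:t.n_monomers]
    return coords - coords.mean(axis=0)


@dataclass
class PlantedFixture:
    """A configuration plus the ground truth it realizes."""

    system: ParticleSystem
    expected: dict

    def as_trajectory(self, n_frames: int = 10) -> Trajectory:
        """Replicate the static frame so block-averaged analyses apply."""
        s = self.system
        return Trajectory(
            steps=np.arange(1, n_frames + 1, dtype=np.int64),
            positions=np.repeat(s.positions[None], n_frames, axis=0),
            species=s.species, charges=s.charges, diameters=s.diameters,
            bonds=s.bonds, box_length=s.box_length,
            params={"synthetic": True}, logs=None)


def _place_dendrimer(topology: DendrimerTopology, L: float):
    coords = reference_conformation(topology.G, topology.S)
    center = np.full(3, L / 2.0)
    pos = coords + center
    com = pos.mean(axis=0)
    rg = float(np.sqrt(((pos - com) ** 2).sum(axis=1).mean()))
    return pos, com, rg


def _verify_counts(system: ParticleSystem, com, r_abs) -> dict:
    """Independent O(N^2) recount of absorbed/condensed ions per species."""
    out = {}
    chm = system.positions[system.charged_monomer_indices]
    for sp in ("c", "b"):
        idx = system.ion_indices(sp)
        if len(idx) == 0:
            out[sp] = (0, 0)
            continue
        pos = system.positions[idx]
        d = minimum_image(pos - com, system.box_length)
        r_com = np.sqrt((d * d).sum(axis=1))
        absorbed = int((r_com < r_abs).sum())
        thr = 0.5 * (2.0 + system.diameters[idx][0])
        dd = minimum_image(pos[:, None, :] - chm[None, :, :], system.box_length)
        rmin = np.sqrt((dd * dd).sum(axis=2)).min(axis=1)
        condensed = int((rmin < thr).sum())
        out[sp] = (absorbed, condensed)
    return out


def make_planted_ion_config(topology: DendrimerTopology, ions: IonMixture,
                            n_absorbed: dict, n_condensed: dict,
                            seed: int, L: float = 100.0,
                            max_tries: int = 4000) -> PlantedFixture:
    """Freeze the dendrimer and plant ions with exact absorbed/condensed counts.

    ``n_absorbed``/``n_condensed`` map species ("c", "b") to requested counts;
    absorbed counts include the condensed ones.  Condensed ions sit at
    0.9x the condensation threshold from distinct charged monomers; the
    remaining absorbed ions are scattered in the shell (0.5 Rg, 1.5 Rg) from
    the COM but farther than 1.1x the threshold from every charged monomer;
    all other ions are placed beyond 3 Rg.  The declared counts are verified
    by an independent distance scan before the fixture is returned.
    """
    rng = np.random.default_rng(seed)
    counts = {"c": ions.N_c, "b": ions.N_b}
    for sp in ("c", "b"):
        na = n_absorbed.get(sp, 0)
        nc = n_condensed.get(sp, 0)
        if not 0 <= nc <= na <= counts[sp]:
            raise ParameterError(
                f"need 0 <= condensed <= absorbed <= N_{sp}; got "
                f"{nc}, {na}, {counts[sp]} for species {sp!r}")
    mono_pos, com, rg = _place_dendrimer(topology, L)
    if 3.0 * rg >= 0.45 * L:
        raise InitializationError("box too small for the far-ion shell")
    chm_idx = np.flatnonzero(topology.charges > 0)
    chm_pos = mono_pos[chm_idx]
    # charged monomers sorted by distance from the COM: nearest first, so the
    # planted condensed ions stay well inside the absorption sphere
    order = np.argsort(np.linalg.norm(chm_pos - com, axis=1))
    ion_positions = {"c": [], "b": []}
    sigma = {"c": ions.sigma_c, "b": ions.sigma_b}
    used_monomers = 0
    for sp in ("c", "b"):
        thr = 0.5 * (2.0 + sigma[sp])
        nc = n_condensed.get(sp, 0)
        for m in range(nc):
            if used_monomers >= len(order):
                raise InitializationError("more condensed ions than charged "
                                          "monomers")
            anchor = chm_pos[order[used_monomers]]
            used_monomers += 1
            for _ in range(max_tries):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = anchor + 0.9 * thr * u
                if np.linalg.norm(cand - com) < 2.0 * rg:
                    ion_positions[sp].append(cand)
                    break
            else:
                raise InitializationError(
                    f"could not keep a condensed {sp} ion inside 2 Rg")
        n_shell = n_absorbed.get(sp, 0) - nc
        for _ in range(n_shell):
            for _ in range(max_tries):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                r = rng.uniform(0.5 * rg, 1.5 * rg)
                cand = com + r * u
                d = np.linalg.norm(chm_pos - cand, axis=1).min()
                if d > 1.1 * thr:
                    ion_positions[sp].append(cand)
                    break
            else:
                raise InitializationError(
                    f"no room for a delocalized {sp} ion between 0.5 and "
                    "1.5 Rg clear of the charged monomers")
        n_far = counts[sp] - n_absorbed.get(sp, 0)
        for _ in range(n_far):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(3.2 * rg, 0.45 * L)
            ion_positions[sp].append(com + r * u)
    all_pos = np.vstack([mono_pos] + [np.array(p).reshape(-1, 3)
                                      for p in (ion_positions["c"],
                                                ion_positions["b"])])
    system = assemble_system(topology, ions, wrap_positions(all_pos, L), L)
    com_w = wrap_positions(com, L)
    check = _verify_counts(system, com_w, 2.0 * rg)
    expected = {"rg": rg, "com": com_w, "absorption_radius": 2.0 * rg,
                "absorbed": {sp: n_absorbed.get(sp, 0) for sp in ("c", "b")},
                "condensed": {sp: n_condensed.get(sp, 0) for sp in ("c", "b")}}
    for sp in ("c", "b"):
        if check[sp] != (expected["absorbed"][sp], expected["condensed"][sp]):
            raise InitializationError(
                f"self-check failed for species {sp!r}: planted "
                f"{expected['absorbed'][sp]}/{expected['condensed'][sp]}, "
                f"scan found {check[sp][0]}/{check[sp][1]}")
    return PlantedFixture(system=system, expected=expected)


def make_uniform_gas(n: int, L: float, n_frames: int, seed: int) -> Trajectory:
    """i.i.d. uniform ideal-gas frames; g(r) around any fixed point is 1."""
    if n < 1:
        raise ParameterError("need at least one particle")
    rng = np.random.default_rng(seed)
    frames = rng.uniform(0.0, L, size=(n_frames, n, 3))
    return Trajectory(steps=np.arange(1, n_frames + 1, dtype=np.int64),
                      positions=frames,
                      species=np.array(["c"] * n),
                      charges=np.zeros(n), diameters=np.ones(n),
                      bonds=np.zeros((0, 2), dtype=np.int64), box_length=L,
                      params={"synthetic": True}, logs=None)


def make_core_shell_config(topology: DendrimerTopology, ions: IonMixture,
                           R_core: float, R_shell_inner: float,
                           R_shell_outer: float, seed: int,
                           L: float = 100.0) -> PlantedFixture:
    """Conventional ions in a core ball, bulky ions in an outer shell.

    Emulates the segregated microstructure: the COM profile of the
    conventional species must peak at a strictly smaller radius than the
    bulky one.
    """
    if not 0 < R_core < R_shell_inner < R_shell_outer < L / 2.0:
        raise InitializationError(
            "need 0 < R_core < R_shell_inner < R_shell_outer < L/2")
    rng = np.random.default_rng(seed)
    mono_pos, com, rg = _place_dendrimer(topology, L)

    def _ball(n, r_lo, r_hi):
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # uniform in the spherical shell [r_lo, r_hi]
        r = (rng.uniform(r_lo**3, r_hi**3, size=n)) ** (1.0 / 3.0)
        return com + u * r[:, None]

    pos_c = _ball(ions.N_c, 0.0, R_core)
    pos_b = _ball(ions.N_b, R_shell_inner, R_shell_outer)
    all_pos = np.vstack([mono_pos, pos_c, pos_b])
    system = assemble_system(topology, ions, wrap_positions(all_pos, L), L)
    com_w = wrap_positions(com, L)
    # independent support check
    for pos, lo, hi in ((pos_c, 0.0, R_core), (pos_b, R_shell_inner,
                                               R_shell_outer)):
        r = np.linalg.norm(pos - com, axis=1)
        if len(r) and not (r.min() >= lo - 1e-9 and r.max() <= hi + 1e-9):
            raise InitializationError("core-shell support check failed")
    expected = {"rg": rg, "com": com_w,
                "support_c": (0.0, R_core),
                "support_b": (R_shell_inner, R_shell_outer)}
    return PlantedFixture(system=system, expected=expected)


def make_harmonic_dimer(k: float = 10.0, T: float = 1.0, L: float = 50.0):
    """Two unit-mass beads on a harmonic spring (rest length 0).

    Returns (system, force-field params).  In equilibrium each Cartesian
    component of the separation vector has variance T/k, giving the
    integrator calibration its closed form.  Diameters are zero so no WCA
    term interferes.
    """
    if k <= 0:
        raise ParameterError("spring constant must be positive")
    pos = np.array([[L / 2 - 0.1, L / 2, L / 2], [L / 2 + 0.1, L / 2, L / 2]])
    system = ParticleSystem(
        positions=pos, species=np.array(["c", "c"]), charges=np.zeros(2),
        diameters=np.zeros(2), bonds=np.array([[0, 1]]), box_length=L)
    ff = ForceFieldParams(bond_style="harmonic", k=k, harmonic_r0=0.0,
                          lambda_B=0.0)
    return system, ff
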