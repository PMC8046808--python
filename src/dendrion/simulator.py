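"""Langevin propagation under periodic boundary conditions.

The integrator is the BAOAB splitting of the Langevin equation with unit
masses: half-kick, half-drift, an exact Ornstein-Uhlenbeck velocity update
(c1 = exp(-gamma dt), noise variance T (1 - c1^2), satisfying
fluctuation-dissipation at temperature T), half-drift, half-kick.  With
gamma = 0 the scheme reduces to velocity Verlet, which the NVE tests use.

A run follows the standard protocol: equilibration steps are discarded, then
every ``sample_every``-th production frame is stored together with an energy
decomposition and the instantaneous temperature.  All randomness flows from
one ``numpy`` Generator seeded by the run seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _kernels, forcefield
from .errors import ParameterError, SimulationFault
from .system import Frame, ParticleSystem, wrap_positions

#: steps advanced per kernel call; bounds how stale the candidate pair list
#: can get (see the skin argument of the pair-list rebuild below).
_CHUNK = 20
#: Verlet skin added to the largest cutoff; at dt = 0.005 and thermal speeds
#: ~sqrt(3T) a particle moves well under skin/2 within one chunk.
_SKIN = 0.5


@dataclass(frozen=True)
class SimulationParams:
    """Time step, thermostat, box and protocol lengths (reduced units)."""

    dt: float = 0.005
    gamma: float = 1.0
    T: float = 1.0
    L: float = 100.0
    n_equil: int = 1_000_000
    n_prod: int = 10_000_000
    sample_every: int = 1000
    seed: int = 0
    preset: str | None = None

    def __post_init__(self):
        if self.dt <= 0 or self.T <= 0 or self.L <= 0:
            raise ParameterError("dt, T and L must be positive")
        if self.gamma < 0:
            raise ParameterError("gamma must be non-negative")
        if self.sample_every < 1:
            raise ParameterError("sample_every must be >= 1")
        if self.n_equil < 0 or self.n_prod < 0:
            raise ParameterError("step counts must be non-negative")


def desk_scale(**overrides) -> SimulationParams:
    """Short-run preset for a G2S2 system in an L = 40 box."""
    kw = dict(dt=0.005, gamma=1.0, T=1.0, L=40.0, n_equil=20_000,
              n_prod=100_000, sample_every=100, preset="desk_scale")
    kw.update(overrides)
    return SimulationParams(**kw)


def paper_scale(**overrides) -> SimulationParams:
    """Production-scale preset for the G4S4 system (cluster-sized runs)."""
    kw = dict(dt=0.005, gamma=1.0, T=1.0, L=100.0, n_equil=1_000_000,
              n_prod=10_000_000, sample_every=1000, preset="paper_scale")
    kw.update(overrides)
    return SimulationParams(**kw)


PRESETS = {"desk_scale": desk_scale, "paper_scale": paper_scale}


@dataclass
class Trajectory:
    """Time-ordered frames with the static particle attributes alongside."""

    steps: np.ndarray        # (F,) strictly increasing production step indices
    positions: np.ndarray    # (F, N, 3), wrapped into [0, L)
    species: np.ndarray
    charges: np.ndarray
    diameters: np.ndarray
    bonds: np.ndarray
    box_length: float
    params: dict
    logs: dict | None = None

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1] if self.positions.ndim == 3 else 0

    def frame(self, i: int) -> Frame:
        return Frame(self.positions[i], self.species, self.charges,
                     self.diameters, self.bonds, self.box_length)


def instantaneous_temperature(velocities: np.ndarray) -> float:
    """Equipartition estimate 2 KE / (3 N) for unit masses, no constraints."""
    v = np.asarray(velocities)
    n = v.shape[0]
    if n == 0:
        raise ParameterError("need at least one particle")
    return float((v * v).sum() / (3.0 * n))


def maxwell_boltzmann_velocities(n: int, T: float, rng) -> np.ndarray:
    return rng.normal(scale=math.sqrt(T), size=(n, 3))


def build_cell_list(positions: np.ndarray, box_length: float,
                    cutoff: float) -> np.ndarray:
    """Candidate pairs from a linked-cell decomposition.

    The returned (n, 2) array is a superset of every pair within ``cutoff``
    under minimum image.  Falls back to all pairs when the box fits fewer
    than three cells per side.
    """
    if cutoff > box_length / 2.0:
        raise ParameterError("cutoff must not exceed L/2 (minimum image)")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    pos = wrap_positions(np.asarray(positions, dtype=float).reshape(-1, 3),
                         box_length)
    n = len(pos)
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64)
    # cells may be larger than the cutoff (the superset contract still
    # holds); cap the grid so sparse systems don't allocate huge cell arrays
    m = min(int(box_length // cutoff), 16)
    if m < 3:
        iu = np.triu_indices(n, 1)
        return np.stack([iu[0], iu[1]], axis=1).astype(np.int64)
    cell_of = np.minimum((pos / (box_length / m)).astype(np.int64), m - 1)
    cell_id = (cell_of[:, 0] * m + cell_of[:, 1]) * m + cell_of[:, 2]
    order = np.argsort(cell_id, kind="stable")
    sorted_ids = cell_id[order]
    starts = np.searchsorted(sorted_ids, np.arange(m**3))
    ends = np.searchsorted(sorted_ids, np.arange(m**3), side="right")
    members = [order[starts[c]:ends[c]] for c in range(m**3)]
    pairs = []
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1)]
    for cx in range(m):
        for cy in range(m):
            for cz in range(m):
                a = members[(cx * m + cy) * m + cz]
                if len(a) == 0:
                    continue
                for dx, dy, dz in offsets:
                    nx, ny, nz = (cx + dx) % m, (cy + dy) % m, (cz + dz) % m
                    nid = (nx * m + ny) * m + nz
                    cid = (cx * m + cy) * m + cz
                    if nid < cid:
                        continue
                    b = members[nid]
                    if len(b) == 0:
                        continue
                    if nid == cid:
                        ii, jj = np.triu_indices(len(a), 1)
                        if len(ii):
                            pairs.append(np.stack([a[ii], a[jj]], axis=1))
                    else:
                        gi, gj = np.meshgrid(a, b, indexing="ij")
                        pairs.append(np.stack([gi.ravel(), gj.ravel()], axis=1))
    if not pairs:
        return np.zeros((0, 2), dtype=np.int64)
    out = np.concatenate(pairs).astype(np.int64)
    # periodic wrap can alias the same neighbour cell twice for small m
    keys = out.min(axis=1) * n + out.max(axis=1)
    return out[np.unique(keys, return_index=True)[1]]


class _Engine:
    """Holds the mutable state of one run and advances it chunk-wise."""

    def __init__(self, system: ParticleSystem, ff: forcefield.ForceFieldParams,
                 sim: SimulationParams, rng):
        self.system = system
        self.ff = ff
        self.sim = sim
        self.rng = rng
        self.L = sim.L
        n = system.n_particles
        self.pos = np.ascontiguousarray(system.positions, dtype=np.float64).copy()
        if system.velocities is None:
            self.vel = maxwell_boltzmann_velocities(n, sim.T, rng)
        else:
            self.vel = np.ascontiguousarray(system.velocities, dtype=np.float64).copy()
        self.charges = np.ascontiguousarray(system.charges, dtype=np.float64)
        self.diam = np.ascontiguousarray(system.diameters, dtype=np.float64)
        self.bonds = np.ascontiguousarray(system.bonds, dtype=np.int64)
        if ff.lambda_B > 0.0 and np.any(self.charges):
            if abs(system.net_charge) > 1e-9:
                raise ParameterError("charged system must be electroneutral")
            setup = forcefield.ewald_setup(self.L, ff.lambda_B, self.charges,
                                           ff.ewald_accuracy, ff.r_cut_real)
            self.alpha, self.r_cut = setup.alpha, setup.r_cut
            self.nvecs, self.kcoef = setup.nvecs, setup.kcoef
            self.two_pi_L, self.n_max = setup.two_pi_L, setup.n_max
            self.e_self = setup.self_energy
        else:
            self.alpha = self.r_cut = 0.0
            self.nvecs, self.kcoef = forcefield._EMPTY_N, forcefield._EMPTY_C
            self.two_pi_L, self.n_max = 0.0, 0
            self.e_self = 0.0
        self.c1 = math.exp(-sim.gamma * sim.dt)
        self.c2 = math.sqrt(sim.T * (1.0 - self.c1 * self.c1))
        self.forces = np.zeros((n, 3))
        self.step = 0
        # the all-pairs candidate list is position-independent; only a true
        # cell-list decomposition needs periodic rebuilds
        max_wca = forcefield.WCA_CUTOFF_FACTOR * float(self.diam.max(initial=0.0))
        cut = max(max_wca, self.r_cut) + _SKIN
        self._static_pairs = (n <= 400 or cut >= self.L / 3.0)
        self._rebuild_pairs(force=True)
        self._recompute_forces(initial=True)

    def _rebuild_pairs(self, force=False):
        if not force and self._static_pairs:
            return
        wrapped = self.system.copy()
        wrapped.positions = wrap_positions(self.pos, self.L)
        self.pairs, self.flags = forcefield.candidate_pairs(
            wrapped, self.ff, r_cut=self.r_cut, skin=_SKIN)

    def _recompute_forces(self, initial=False):
        e_wca, e_bond, e_coul, fault = _kernels.compute_forces(
            self.pos, self.charges, self.diam, self.pairs, self.flags,
            self.bonds, self.L, self.ff.epsilon, self.ff.lambda_B, self.alpha,
            self.r_cut**2, self.nvecs, self.kcoef, self.two_pi_L, self.n_max,
            self.ff.bond_style_code, self.ff.k, self.ff.R0,
            self.ff.harmonic_r0, self.forces)
        if fault >= 0:
            raise SimulationFault(
                f"bond {fault} overstretched at step {self.step}",
                step=self.step, last_good_frame=self.snapshot())
        return {"wca": e_wca, "fene": e_bond, "coulomb": e_coul + self.e_self}

    def snapshot(self) -> Frame:
        return Frame(wrap_positions(self.pos, self.L), self.system.species,
                     self.charges, self.diam, self.bonds, self.L)

    def advance(self, n_steps: int):
        n = self.pos.shape[0]
        done = 0
        while done < n_steps:
            c = min(_CHUNK, n_steps - done)
            self._rebuild_pairs()
            noise = self.rng.standard_normal((c, n, 3))
            fault = _kernels.advance_chunk(
                self.pos, self.vel, self.forces, c, self.sim.dt, self.c1,
                self.c2, noise, self.charges, self.diam, self.pairs,
                self.flags, self.bonds, self.L, self.ff.epsilon,
                self.ff.lambda_B, self.alpha, self.r_cut**2, self.nvecs,
                self.kcoef, self.two_pi_L, self.n_max,
                self.ff.bond_style_code, self.ff.k, self.ff.R0,
                self.ff.harmonic_r0)
            if fault >= 0:
                raise SimulationFault(
                    f"bond overstretch at step {self.step + fault}",
                    step=self.step + fault, last_good_frame=self.snapshot())
            if not np.isfinite(self.pos).all():
                raise SimulationFault(
                    f"non-finite positions at step {self.step + c}",
                    step=self.step + c, last_good_frame=self.snapshot())
            done += c
            self.step += c


def langevin_step(system: ParticleSystem, ff: forcefield.ForceFieldParams,
                  sim: SimulationParams, rng) -> ParticleSystem:
    """One BAOAB step; returns an updated copy of the system.

    Velocities are drawn from Maxwell-Boltzmann if the system carries none.
    Deterministic for a given Generator state.
    """
    engine = _Engine(system, ff, sim, rng)
    engine.advance(1)
    out = system.copy()
    out.positions = engine.pos.copy()
    out.velocities = engine.vel.copy()
    return out


def run_simulation(system: ParticleSystem, ff: forcefield.ForceFieldParams,
                   sim: SimulationParams) -> Trajectory:
    """Equilibrate, then sample the production run.

    Returns a Trajectory holding every ``sample_every``-th production frame
    (positions wrapped into the box) plus per-sample logs of the energy
    decomposition and instantaneous temperature.
    """
    max_cut = max(forcefield.WCA_CUTOFF_FACTOR * float(system.diameters.max(initial=1.0)),
                  ff.r_cut_real if ff.lambda_B > 0 else 0.0)
    if min(ff.r_cut_real, 0.499 * sim.L) > sim.L / 2.0 or max_cut > sim.L:
        raise ParameterError("cutoffs are inconsistent with the box size")
    rng = np.random.default_rng(sim.seed)
    engine = _Engine(system, ff, sim, rng)
    engine.advance(sim.n_equil)
    n_frames = sim.n_prod // sim.sample_every
    steps = np.empty(n_frames, dtype=np.int64)
    frames = np.empty((n_frames, system.n_particles, 3))
    logs = {k: np.empty(n_frames) for k in
            ("e_wca", "e_fene", "e_coulomb", "temperature")}
    for f in range(n_frames):
        engine.advance(sim.sample_every)
        steps[f] = engine.step
        frames[f] = wrap_positions(engine.pos, sim.L)
        energies = engine._recompute_forces()
        logs["e_wca"][f] = energies["wca"]
        logs["e_fene"][f] = energies["fene"]
        logs["e_coulomb"][f] = energies["coulomb"]
        logs["temperature"][f] = instantaneous_temperature(engine.vel)
    leftover = sim.n_prod - n_frames * sim.sample_every
    if leftover:
        engine.advance(leftover)
    params = {"forcefield": asdict(ff), "simulation": asdict(sim)}
    return Trajectory(steps=steps, positions=frames, species=system.species,
                      charges=system.charges, diameters=system.diameters,
                      bonds=system.bonds, box_length=sim.L, params=params,
                      logs=logs)
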