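import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def g2s2_topology():
    from dendrion.topology import build_dendrimer
    return build_dendrimer(2, 2)


@pytest.fixture(scope="session")
def g4s4_topology():
    from dendrion.topology import build_dendrimer
    return build_dendrimer(4, 4)


@pytest.fixture(scope="session")
def neutral_g2s2_run():
    """Short neutral-dendrimer run shared by integrator/observable tests."""
    from dendrion.forcefield import ForceFieldParams
    from dendrion.simulator import SimulationParams, run_simulation
    from dendrion.topology import build_dendrimer, embed_initial_configuration

    topo = build_dendrimer(2, 2)
    system = embed_initial_configuration(topo, None, L=40.0, seed=5)
    sim = SimulationParams(dt=0.005, gamma=1.0, T=1.0, L=40.0,
                           n_equil=10_000, n_prod=40_000, sample_every=100,
                           seed=5)
    return run_simulation(system, ForceFieldParams(lambda_B=0.0), sim), topo


def direct_image_sum(positions, charges, box_length, lambda_B, n_shells):
    """Brute-force periodic Coulomb energy by spherically ordered image sums.

    Sums q_i q_j / |r_ij + n L| shell by shell over image vectors with
    |n|^2 <= n_shells^2, including self-image terms, then removes the
    surface dipole term so the limit matches tinfoil (Ewald) boundary
    conditions.  Independent of the Ewald implementation.
    """
    pos = np.asarray(positions, float)
    q = np.asarray(charges, float)
    n = len(pos)
    rng = np.arange(-n_shells, n_shells + 1)
    nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
    ns = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], 1)
    ns = ns[(ns**2).sum(1) <= n_shells**2]
    order = np.argsort((ns**2).sum(1), kind="stable")
    ns = ns[order]
    iu, ju = np.triu_indices(n, 1)
    dij = pos[iu] - pos[ju]              # (P, 3) distinct pairs
    qq_pairs = q[iu] * q[ju]
    qq_self = 0.5 * q * q
    e = 0.0
    for chunk in np.array_split(ns, max(1, len(ns) // 2000)):
        shifts = chunk * box_length       # (C, 3)
        r_pairs = np.linalg.norm(dij[None, :, :] + shifts[:, None, :], axis=2)
        zero = np.all(chunk == 0, axis=1)
        e += (qq_pairs[None, :] / r_pairs).sum()
        r_self = np.linalg.norm(shifts, axis=1)
        nz_mask = ~zero
        if nz_mask.any():
            e += (qq_self.sum() * (1.0 / r_self[nz_mask]).sum())
    M = (q[:, None] * pos).sum(0)
    return lambda_B * e - 2 * np.pi * lambda_B * (M @ M) / (3 * box_length**3)
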