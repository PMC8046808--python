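"""Conversion between reduced Lennard-Jones units and laboratory units.

Internally every quantity in this package is dimensionless: the energy unit
is the LJ well depth epsilon = kB * 298 K, the length unit is the monomer
diameter sigma_m, and all particle masses are 1.  The monomer diameter is
identified with the Bjerrum length of water at room temperature, so that the
reduced Bjerrum length lambda_B* = eps_rw / eps_r can be dialled by changing
the relative permittivity of the implicit solvent.  These helpers live only
at the I/O boundary; the simulator never touches SI units.
"""

import math

from scipy import constants

#: Relative permittivity of water near room temperature.
EPS_R_WATER = 81.0
#: Room temperature in kelvin.
T_ROOM = 298.0


def bjerrum_length(eps_r: float = EPS_R_WATER, temperature: float = T_ROOM) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T) in metres.

    For water at 298 K this is ~6.92 Angstrom, conventionally quoted as 7 A.
    """
    e = constants.elementary_charge
    kT = constants.Boltzmann * temperature
    return e**2 / (4.0 * math.pi * constants.epsilon_0 * eps_r * kT)


def reduced_bjerrum_length(eps_r: float, temperature: float = T_ROOM) -> float:
    """lambda_B* = lambda_B(eps_r, T) / sigma_m with sigma_m = lambda_B(water, 298 K).

    At room temperature this reduces to eps_rw / eps_r.
    """
    sigma_m = bjerrum_length(EPS_R_WATER, T_ROOM)
    return bjerrum_length(eps_r, temperature) / sigma_m


def reduced_charge(temperature: float = T_ROOM) -> float:
    """Reduced elementary charge q* = e / sqrt(4 pi eps0 epsilon sigma_m).

    With epsilon = kB*298 K and sigma_m equal to the Bjerrum length of water
    this evaluates to sqrt(eps_rw) = 9.
    """
    e = constants.elementary_charge
    epsilon = constants.Boltzmann * temperature
    sigma_m = bjerrum_length(EPS_R_WATER, T_ROOM)
    return e / math.sqrt(4.0 * math.pi * constants.epsilon_0 * epsilon * sigma_m)


def lj_time(mass_g_mol: float = 30.0, temperature: float = T_ROOM) -> float:
    """LJ time unit tau = sigma_m * sqrt(m / epsilon) in seconds.

    For a bead mass of 30 g/mol this is ~2.4 ps.
    """
    mass_kg = mass_g_mol * 1e-3 / constants.Avogadro
    epsilon = constants.Boltzmann * temperature
    sigma_m = bjerrum_length(EPS_R_WATER, T_ROOM)
    return sigma_m * math.sqrt(mass_kg / epsilon)


def box_number_density(n_particles: int, box_length: float) -> float:
    """Number density N / L^3 in units of sigma_m^-3."""
    return n_particles / box_length**3
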