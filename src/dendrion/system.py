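"""The in-memory particle container shared by all modules.

A :class:`ParticleSystem` holds positions, species labels, charges, diameters
and the bonded topology of one configuration in a cubic periodic box.  The
three species are labelled ``"m"`` (monomer), ``"c"`` (conventional
counterion, diameter 1) and ``"b"`` (bulky counterion, diameter 2 or 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ParameterError

SPECIES = ("m", "c", "b")


class Frame(NamedTuple):
    """A single configuration snapshot, as handed to the analysis functions."""

    positions: np.ndarray   # (N, 3)
    species: np.ndarray     # (N,) unicode, entries in SPECIES
    charges: np.ndarray     # (N,) float valences
    diameters: np.ndarray   # (N,) float
    bonds: np.ndarray       # (M, 2) int
    box_length: float


@dataclass
class ParticleSystem:
    """Positions plus static particle attributes in a cubic periodic box."""

    positions: np.ndarray
    species: np.ndarray
    charges: np.ndarray
    diameters: np.ndarray
    bonds: np.ndarray
    box_length: float
    velocities: np.ndarray | None = None
    roles: np.ndarray | None = field(default=None)  # monomer roles, len n_monomers

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.species = np.asarray(self.species)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.diameters = np.asarray(self.diameters, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        if self.box_length <= 0:
            raise ParameterError("box_length must be positive")
        n = self.positions.shape[0]
        if not (len(self.species) == len(self.charges) == len(self.diameters) == n):
            raise ParameterError("per-particle arrays must share one length")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def monomer_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == "m")

    @property
    def charged_monomer_indices(self) -> np.ndarray:
        return np.flatnonzero((self.species == "m") & (self.charges > 0))

    def ion_indices(self, species: str) -> np.ndarray:
        if species not in ("c", "b"):
            raise ParameterError(f"unknown counterion species {species!r}")
        return np.flatnonzero(self.species == species)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def frame(self) -> Frame:
        return Frame(self.positions.copy(), self.species, self.charges,
                     self.diameters, self.bonds, self.box_length)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            species=self.species.copy(),
            charges=self.charges.copy(),
            diameters=self.diameters.copy(),
            bonds=self.bonds.copy(),
            box_length=self.box_length,
            velocities=None if self.velocities is None else self.velocities.copy(),
            roles=None if self.roles is None else self.roles.copy(),
        )


def minimum_image(displacements: np.ndarray, box_length: float) -> np.ndarray:
    """Map displacement vectors to their nearest periodic image."""
    return displacements - box_length * np.rint(displacements / box_length)


def wrap_positions(positions: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap coordinates into [0, L)."""
    return np.mod(positions, box_length)
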