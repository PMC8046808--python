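"""Conformational and counterion statistics computed from trajectories.

Definitions
-----------
* Rg: root-mean-square distance of the monomers from their centre of mass
  (unit masses), computed on coordinates unwrapped along the bond tree.
* Swelling factor alpha = Rg* / Rg0*, the charged molecule's gyration radius
  over that of its neutral analogue (same topology, all valences zero, no
  counterions).
* Absorption: a counterion is absorbed when its distance from the dendrimer
  centre of mass is strictly less than 2 Rg*; by default Rg* is the
  production-run mean (switchable to per-frame instantaneous).
* Condensation: a counterion of diameter sigma_a is condensed when its
  distance to at least one charged monomer is strictly less than
  (2 + sigma_a)/2, i.e. slightly beyond monomer-ion contact.
* The nine fractions, all relative to the total counterion number N_bg:
  absorbed f_in (conventional), f_bin (bulky), f_oin = f_in + f_bin;
  condensed f_cond, f_bcond, f_ocond = f_cond + f_bcond; delocalized
  (absorbed but not condensed) f_d = f_in - f_cond, f_bd = f_bin - f_bcond,
  f_od = f_d + f_bd.

Standard errors are block averages over contiguous frame blocks (10 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientStatisticsError, ParameterError, UnwrapError
from .system import Frame, minimum_image, wrap_positions


# ---------------------------------------------------------------------------
# geometry helpers

def unwrap_bonded(positions: np.ndarray, bonds: np.ndarray,
                  box_length: float) -> np.ndarray:
    """Unwrap bonded coordinates across periodic images along the bond tree.

    Walks the bond graph breadth-first from the lowest-indexed bonded
    particle and places every particle at its parent plus the minimum-image
    bond vector.  Raises UnwrapError if any resulting bond exceeds L/2
    (wrapped or disconnected input).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    out = pos.copy()
    if len(bonds) == 0:
        return out
    n = len(pos)
    adj = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = np.zeros(n, dtype=bool)
    root = int(bonds.min())
    seen[root] = True
    queue = [root]
    while queue:
        i = queue.pop(0)
        for j in adj[i]:
            if not seen[j]:
                d = minimum_image(pos[j] - out[i], box_length)
                if np.linalg.norm(d) > box_length / 2.0:
                    raise UnwrapError(f"bond ({i},{j}) longer than L/2 after "
                                      "minimum-image unwrap")
                out[j] = out[i] + d
                seen[j] = True
                queue.append(j)
    return out


def radius_of_gyration(positions: np.ndarray,
                       indices: np.ndarray | None = None) -> float:
    """RMS distance from the centre of mass; expects unwrapped coordinates."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if indices is not None:
        pos = pos[np.asarray(indices)]
    if len(pos) == 0:
        raise ParameterError("need at least one particle")
    com = pos.mean(axis=0)
    return float(np.sqrt(((pos - com) ** 2).sum(axis=1).mean()))


def swelling_factor(rg_charged: float, rg_neutral: float) -> float:
    """alpha = Rg*(charged) / Rg0*(neutral analogue)."""
    if rg_neutral <= 0:
        raise ParameterError("neutral baseline Rg0 must be positive")
    return rg_charged / rg_neutral


def _monomer_com_and_rg(frame: Frame):
    """Unwrapped-monomer COM (wrapped back into the box) and Rg."""
    mono = np.flatnonzero(frame.species == "m")
    unwrapped = unwrap_bonded(frame.positions, frame.bonds, frame.box_length)
    com = unwrapped[mono].mean(axis=0)
    rg = radius_of_gyration(unwrapped, mono)
    return wrap_positions(com, frame.box_length), rg


def _distances_from(points: np.ndarray, center: np.ndarray,
                    box_length: float) -> np.ndarray:
    d = minimum_image(points - center, box_length)
    return np.sqrt((d * d).sum(axis=1))


# ---------------------------------------------------------------------------
# radial profiles

@dataclass
class RadialProfile:
    """A binned radial correlation or density function."""

    bin_edges: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    center: str                 # "com" | "charged-monomers" | "box-center"
    species: str
    normalization: str          # "pair-correlation" | "number-density"
    n_frames: int
    empty: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def argmax_radius(self) -> float:
        """Radius of the most populated bin."""
        if self.empty:
            raise ParameterError("profile has no data")
        return float(self.bin_centers[int(np.argmax(self.values))])

    def integrated_count(self) -> float:
        """Sum of values * shell volumes; equals the particle count for
        number-density normalization."""
        shell = 4.0 / 3.0 * np.pi * np.diff(self.bin_edges**3)
        return float((self.values * shell).sum())


def _block_errors(per_frame_hist: np.ndarray, n_blocks: int) -> np.ndarray:
    f = per_frame_hist.shape[0]
    nb = min(n_blocks, f)
    if nb < 2:
        return np.zeros(per_frame_hist.shape[1])
    cut = (f // nb) * nb
    blocks = per_frame_hist[:cut].reshape(nb, -1, per_frame_hist.shape[1]).mean(axis=1)
    return blocks.std(axis=0, ddof=1) / np.sqrt(nb)


def _profile_from_distances(dist_per_frame, bin_edges, n_centers, volume,
                            n_targets, normalization, n_blocks):
    shell = 4.0 / 3.0 * np.pi * np.diff(bin_edges**3)
    hists = np.array([np.histogram(d, bins=bin_edges)[0] for d in dist_per_frame],
                     dtype=float)
    if normalization == "pair-correlation":
        rho = n_targets / volume
        norm = shell * rho * n_centers
    elif normalization == "number-density":
        norm = shell * n_centers
    else:
        raise ParameterError(f"unknown normalization {normalization!r}")
    hists /= norm
    return hists.mean(axis=0), _block_errors(hists, n_blocks)


def com_radial_profile(traj, target_species: str = "c", bin_width: float = 0.1,
                       r_max: float | None = None,
                       normalization: str = "pair-correlation",
                       center: str = "com", n_blocks: int = 10) -> RadialProfile:
    """Radial profile of a species around the dendrimer centre of mass.

    ``center="box-center"`` profiles around the fixed box midpoint instead
    (used by the ideal-gas calibration fixture).  Pair-correlation
    normalization divides shell counts by shell volume times the box-average
    target density; number-density divides by shell volume only.
    """
    if traj.n_frames == 0:
        raise ParameterError("trajectory has no frames")
    L = traj.box_length
    r_max = r_max if r_max is not None else L / 2.0
    if r_max > L / 2.0 + 1e-12:
        raise ParameterError("bin range must not exceed L/2")
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    target = np.flatnonzero(traj.species == target_species)
    if len(target) == 0 or (center == "com"
                            and not np.any(traj.species == "m")):
        return RadialProfile(edges, np.zeros(len(edges) - 1),
                             np.zeros(len(edges) - 1), center, target_species,
                             normalization, traj.n_frames, empty=True)
    dists = []
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        if center == "com":
            c, _ = _monomer_com_and_rg(frame)
        elif center == "box-center":
            c = np.full(3, L / 2.0)
        else:
            raise ParameterError(f"unknown center {center!r}")
        dists.append(_distances_from(frame.positions[target], c, L))
    if center == "box-center" and len(target) == 1:
        # a single particle around the box centre has no pair statistics
        return RadialProfile(edges, np.zeros(len(edges) - 1),
                             np.zeros(len(edges) - 1), center, target_species,
                             normalization, traj.n_frames, empty=True)
    values, errors = _profile_from_distances(
        dists, edges, 1, L**3, len(target), normalization, n_blocks)
    return RadialProfile(edges, values, errors, center, target_species,
                         normalization, traj.n_frames)


def charged_monomer_profile(traj, target_species: str, bin_width: float = 0.1,
                            r_max: float | None = None,
                            n_blocks: int = 10) -> RadialProfile:
    """Pair correlation of counterions around the charged monomers.

    Every charged monomer is a centre; counts are normalized per centre by
    shell volume times the box-average density of the target species, so a
    uniform gas gives 1.
    """
    if traj.n_frames == 0:
        raise ParameterError("trajectory has no frames")
    L = traj.box_length
    r_max = r_max if r_max is not None else min(L / 2.0, 10.0)
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    chm = np.flatnonzero((traj.species == "m") & (traj.charges > 0))
    target = np.flatnonzero(traj.species == target_species)
    if len(target) == 0 or len(chm) == 0:
        return RadialProfile(edges, np.zeros(len(edges) - 1),
                             np.zeros(len(edges) - 1), "charged-monomers",
                             target_species, "pair-correlation", traj.n_frames,
                             empty=True)
    dists = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        d = minimum_image(pos[target][None, :, :] - pos[chm][:, None, :], L)
        dists.append(np.sqrt((d * d).sum(axis=2)).ravel())
    values, errors = _profile_from_distances(
        dists, edges, len(chm), L**3, len(target), "pair-correlation", n_blocks)
    return RadialProfile(edges, values, errors, "charged-monomers",
                         target_species, "pair-correlation", traj.n_frames)


# ---------------------------------------------------------------------------
# counterion counting

def condensation_threshold(sigma_alpha: float) -> float:
    """(2 + sigma_alpha)/2: contact distance plus half a thermal shell."""
    return 0.5 * (2.0 + sigma_alpha)


def absorbed_counts(frame: Frame, species: str, absorption_radius: float) -> int:
    """Counterions of ``species`` strictly inside ``absorption_radius`` of
    the dendrimer centre of mass."""
    idx = np.flatnonzero(frame.species == species)
    if len(idx) == 0:
        return 0
    com, _ = _monomer_com_and_rg(frame)
    r = _distances_from(frame.positions[idx], com, frame.box_length)
    return int((r < absorption_radius).sum())


def condensed_counts(frame: Frame, species: str) -> int:
    """Counterions of ``species`` strictly within (2 + sigma)/2 of at least
    one charged monomer; each ion counted once."""
    idx = np.flatnonzero(frame.species == species)
    chm = np.flatnonzero((frame.species == "m") & (frame.charges > 0))
    if len(idx) == 0 or len(chm) == 0:
        return 0
    d = minimum_image(frame.positions[idx][:, None, :]
                      - frame.positions[chm][None, :, :], frame.box_length)
    rmin = np.sqrt((d * d).sum(axis=2)).min(axis=1)
    thresh = condensation_threshold(frame.diameters[idx])
    return int((rmin < thresh).sum())


@dataclass
class IonFractionReport:
    """The nine counterion fraction statistics with block-averaged errors."""

    f_in: float
    f_bin: float
    f_oin: float
    f_cond: float
    f_bcond: float
    f_ocond: float
    f_d: float
    f_bd: float
    f_od: float
    errors: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    FIELDS = ("f_in", "f_bin", "f_oin", "f_cond", "f_bcond", "f_ocond",
              "f_d", "f_bd", "f_od")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def fraction_report(traj, rg_source: str = "mean",
                    n_blocks: int = 10) -> IonFractionReport:
    """Frame-averaged absorbed/condensed/delocalized fractions.

    ``rg_source``: "mean" uses the production-mean Rg for the 2 Rg absorption
    radius in every frame; "instantaneous" uses each frame's own Rg.
    Derived sums and differences are formed from the averaged components, so
    the identity chain (f_oin = f_in + f_bin, etc.) holds exactly.
    """
    if rg_source not in ("mean", "instantaneous"):
        raise ParameterError(f"unknown rg_source {rg_source!r}")
    n_frames = traj.n_frames
    if n_frames < max(2, n_blocks):
        raise InsufficientStatisticsError(
            f"{n_frames} frames < {max(2, n_blocks)} needed for "
            f"{n_blocks}-block errors")
    n_bg = int((traj.species != "m").sum())
    if n_bg == 0:
        raise ParameterError("trajectory contains no counterions")
    rgs = np.empty(n_frames)
    coms = np.empty((n_frames, 3))
    for f in range(n_frames):
        coms[f], rgs[f] = _monomer_com_and_rg(traj.frame(f))
    rg_mean = float(rgs.mean())
    counts = {k: np.zeros(n_frames) for k in ("in", "bin", "cond", "bcond")}
    for f in range(n_frames):
        frame = traj.frame(f)
        r_abs = 2.0 * (rg_mean if rg_source == "mean" else rgs[f])
        for sp, a_key, c_key in (("c", "in", "cond"), ("b", "bin", "bcond")):
            idx = np.flatnonzero(frame.species == sp)
            if len(idx) == 0:
                continue
            r = _distances_from(frame.positions[idx], coms[f], frame.box_length)
            counts[a_key][f] = (r < r_abs).sum()
            counts[c_key][f] = condensed_counts(frame, sp)
    fr = {k: counts[k] / n_bg for k in counts}
    fr["oin"] = fr["in"] + fr["bin"]
    fr["ocond"] = fr["cond"] + fr["bcond"]
    fr["d"] = fr["in"] - fr["cond"]
    fr["bd"] = fr["bin"] - fr["bcond"]
    fr["od"] = fr["d"] + fr["bd"]
    means = {k: float(v.mean()) for k, v in fr.items()}
    errors = {f"f_{k}": float(_block_errors(v[:, None], n_blocks)[0])
              for k, v in fr.items()}
    n_b = int((traj.species == "b").sum())
    meta = {"rg_mean": rg_mean, "rg_source": rg_source, "n_bg": n_bg,
            "f_b": n_b / n_bg, "n_frames": n_frames}
    params = getattr(traj, "params", None) or {}
    if "forcefield" in params:
        meta["lambda_B"] = params["forcefield"].get("lambda_B")
    return IonFractionReport(
        f_in=means["in"], f_bin=means["bin"],
        f_oin=means["in"] + means["bin"],
        f_cond=means["cond"], f_bcond=means["bcond"],
        f_ocond=means["cond"] + means["bcond"],
        f_d=means["in"] - means["cond"], f_bd=means["bin"] - means["bcond"],
        f_od=(means["in"] - means["cond"]) + (means["bin"] - means["bcond"]),
        errors=errors, metadata=meta)


def trajectory_rg(traj) -> np.ndarray:
    """Per-frame gyration radius of the dendrimer."""
    return np.array([_monomer_com_and_rg(traj.frame(f))[1]
                     for f in range(traj.n_frames)])
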