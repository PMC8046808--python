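"""Configuration, trajectory and results I/O.

* Run configurations are YAML with five blocks (topology, mixture,
  forcefield, simulation, analysis); unknown keys are rejected by name and
  all validation failures are reported together.
* Trajectories are text: extended-XYZ with per-atom species/charge/diameter
  columns (bond list carried in the first frame's comment line), or the
  LAMMPS dump dialect ``id type q x y z`` with box bounds.  Coordinates are
  printed with 12 significant digits, so a round trip reproduces them to
  better than 1e-8 even in an L = 100 box.
* Results are TSV files with ``#``-prefixed metadata headers.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .errors import ConfigError, TrajectoryParseError
from .observables import IonFractionReport, RadialProfile
from .simulator import Trajectory

_TYPE_OF_SPECIES = {"m": 1, "c": 2, "b": 3}
_SPECIES_OF_TYPE = {v: k for k, v in _TYPE_OF_SPECIES.items()}
_FMT = "%.12g"


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class TopologyBlock:
    G: int = 4
    S: int = 4


@dataclass
class MixtureBlock:
    f_b: float = 0.0
    sigma_b: float = 2.0


@dataclass
class ForceFieldBlock:
    lambda_B: float = 1.0
    ewald_accuracy: float = 1e-4
    r_cut_real: float = 10.0


@dataclass
class SimulationBlock:
    dt: float = 0.005
    gamma: float = 1.0
    T: float = 1.0
    L: float = 100.0
    n_equil: int = 1_000_000
    n_prod: int = 10_000_000
    sample_every: int = 1000
    seed: int = 0
    preset: str | None = None


@dataclass
class AnalysisBlock:
    gr_bin_width: float = 0.1
    com_bin_width: float = 0.1
    n_blocks: int = 10
    rg_source: str = "mean"


@dataclass
class RunConfig:
    """Validated run description; derived counts come from the topology."""

    topology: TopologyBlock = field(default_factory=TopologyBlock)
    mixture: MixtureBlock = field(default_factory=MixtureBlock)
    forcefield: ForceFieldBlock = field(default_factory=ForceFieldBlock)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)

    @property
    def n_monomers(self) -> int:
        from .topology import monomer_count
        return monomer_count(self.topology.G, self.topology.S)

    @property
    def n_counterions(self) -> int:
        from .topology import branching_group_count
        return branching_group_count(self.topology.G)

    def validate(self):
        problems = []
        t, m, f, s, a = (self.topology, self.mixture, self.forcefield,
                         self.simulation, self.analysis)
        if t.G < 1 or int(t.G) != t.G:
            problems.append(f"topology.G must be a positive integer, got {t.G}")
        if t.S < 1 or int(t.S) != t.S:
            problems.append(f"topology.S must be a positive integer, got {t.S}")
        if not 0.0 <= m.f_b <= 1.0:
            problems.append(f"mixture.f_b must lie in [0, 1], got {m.f_b}")
        if m.sigma_b < 1.0:
            problems.append(f"mixture.sigma_b must be >= 1, got {m.sigma_b}")
        if f.lambda_B < 0:
            problems.append(f"forcefield.lambda_B must be >= 0, got {f.lambda_B}")
        if not 0 < f.ewald_accuracy < 1:
            problems.append("forcefield.ewald_accuracy must lie in (0, 1)")
        if f.r_cut_real <= 0:
            problems.append("forcefield.r_cut_real must be positive")
        for name, val in (("dt", s.dt), ("T", s.T), ("L", s.L)):
            if val <= 0:
                problems.append(f"simulation.{name} must be positive, got {val}")
        if s.gamma < 0:
            problems.append(f"simulation.gamma must be >= 0, got {s.gamma}")
        if s.sample_every < 1:
            problems.append("simulation.sample_every must be >= 1")
        if s.n_equil < 0 or s.n_prod < 0:
            problems.append("simulation step counts must be non-negative")
        if s.preset not in (None, "desk_scale", "paper_scale"):
            problems.append(f"unknown simulation.preset {s.preset!r}")
        if a.gr_bin_width <= 0 or a.com_bin_width <= 0:
            problems.append("analysis bin widths must be positive")
        if a.n_blocks < 2:
            problems.append("analysis.n_blocks must be >= 2")
        if a.rg_source not in ("mean", "instantaneous"):
            problems.append(f"unknown analysis.rg_source {a.rg_source!r}")
        if problems:
            raise ConfigError("invalid configuration:\n  - "
                              + "\n  - ".join(problems))
        if f.lambda_B and not 0.125 <= f.lambda_B <= 16.0:
            warnings.warn(f"lambda_B = {f.lambda_B} lies outside the studied "
                          "range [0.125, 16]", stacklevel=3)
        return self


_BLOCK_TYPES = {"topology": TopologyBlock, "mixture": MixtureBlock,
                "forcefield": ForceFieldBlock, "simulation": SimulationBlock,
                "analysis": AnalysisBlock}


def read_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = [k for k in raw if k not in _BLOCK_TYPES]
    if unknown:
        raise ConfigError(f"unknown configuration block(s): {sorted(unknown)}")
    blocks = {}
    bad_keys = []
    for name, cls in _BLOCK_TYPES.items():
        sub = raw.get(name, {}) or {}
        allowed = {f.name for f in fields(cls)}
        bad_keys += [f"{name}.{k}" for k in sub if k not in allowed]
        blocks[name] = cls(**{k: v for k, v in sub.items() if k in allowed})
    if bad_keys:
        raise ConfigError(f"unknown configuration key(s): {sorted(bad_keys)}")
    return RunConfig(**blocks).validate()


def write_config(config: RunConfig, path):
    config.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trajectories

def write_trajectory(traj: Trajectory, path, fmt: str = "extended-xyz"):
    if fmt == "extended-xyz":
        _write_xyz(traj, path)
    elif fmt == "lammps-dump":
        _write_dump(traj, path)
    else:
        raise TrajectoryParseError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, fmt: str = "extended-xyz",
                    sigma_b: float = 2.0) -> Trajectory:
    if fmt == "extended-xyz":
        return _read_xyz(path)
    if fmt == "lammps-dump":
        return _read_dump(path, sigma_b)
    raise TrajectoryParseError(f"unknown trajectory format {fmt!r}")


def _bond_string(bonds) -> str:
    return " ".join(f"{i}-{j}" for i, j in bonds)


def _write_xyz(traj: Trajectory, path):
    L = traj.box_length
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            comment = (f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
                       'Properties=species:S:1:pos:R:3:charge:R:1:diameter:R:1 '
                       f"step={int(traj.steps[f])}")
            if f == 0 and len(traj.bonds):
                comment += f' bonds="{_bond_string(traj.bonds)}"'
            fh.write(comment + "\n")
            for i in range(traj.n_particles):
                x, y, z = traj.positions[f, i]
                fh.write(f"{traj.species[i]} {_FMT % x} {_FMT % y} {_FMT % z} "
                         f"{_FMT % traj.charges[i]} "
                         f"{_FMT % traj.diameters[i]}\n")


def _read_xyz(path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, steps = [], []
    species = charges = diameters = None
    bonds = np.zeros((0, 2), dtype=np.int64)
    L = None
    ln = 0
    frame_idx = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"line {ln + 1}: expected atom count") from None
        if ln + 1 >= len(lines):
            raise TrajectoryParseError(f"frame {frame_idx}: missing comment "
                                       f"line (line {ln + 2})")
        comment = lines[ln + 1]
        kv = _parse_xyz_comment(comment, ln + 2)
        if "Lattice" in kv:
            L = float(kv["Lattice"].split()[0])
        if "bonds" in kv and kv["bonds"]:
            bonds = np.array([[int(a) for a in pair.split("-")]
                              for pair in kv["bonds"].split()], dtype=np.int64)
        step = int(float(kv.get("step", frame_idx)))
        body = lines[ln + 2: ln + 2 + n]
        if len(body) < n:
            raise TrajectoryParseError(
                f"frame {frame_idx}: truncated after {len(body)} of {n} atoms "
                f"(line {ln + 2 + len(body)})")
        sp, pos, q, d = [], [], [], []
        for k, row in enumerate(body):
            parts = row.split()
            if len(parts) < 6:
                raise TrajectoryParseError(
                    f"line {ln + 3 + k}: expected 6 columns, got {len(parts)}")
            sp.append(parts[0])
            pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            q.append(float(parts[4]))
            d.append(float(parts[5]))
        if species is None:
            species = np.array(sp)
            charges = np.array(q)
            diameters = np.array(d)
        frames.append(pos)
        steps.append(step)
        ln += 2 + n
        frame_idx += 1
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    if L is None:
        raise TrajectoryParseError("no Lattice entry found in any header")
    return Trajectory(steps=np.array(steps, dtype=np.int64),
                      positions=np.array(frames, dtype=float),
                      species=species, charges=charges, diameters=diameters,
                      bonds=bonds, box_length=L, params={"source": str(path)},
                      logs=None)


def _parse_xyz_comment(comment: str, lineno: int) -> dict:
    """Parse key=value pairs with optional double-quoted values."""
    out = {}
    i = 0
    s = comment
    while i < len(s):
        if s[i].isspace():
            i += 1
            continue
        eq = s.find("=", i)
        if eq < 0:
            break
        key = s[i:eq].strip()
        j = eq + 1
        if j < len(s) and s[j] == '"':
            end = s.find('"', j + 1)
            if end < 0:
                raise TrajectoryParseError(f"line {lineno}: unterminated quote")
            out[key] = s[j + 1:end]
            i = end + 1
        else:
            end = j
            while end < len(s) and not s[end].isspace():
                end += 1
            out[key] = s[j:end]
            i = end
    return out


def _write_dump(traj: Trajectory, path):
    L = traj.box_length
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n%d\n" % int(traj.steps[f]))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % traj.n_particles)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0 {_FMT % L}\n")
            fh.write("ITEM: ATOMS id type q x y z\n")
            for i in range(traj.n_particles):
                x, y, z = traj.positions[f, i]
                fh.write(f"{i + 1} {_TYPE_OF_SPECIES[str(traj.species[i])]} "
                         f"{_FMT % traj.charges[i]} "
                         f"{_FMT % x} {_FMT % y} {_FMT % z}\n")


def _read_dump(path, sigma_b: float = 2.0) -> Trajectory:
    """Read the ``id type q x y z`` dump dialect.

    Diameters are reconstructed from the type map (monomer and conventional
    ion 1, bulky ion ``sigma_b``); the dump format does not carry them.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, steps = [], []
    species = charges = None
    L = None
    ln = 0
    frame_idx = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        if not lines[ln].startswith("ITEM: TIMESTEP"):
            raise TrajectoryParseError(f"line {ln + 1}: expected ITEM: TIMESTEP")
        try:
            step = int(lines[ln + 1])
            n = int(lines[ln + 3])
            lo, hi = (float(x) for x in lines[ln + 5].split()[:2])
        except (IndexError, ValueError):
            raise TrajectoryParseError(
                f"frame {frame_idx}: malformed header near line {ln + 1}") from None
        L = hi - lo
        header = lines[ln + 8]
        cols = header.replace("ITEM: ATOMS", "").split()
        if cols[:6] != ["id", "type", "q", "x", "y", "z"]:
            raise TrajectoryParseError(
                f"line {ln + 9}: unsupported ATOMS columns {cols}")
        body = lines[ln + 9: ln + 9 + n]
        if len(body) < n:
            raise TrajectoryParseError(
                f"frame {frame_idx}: truncated after {len(body)} of {n} atoms")
        rows = np.array([[float(x) for x in row.split()] for row in body])
        order = np.argsort(rows[:, 0])
        rows = rows[order]
        if species is None:
            species = np.array([_SPECIES_OF_TYPE[int(t)] for t in rows[:, 1]])
            charges = rows[:, 2].copy()
        frames.append(rows[:, 3:6])
        steps.append(step)
        ln += 9 + n
        frame_idx += 1
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    diameters = np.where(species == "b", sigma_b, 1.0)
    return Trajectory(steps=np.array(steps, dtype=np.int64),
                      positions=np.array(frames), species=species,
                      charges=charges, diameters=diameters,
                      bonds=np.zeros((0, 2), dtype=np.int64), box_length=L,
                      params={"source": str(path)}, logs=None)


# ---------------------------------------------------------------------------
# results

def write_profile_tsv(profile: RadialProfile, path):
    """One TSV per profile: r, value, stderr; '#' metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# center={profile.center} species={profile.species} "
                 f"normalization={profile.normalization} "
                 f"n_frames={profile.n_frames}\n")
        fh.write("# r\tvalue\tstderr\n")
        if profile.empty:
            return
        for r, v, e in zip(profile.bin_centers, profile.values, profile.errors):
            fh.write(f"{_FMT % r}\t{_FMT % v}\t{_FMT % e}\n")


def write_fractions_tsv(report: IonFractionReport, path):
    """The nine fractions with errors; metadata lines prefixed '#'."""
    with open(path, "w") as fh:
        for k, v in report.metadata.items():
            fh.write(f"# {k}={v}\n")
        cols = IonFractionReport.FIELDS
        fh.write("row\t" + "\t".join(cols) + "\n")
        fh.write("value\t" + "\t".join(_FMT % getattr(report, c)
                                       for c in cols) + "\n")
        fh.write("stderr\t" + "\t".join(_FMT % report.errors.get(c, 0.0)
                                        for c in cols) + "\n")


def write_results(profiles: dict, report: IonFractionReport | None, outdir):
    """Emit one TSV per named profile plus the fraction table."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for name, profile in profiles.items():
        write_profile_tsv(profile, os.path.join(outdir, f"{name}.tsv"))
    if report is not None:
        write_fractions_tsv(report, os.path.join(outdir, "fractions.tsv"))
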