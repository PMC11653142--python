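"""Stand-in coarse-grained CA Monte Carlo sampler.

This is NOT the CABS lattice engine.  It is a deliberately simple
off-lattice CA-bead sampler whose only job is to exercise restraint sets
end-to-end: a harmonic virtual-bond term keeps the chain connected, a soft
excluded-volume term keeps beads apart, and the flat-bottom restraint
energy discourages moves that violate the restraints.  Single-bead
Gaussian-displacement moves are accepted by the Metropolis criterion at
fixed kT; energies are in kT units.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import DivergenceError, MalformedInput, RangeError
from .restraints import RestraintConfig, RestraintSet, restraint_energy
from .structure import ProteinStructure

__all__ = [
    "SamplerConfig",
    "Trajectory",
    "pseudo_energy",
    "run_sampler",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_trajectory_table",
    "read_trajectory_table",
]

_DIVERGENCE_RADIUS = 1e3  # Å from the initial centroid


@dataclass(frozen=True)
class SamplerConfig:
    """Tunables of the stand-in sampler (energies in kT units)."""

    n_steps: int = 200_000
    snapshot_every: int = 1_000
    temperature: float = 0.3  # dimensionless kT; see docs/methods.md
    move_sigma: float = 0.35  # Å, per-axis s.d. of the single-bead move
    bond_length: float = 3.8  # Å, ideal CA-CA virtual bond
    bond_k: float = 20.0  # energy/Å², harmonic bond stiffness
    ev_radius: float = 3.5  # Å, soft excluded-volume onset
    ev_k: float = 5.0  # energy/Å², excluded-volume stiffness
    seed: int = 7503

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise RangeError("n_steps must be non-negative")
        for name in ("snapshot_every", "temperature", "move_sigma", "bond_length",
                     "bond_k", "ev_radius", "ev_k"):
            if getattr(self, name) <= 0:
                raise RangeError(f"{name} must be positive")
        if self.n_steps and self.snapshot_every > self.n_steps:
            raise RangeError("snapshot_every must not exceed n_steps")


@dataclass
class Trajectory:
    """Ordered CA-coordinate snapshots, shape (n_frames, n_residues, 3) in Å."""

    frames: np.ndarray
    frame_interval: int = 1
    acceptance_rate: float | None = None
    final_energy: float | None = None
    #: incrementally tracked pseudo-energy at each snapshot (diagnostic)
    frame_energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[2] != 3:
            raise RangeError(f"frames must be (n_frames, n_residues, 3), got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise RangeError("trajectory contains non-finite coordinates")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]


def _bond_pairs(structure: ProteinStructure) -> list[tuple[int, int]]:
    """Consecutive same-chain residue pairs (virtual bonds)."""
    pairs = []
    for i in range(len(structure) - 1):
        if structure[i].chain_id == structure[i + 1].chain_id:
            pairs.append((i, i + 1))
    return pairs


def pseudo_energy(
    coords: np.ndarray,
    restraints: RestraintSet,
    config: SamplerConfig | None = None,
    structure: ProteinStructure | None = None,
) -> float:
    """Total stand-in energy of one conformation, in kT.

    Sum of (a) harmonic virtual-bond term over consecutive intra-chain
    pairs, (b) soft excluded-volume penalty for non-bonded pairs closer
    than ``ev_radius``, (c) the flat-bottom restraint energy.  Without a
    ``structure``, all consecutive index pairs are treated as bonded.
    """
    config = config or SamplerConfig()
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if structure is not None:
        bonds = _bond_pairs(structure)
    else:
        bonds = [(i, i + 1) for i in range(n - 1)]
    bonded = set(bonds)

    e = 0.0
    for i, j in bonds:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        e += config.bond_k * (d - config.bond_length) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < config.ev_radius:
                e += config.ev_k * (config.ev_radius - d) ** 2
    rcfg = restraints.config or RestraintConfig()
    for r in restraints:
        d = float(np.linalg.norm(coords[r.i] - coords[r.j]))
        e += restraint_energy(d, r, rcfg.flat_halfwidth, rcfg.penalty)
    return e


class _EnergyModel:
    """Precomputed neighbor lists for O(n) single-bead energy deltas."""

    def __init__(
        self,
        structure: ProteinStructure,
        restraints: RestraintSet,
        config: SamplerConfig,
    ) -> None:
        self.cfg = config
        n = len(structure)
        self.n = n
        bonds = _bond_pairs(structure)
        self.bond_partners: list[list[int]] = [[] for _ in range(n)]
        bonded_mask = np.zeros((n, n), dtype=bool)
        for i, j in bonds:
            self.bond_partners[i].append(j)
            self.bond_partners[j].append(i)
            bonded_mask[i, j] = bonded_mask[j, i] = True
        # per-residue restraint arrays: partner index, d0, slopes
        rcfg = restraints.config or RestraintConfig()
        self.flat_halfwidth = rcfg.flat_halfwidth
        self.penalty = rcfg.penalty
        per_res: list[list[tuple[int, float, float, float]]] = [[] for _ in range(n)]
        for r in restraints:
            per_res[r.i].append((r.j, r.d0, r.slope_min, r.slope_max))
            per_res[r.j].append((r.i, r.d0, r.slope_min, r.slope_max))
        self.r_partner = [np.array([t[0] for t in lst], dtype=int) for lst in per_res]
        self.r_d0 = [np.array([t[1] for t in lst]) for lst in per_res]
        self.r_smin = [np.array([t[2] for t in lst]) for lst in per_res]
        self.r_smax = [np.array([t[3] for t in lst]) for lst in per_res]
        # excluded-volume mask per residue: everything except self and bonded
        self.ev_mask = ~(bonded_mask | np.eye(n, dtype=bool))

    def local_energy(self, coords: np.ndarray, k: int, pos: np.ndarray) -> float:
        """Energy of all terms involving bead ``k`` placed at ``pos``."""
        cfg = self.cfg
        e = 0.0
        for nb in self.bond_partners[k]:
            d = float(np.linalg.norm(pos - coords[nb]))
            e += cfg.bond_k * (d - cfg.bond_length) ** 2
        d_all = np.linalg.norm(coords - pos, axis=1)
        ev = d_all[self.ev_mask[k]]
        close = ev[ev < cfg.ev_radius]
        if close.size:
            e += cfg.ev_k * float(np.sum((cfg.ev_radius - close) ** 2))
        part = self.r_partner[k]
        if part.size:
            d = d_all[part]
            dev = d - self.r_d0[k]
            w = self.flat_halfwidth
            over = np.clip(dev - w, 0.0, None)
            under = np.clip(-dev - w, 0.0, None)
            if self.penalty == "quadratic":
                over, under = over**2, under**2
            e += float(np.sum(self.r_smax[k] * over) + np.sum(self.r_smin[k] * under))
        return e


def run_sampler(
    structure: ProteinStructure,
    restraints: RestraintSet,
    config: SamplerConfig | None = None,
) -> Trajectory:
    """Run the stand-in Metropolis sampler and return snapshots.

    Moves displace one bead at a time by an isotropic Gaussian of s.d.
    ``move_sigma``; acceptance is min(1, exp(−ΔE/kT)).  Snapshots are taken
    every ``snapshot_every`` *attempted* moves (so snapshot indexing does
    not depend on acceptance history); the first frame is the input
    conformation.  Raises :class:`DivergenceError` if any coordinate drifts
    more than 1000 Å from the initial centroid.
    """
    config = config or SamplerConfig()
    coords = structure.ca_coords().copy()
    n = len(coords)
    centroid0 = coords.mean(axis=0)
    model = _EnergyModel(structure, restraints, config)

    rng = np.random.default_rng(config.seed)
    steps = config.n_steps
    frames = [coords.copy()]
    n_accept = 0
    energy = pseudo_energy(coords, restraints, config, structure)
    energies = [energy]
    if steps:
        which = rng.integers(0, n, size=steps)
        disp = rng.normal(0.0, config.move_sigma, size=(steps, 3))
        unif = rng.random(steps)
        kT = config.temperature
        for t in range(steps):
            k = int(which[t])
            old = coords[k].copy()
            new = old + disp[t]
            de = model.local_energy(coords, k, new) - model.local_energy(coords, k, old)
            if de <= 0.0 or unif[t] < np.exp(-de / kT):
                coords[k] = new
                energy += de
                n_accept += 1
            if (t + 1) % config.snapshot_every == 0:
                _check_divergence(coords, centroid0)
                frames.append(coords.copy())
                energies.append(energy)
    return Trajectory(
        frames=np.stack(frames),
        frame_interval=config.snapshot_every,
        acceptance_rate=(n_accept / steps) if steps else None,
        final_energy=energy,
        frame_energies=np.array(energies),
    )


def _check_divergence(coords: np.ndarray, centroid0: np.ndarray) -> None:
    drift = np.linalg.norm(coords - centroid0, axis=1)
    if drift.max() > _DIVERGENCE_RADIUS:
        raise DivergenceError(
            f"coordinate drifted {drift.max():.0f} Å from the initial centroid"
        )


def write_trajectory_pdb(
    traj: Trajectory, structure: ProteinStructure | None = None
) -> str:
    """Serialize a trajectory as a CA-only multi-model PDB (MODEL/ENDMDL)."""
    nf, n = traj.n_frames, traj.n_residues
    atoms = struc.AtomArray(n)
    if structure is not None:
        if len(structure.ca_indices) != n:
            raise RangeError("structure CA count does not match trajectory width")
        idx = structure.ca_indices
        atoms.chain_id = np.array([structure[i].chain_id for i in idx])
        atoms.res_id = np.array([structure[i].res_num for i in idx])
        atoms.res_name = np.array([structure[i].res_name for i in idx])
        atoms.ins_code = np.array([structure[i].icode or "" for i in idx])
    else:
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    stack = struc.AtomArrayStack(nf, n)
    for cat in atoms.get_annotation_categories():
        stack.set_annotation(cat, atoms.get_annotation(cat))
    stack.coord = traj.frames
    pdb = PDBFile()
    pdb.set_structure(stack)
    return "\n".join(pdb.lines) + "\n"


def read_trajectory_pdb(pdb_text: str) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (CA atoms only, all models)."""
    if not pdb_text.strip():
        raise MalformedInput("empty trajectory PDB text")
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        stack = pdb.get_structure(altloc="first")
    except MalformedInput:
        raise
    except Exception as exc:
        raise MalformedInput(f"could not parse trajectory PDB: {exc}") from exc
    if stack.array_length() == 0:
        raise MalformedInput("no atoms in trajectory PDB")
    ca = stack[:, stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise MalformedInput("no CA atoms in trajectory PDB")
    return Trajectory(frames=ca.coord)


def write_trajectory_table(traj: Trajectory) -> str:
    """Plain-text table: ``frame residue x y z`` per line, '#' header."""
    lines = ["# frame residue x y z"]
    for f in range(traj.n_frames):
        for i in range(traj.n_residues):
            x, y, z = traj.frames[f, i]
            lines.append(f"{f} {i} {x:.3f} {y:.3f} {z:.3f}")
    return "\n".join(lines) + "\n"


def read_trajectory_table(text: str) -> Trajectory:
    """Parse the plain-text trajectory table format."""
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise MalformedInput(f"line {lineno}: expected 5 fields")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise MalformedInput(f"line {lineno}: non-numeric field")
    if not rows:
        raise MalformedInput("no data rows in trajectory table")
    arr = np.array(rows)
    n_frames = int(arr[:, 0].max()) + 1
    n_res = int(arr[:, 1].max()) + 1
    frames = np.full((n_frames, n_res, 3), np.nan)
    frames[arr[:, 0].astype(int), arr[:, 1].astype(int)] = arr[:, 2:5]
    if np.isnan(frames).any():
        raise MalformedInput("trajectory table has missing (frame, residue) entries")
    return Trajectory(frames=frames)
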