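"""Synthetic structures, pLDDT profiles and trajectories with planted signal.

Everything downstream (restraint generation, the sampler, RMSF scoring) is
testable offline against fixtures built here: CA traces with ideal helix
geometry and defined coil/turn segments, per-residue pLDDT profiles, and
trajectories whose per-residue fluctuation magnitudes are planted, so the
expected RMSF is known in closed form.  Fixtures are statistical stand-ins,
not physical models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import MissingScore, SpecError
from .sampler import Trajectory
from .structure import ProteinStructure, Residue, SecondaryStructure, write_structure_pdb

__all__ = [
    "SegmentSpec",
    "PlantedFlexibility",
    "make_toy_structure",
    "make_planted_trajectory",
    "make_af_like_pdb",
    "planted_from_structure",
    "make_helix_coil_helix",
    "make_benchmark_cohort",
]

# ideal alpha-helix CA geometry: 1.5 A rise, 2.3 A radius, 100 degrees/residue
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = math.radians(100.0)
_STEP = 3.8  # extended/turn CA step, A
_COORD_JITTER = 0.02  # A, keeps fixtures distinct across seeds


@dataclass(frozen=True)
class SegmentSpec:
    """One secondary-structure segment of a synthetic chain.

    ``geometry`` controls the CA trace shape independently of the ``ss``
    label when set (e.g. a COIL-labelled loop laid out as a TURN arc so a
    chain can fold back on itself); it defaults to the label's own shape.
    """

    ss_class: SecondaryStructure
    length: int
    plddt_level: float = 90.0
    plddt_jitter: float = 0.0
    geometry: SecondaryStructure | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SpecError("segment length must be >= 1")
        if not (0.0 <= self.plddt_level <= 100.0):
            raise SpecError("plddt_level must lie in [0, 100]")
        if self.plddt_jitter < 0:
            raise SpecError("plddt_jitter must be non-negative")

    @property
    def shape(self) -> SecondaryStructure:
        return self.geometry or self.ss_class


@dataclass(frozen=True)
class PlantedFlexibility:
    """Per-residue target fluctuation magnitudes sigma (Å)."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if (s < 0).any() or not np.all(np.isfinite(s)):
            raise SpecError("planted sigma values must be finite and non-negative")
        object.__setattr__(self, "sigma", s)


def _segment_local_coords(spec: SegmentSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment CA coordinates in a local frame advancing along +z.

    Returns ``(points, t_in, t_out)`` where the tangents are the directions
    the chain enters and leaves the segment with; placement rotates
    ``t_in`` onto the current chain heading so helices propagate by their
    axis and turn arcs genuinely bend the heading.
    """
    k = np.arange(spec.length)
    z = np.array([0.0, 0.0, 1.0])
    if spec.shape is SecondaryStructure.HELIX:
        theta = k * _HELIX_TWIST
        pts = np.column_stack(
            [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * k]
        )
        return pts, z, z  # enters and leaves along the helix axis
    if spec.shape is SecondaryStructure.TURN:
        # smooth 90-degree arc with constant 3.8 A chord steps
        total = math.radians(90.0)
        phi = total / spec.length
        rho = _STEP / (2.0 * math.sin(phi / 2.0))
        ang = k * phi
        pts = np.column_stack(
            [rho * (1.0 - np.cos(ang)), np.zeros_like(ang), rho * np.sin(ang)]
        )
        t_out = np.array([math.sin(total), 0.0, math.cos(total)])
        return pts, z, t_out
    # SHEET / COIL: extended 3.8 A steps
    pts = np.column_stack([np.zeros(spec.length), np.zeros(spec.length), _STEP * k])
    return pts, z, z


def _rotation_mapping(a: np.ndarray, b: np.ndarray) -> Rotation:
    """Minimal rotation taking unit vector a onto unit vector b."""
    rot, _ = Rotation.align_vectors(b[None, :], a[None, :])
    return rot


def make_toy_structure(
    segments: list[SegmentSpec], seed: int = 7503, chain_id: str = "A"
) -> ProteinStructure:
    """Build a synthetic CA trace from secondary-structure segments.

    Helix segments use ideal alpha geometry; sheet/coil segments are
    extended 3.8 Å steps; turns are smooth 90° arcs.  Segments are chained
    head-to-tail so every consecutive CA distance stays in [3.6, 4.0] Å.
    pLDDT per residue is the segment level plus seeded Gaussian jitter
    (clipped to [0, 100]); a tiny coordinate jitter makes fixtures distinct
    across seeds while preserving the geometric contract.  Deterministic
    per (segments, seed).
    """
    if not segments:
        raise SpecError("at least one segment is required")
    rng = np.random.default_rng(seed)

    coords_parts: list[np.ndarray] = []
    end: np.ndarray | None = None
    heading = np.array([0.0, 0.0, 1.0])
    for spec in segments:
        local, t_in, t_out = _segment_local_coords(spec)
        rot = _rotation_mapping(t_in, heading)
        placed = rot.apply(local - local[0])
        anchor = np.zeros(3) if end is None else end + _STEP * heading
        placed = placed + anchor
        coords_parts.append(placed)
        end = placed[-1]
        heading = rot.apply(t_out)
    coords = np.vstack(coords_parts)
    coords = coords + rng.normal(0.0, _COORD_JITTER, size=coords.shape)

    residues: list[Residue] = []
    pos = 0
    for spec in segments:
        plddt = np.clip(
            spec.plddt_level + rng.normal(0.0, spec.plddt_jitter, size=spec.length),
            0.0,
            100.0,
        )
        for k in range(spec.length):
            residues.append(
                Residue(
                    chain_id=chain_id,
                    res_num=pos + 1,
                    res_name="ALA",
                    ca=coords[pos],
                    plddt=float(plddt[k]),
                    ss=spec.ss_class,
                )
            )
            pos += 1
    return ProteinStructure(residues=residues, source_id=f"toy-seed{seed}")


def make_planted_trajectory(
    structure: ProteinStructure,
    flex: PlantedFlexibility,
    n_frames: int,
    seed: int = 7503,
    rigid_motion: bool = False,
) -> Trajectory:
    """Gaussian-noise trajectory with a planted per-residue RMSF.

    Each frame is the reference plus independent isotropic Gaussian noise
    with per-axis s.d. sigma_i/sqrt(3), so the expected RMSF of residue i
    is exactly sigma_i.  With ``rigid_motion`` a random rotation and
    translation is applied per frame (superposition should remove it).
    """
    if n_frames < 2:
        raise SpecError("a planted trajectory needs at least 2 frames")
    ref = structure.ca_coords()
    sigma = flex.sigma
    if len(sigma) != len(ref):
        raise SpecError(
            f"planted sigma length {len(sigma)} != {len(ref)} residues"
        )
    rng = np.random.default_rng(seed)
    per_axis = sigma[None, :, None] / math.sqrt(3.0)
    frames = ref[None, :, :] + rng.normal(size=(n_frames, len(ref), 3)) * per_axis
    if rigid_motion:
        for f in range(n_frames):
            rot = Rotation.random(rng=rng)
            shift = rng.uniform(-5.0, 5.0, size=3)
            frames[f] = rot.apply(frames[f]) + shift
    return Trajectory(frames=frames)


def make_af_like_pdb(structure: ProteinStructure) -> str:
    """PDB text with pLDDT in the B-factor column (AlphaFold model style)."""
    if not structure.has_full_plddt:
        raise MissingScore("every CA residue needs a pLDDT score for an AF-style PDB")
    return write_structure_pdb(structure, plddt_as_bfactor=True)


#: default planted fluctuation magnitudes (Å) by secondary structure:
#: flexible coil, intermediate turn, rigid regular structure
_DEFAULT_SIGMA_BY_SS = {
    SecondaryStructure.COIL: 1.2,
    SecondaryStructure.TURN: 0.7,
    SecondaryStructure.HELIX: 0.3,
    SecondaryStructure.SHEET: 0.3,
}


def planted_from_structure(
    structure: ProteinStructure,
    sigma_by_ss: dict[SecondaryStructure, float] | None = None,
) -> PlantedFlexibility:
    """Map segment classes to planted sigmas (coil flexible, helix/sheet rigid).

    The default mirrors the common observation that low-confidence loops
    and termini are the dynamic parts of a structure; pass a custom map to
    build counter-examples such as a rigid low-pLDDT helix.
    """
    table = sigma_by_ss or _DEFAULT_SIGMA_BY_SS
    sigma = np.array([table[r.ss] for r in structure])
    return PlantedFlexibility(sigma=sigma)


def make_helix_coil_helix(seed: int = 7503) -> ProteinStructure:
    """30-residue benchmark fixture: flexible coil termini, rigid helix hairpin.

    Layout: coil×4 (pLDDT 40) | helix×9 (95) | coil×4 loop (40) | helix×9
    (95) | coil×4 (40).  The loop is laid out as a U-turn so the two
    helices pack antiparallel within restraint range of each other — a
    compact single-domain core, not a floppy dumbbell.  Under Category-mode
    rules the low-confidence coil termini and loop are fully flexible
    (category 0, unrestrained) and the helix cores rigid (category 3).
    """
    turn = SecondaryStructure.TURN
    return make_toy_structure(
        [
            SegmentSpec(SecondaryStructure.COIL, 4, 40.0, 2.0),
            SegmentSpec(SecondaryStructure.HELIX, 9, 95.0, 1.0),
            SegmentSpec(SecondaryStructure.COIL, 2, 40.0, 2.0, geometry=turn),
            SegmentSpec(SecondaryStructure.COIL, 2, 40.0, 2.0, geometry=turn),
            SegmentSpec(SecondaryStructure.HELIX, 9, 95.0, 1.0),
            SegmentSpec(SecondaryStructure.COIL, 4, 40.0, 2.0),
        ],
        seed=seed,
    )


def make_compact_serpentine(n: int = 30, seed: int = 7503) -> ProteinStructure:
    """Maximally compact CA fold: a boustrophedon path on a 3.8 Å grid.

    Every bead sits deep inside the restraint cutoff of many others
    (typically 15+ partners under the default 11.5 Å), which makes this the
    fixture of choice for dense-network limit checks such as
    rigidification; chain steps are exactly one grid spacing, and
    non-bonded lattice neighbors (3.8 Å) sit outside the soft
    excluded-volume shell.
    """
    if n < 2:
        raise SpecError("serpentine fold needs at least 2 residues")
    rng = np.random.default_rng(seed)
    side = 3
    coords = []
    i = 0
    z = 0
    while len(coords) < n:
        ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
        for yi, y in enumerate(ys):
            xs = range(side) if (z + yi) % 2 == 0 else range(side - 1, -1, -1)
            for x in xs:
                coords.append((x * _STEP, y * _STEP, z * _STEP))
                if len(coords) == n:
                    break
            if len(coords) == n:
                break
        z += 1
    arr = np.asarray(coords, dtype=float) + rng.normal(0.0, _COORD_JITTER, size=(n, 3))
    residues = [
        Residue(chain_id="A", res_num=k + 1, res_name="ALA", ca=arr[k],
                plddt=90.0, ss=SecondaryStructure.COIL)
        for k in range(n)
    ]
    return ProteinStructure(residues=residues, source_id=f"serpentine-seed{seed}")


def make_benchmark_cohort(
    n_proteins: int = 10, base_seed: int = 7503
) -> list[ProteinStructure]:
    """Cohort of helix/coil fixtures (helix cores pLDDT 95, loops/termini 40).

    Each member shares the segment layout of :func:`make_helix_coil_helix`
    but differs in seed (pLDDT jitter and coordinate jitter), emulating a
    small benchmark set of single-domain proteins.
    """
    return [make_helix_coil_helix(seed=base_seed + k) for k in range(n_proteins)]
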