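"""Protein structures at CA resolution: PDB parsing, pLDDT handling, secondary structure.

The central container is :class:`ProteinStructure`, an ordered list of
:class:`Residue` records.  Each residue optionally carries a CA coordinate
(in Å), a pLDDT confidence score on the AlphaFold 0–100 scale, and a
4-state secondary-structure class.  AlphaFold-style models store pLDDT in
the B-factor column; a plain TSV sidecar is supported as an alternative
channel.  Heavy-duty PDB parsing/writing is delegated to biotite.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    LengthMismatch,
    MalformedInput,
    MissingScore,
    RangeError,
    UnknownCode,
)

__all__ = [
    "SecondaryStructure",
    "Residue",
    "ProteinStructure",
    "DSSP_TO_FOUR_STATE",
    "parse_structure",
    "load_plddt_sidecar",
    "assign_ss_from_dssp",
    "assign_ss_geometric",
    "write_structure_pdb",
]


class SecondaryStructure(str, Enum):
    """4-state secondary-structure alphabet used throughout the package."""

    HELIX = "HELIX"
    SHEET = "SHEET"
    TURN = "TURN"
    COIL = "COIL"


#: DSSP 8-state to 4-state collapse.  Dialect: the isolated beta-bridge (B)
#: counts as SHEET and the bend (S) as TURN, so that the moderately-flexible
#: turn class stays populated; everything unassigned is COIL.
DSSP_TO_FOUR_STATE: dict[str, SecondaryStructure] = {
    "H": SecondaryStructure.HELIX,
    "G": SecondaryStructure.HELIX,
    "I": SecondaryStructure.HELIX,
    "E": SecondaryStructure.SHEET,
    "B": SecondaryStructure.SHEET,
    "T": SecondaryStructure.TURN,
    "S": SecondaryStructure.TURN,
    "-": SecondaryStructure.COIL,
    " ": SecondaryStructure.COIL,
    "C": SecondaryStructure.COIL,
}


@dataclass(frozen=True, eq=False)
class Residue:
    """One residue: identity, optional CA coordinate, pLDDT and SS class.

    ``plddt`` is stored on the 0–100 scale exactly as AlphaFold emits it;
    restraint modes that need a fractional strength divide by 100 at the
    point of use.
    """

    chain_id: str
    res_num: int
    icode: str | None = None
    res_name: str = "ALA"
    ca: np.ndarray | None = None
    plddt: float | None = None
    ss: SecondaryStructure | None = None

    def __post_init__(self) -> None:
        if self.plddt is not None and not (0.0 <= self.plddt <= 100.0):
            raise RangeError(
                f"pLDDT {self.plddt} for {self.rid} outside [0, 100]"
            )
        if self.ca is not None:
            ca = np.asarray(self.ca, dtype=float)
            if ca.shape != (3,) or not np.all(np.isfinite(ca)):
                raise RangeError(f"CA coordinate for {self.rid} is not a finite 3-vector")
            object.__setattr__(self, "ca", ca)

    @property
    def rid(self) -> tuple[str, int, str | None]:
        """Residue identity: (chain_id, res_num, icode)."""
        return (self.chain_id, self.res_num, self.icode)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Residue):
            return NotImplemented
        same_ca = (
            (self.ca is None and other.ca is None)
            or (self.ca is not None and other.ca is not None and np.allclose(self.ca, other.ca, atol=0.0))
        )
        return (
            self.rid == other.rid
            and self.res_name == other.res_name
            and same_ca
            and self.plddt == other.plddt
            and self.ss == other.ss
        )


@dataclass
class ProteinStructure:
    """Ordered residues of one structure (possibly multi-chain).

    The 0-based position of a residue in ``residues`` is its *sequence
    index*; sequence-separation rules for restraints operate on this index.
    """

    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str | None]] = set()
        for r in self.residues:
            if r.rid in seen:
                raise MalformedInput(f"duplicate residue identity {r.rid}")
            seen.add(r.rid)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    @property
    def ca_indices(self) -> list[int]:
        """Sequence indices of residues that have a CA coordinate."""
        return [i for i, r in enumerate(self.residues) if r.ca is not None]

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA coordinates; requires every residue to have one."""
        missing = [r.rid for r in self.residues if r.ca is None]
        if missing:
            raise MalformedInput(f"residues without CA coordinates: {missing[:5]}")
        return np.stack([r.ca for r in self.residues])

    @property
    def has_full_plddt(self) -> bool:
        """True when every CA-bearing residue carries a pLDDT score."""
        return all(r.plddt is not None for r in self.residues if r.ca is not None)

    @property
    def has_full_ss(self) -> bool:
        return all(r.ss is not None for r in self.residues if r.ca is not None)

    def with_residues(self, residues: list[Residue]) -> "ProteinStructure":
        return ProteinStructure(residues=residues, source_id=self.source_id)


def parse_structure(pdb_text: str, plddt_source: str = "none") -> ProteinStructure:
    """Parse PDB text into a :class:`ProteinStructure`.

    Parameters
    ----------
    pdb_text
        Contents of a PDB file.  For multi-model files only the first
        MODEL becomes the structure (use :func:`flexrestrain.sampler.read_trajectory_pdb`
        for the ensemble view).
    plddt_source
        ``"bfactor"`` reads the B-factor column as pLDDT (AlphaFold
        convention), ``"sidecar"``/``"none"`` leave pLDDT unset.

    Residues lacking a CA atom are retained with ``ca=None``; they are never
    restrained downstream.  Altloc conflicts take the first location.
    """
    if plddt_source not in ("bfactor", "sidecar", "none"):
        raise ValueError(f"unknown plddt_source {plddt_source!r}")
    if not pdb_text or not pdb_text.strip():
        raise MalformedInput("empty PDB text")
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb.get_structure(model=1, altloc="first", extra_fields=["b_factor"])
    except MalformedInput:
        raise
    except Exception as exc:  # biotite raises assorted errors on garbage
        raise MalformedInput(f"could not parse PDB text: {exc}") from exc
    if atoms.array_length() == 0:
        raise MalformedInput("no parsable ATOM records")

    if plddt_source == "bfactor":
        bf = atoms.b_factor
        bad = bf[(bf < 0.0) | (bf > 100.0)]
        if bad.size:
            raise RangeError(
                f"B-factor value {bad[0]:.2f} outside [0, 100]; not a pLDDT column"
            )

    residues: list[Residue] = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for lo, hi in zip(starts[:-1], starts[1:]):
        sub = atoms[lo:hi]
        if sub.res_name[0] == "HOH":
            continue
        ca_mask = sub.atom_name == "CA"
        ca = sub.coord[ca_mask][0] if ca_mask.any() else None
        plddt = None
        if plddt_source == "bfactor":
            plddt = float(sub.b_factor[ca_mask][0] if ca_mask.any() else sub.b_factor[0])
        icode = sub.ins_code[0].strip() or None
        residues.append(
            Residue(
                chain_id=str(sub.chain_id[0]),
                res_num=int(sub.res_id[0]),
                icode=icode,
                res_name=str(sub.res_name[0]),
                ca=ca,
                plddt=plddt,
            )
        )
    if not residues:
        raise MalformedInput("no residues found in PDB text")
    return ProteinStructure(residues=residues)


def write_structure_pdb(structure: ProteinStructure, plddt_as_bfactor: bool = True) -> str:
    """Serialize the CA trace as PDB text (one CA ATOM record per residue).

    When ``plddt_as_bfactor`` is set, the pLDDT score is written into the
    B-factor column (two decimals, the AlphaFold convention); residues
    without a score get 0.00.  Coordinates round-trip at three decimals,
    the PDB fixed-width contract.
    """
    idx = structure.ca_indices
    n = len(idx)
    if n == 0:
        raise MalformedInput("structure has no CA coordinates to write")
    atoms = struc.AtomArray(n)
    atoms.coord = np.stack([structure[i].ca for i in idx])
    atoms.chain_id = np.array([structure[i].chain_id for i in idx])
    atoms.res_id = np.array([structure[i].res_num for i in idx])
    atoms.ins_code = np.array([structure[i].icode or "" for i in idx])
    atoms.res_name = np.array([structure[i].res_name for i in idx])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    bf = np.zeros(n)
    if plddt_as_bfactor:
        bf = np.array([structure[i].plddt or 0.0 for i in idx])
    atoms.set_annotation("b_factor", bf)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    return "\n".join(pdb.lines) + "\n"


def load_plddt_sidecar(structure: ProteinStructure, tsv_text: str) -> ProteinStructure:
    """Fill pLDDT from a 3-column TSV sidecar: ``chain<TAB>res_num<TAB>plddt``.

    Comment lines start with ``#``; a single header line is tolerated.
    Rows addressing residues absent from the structure are reported as
    warnings and otherwise ignored.
    """
    scores: dict[tuple[str, int], float] = {}
    first_data_line = True
    for lineno, raw in enumerate(tsv_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise MalformedInput(f"sidecar line {lineno}: expected 3 columns, got {len(parts)}")
        chain, num_s, score_s = parts[0], parts[1], parts[2]
        try:
            res_num = int(num_s)
            score = float(score_s)
        except ValueError:
            if first_data_line:  # optional header row
                first_data_line = False
                continue
            raise MalformedInput(f"sidecar line {lineno}: non-numeric fields {num_s!r}/{score_s!r}")
        first_data_line = False
        if not (0.0 <= score <= 100.0):
            raise RangeError(f"sidecar line {lineno}: pLDDT {score} outside [0, 100]")
        scores[(chain, res_num)] = score

    known = {(r.chain_id, r.res_num) for r in structure}
    for key in scores:
        if key not in known:
            warnings.warn(f"sidecar row for absent residue {key[0]}/{key[1]} ignored")
    residues = [
        replace(r, plddt=scores.get((r.chain_id, r.res_num), r.plddt))
        for r in structure
    ]
    return structure.with_residues(residues)


def _extract_dssp_string(dssp8: str) -> str:
    """Accept either a bare 8-state string or a full dssp output file."""
    if "#  RESIDUE" in dssp8:
        out = []
        seen_header = False
        for line in dssp8.splitlines():
            if "#  RESIDUE" in line:
                seen_header = True
                continue
            if not seen_header or len(line) < 17:
                continue
            if line[13] == "!":  # chain break marker
                continue
            out.append(line[16] if line[16] != " " else "-")
        return "".join(out)
    return "".join(dssp8.split())


def assign_ss_from_dssp(structure: ProteinStructure, dssp8: str) -> ProteinStructure:
    """Assign 4-state classes from an 8-state DSSP string (or dssp file text).

    The string covers the CA-bearing residues in structure order; its length
    must match their count.  Mapping: H/G/I→HELIX, E/B→SHEET, T/S→TURN,
    everything else in the DSSP alphabet→COIL.  Idempotent and total on
    valid input.
    """
    ss_string = _extract_dssp_string(dssp8)
    idx = structure.ca_indices
    if len(ss_string) != len(idx):
        raise LengthMismatch(
            f"DSSP string length {len(ss_string)} != {len(idx)} CA residues"
        )
    residues = list(structure.residues)
    for pos, ch in zip(idx, ss_string):
        if ch not in DSSP_TO_FOUR_STATE:
            raise UnknownCode(f"unknown DSSP code {ch!r}")
        residues[pos] = replace(residues[pos], ss=DSSP_TO_FOUR_STATE[ch])
    return structure.with_residues(residues)


# CA-geometry windows: an ideal alpha helix has d(i,i+3) ~ 5.1 A and
# d(i,i+4) ~ 6.2 A; a fully extended 3.8 A-step trace has ~11.4 / ~15.2 A.
_HELIX_D13 = (4.2, 6.2)
_HELIX_D14 = (5.0, 7.2)
_STRAND_D13_MIN = 9.5
_STRAND_D14_MIN = 12.5


def assign_ss_geometric(structure: ProteinStructure) -> ProteinStructure:
    """Fixture-grade secondary-structure assignment from CA geometry alone.

    Classifies 5-residue windows by their i→i+3 / i→i+4 CA distance
    signature (helix-like vs highly extended), then collapses segments
    shorter than 3 residues to COIL.  Chains with fewer than 5 CA atoms are
    all-COIL.  Deterministic; meant as a fallback when no DSSP output is
    available, not as a DSSP replacement.
    """
    residues = list(structure.residues)
    by_chain: dict[str, list[int]] = {}
    for i in structure.ca_indices:
        by_chain.setdefault(residues[i].chain_id, []).append(i)

    for chain_idx in by_chain.values():
        m = len(chain_idx)
        labels = [SecondaryStructure.COIL] * m
        if m >= 5:
            xyz = np.stack([residues[i].ca for i in chain_idx])
            d13 = np.linalg.norm(xyz[3:] - xyz[:-3], axis=1)
            d14 = np.linalg.norm(xyz[4:] - xyz[:-4], axis=1)
            for i in range(m - 4):
                if d13[i] >= _STRAND_D13_MIN and d14[i] >= _STRAND_D14_MIN:
                    for k in range(i, i + 5):
                        labels[k] = SecondaryStructure.SHEET
            for i in range(m - 4):
                if (
                    _HELIX_D13[0] <= d13[i] <= _HELIX_D13[1]
                    and _HELIX_D14[0] <= d14[i] <= _HELIX_D14[1]
                ):
                    for k in range(i, i + 5):
                        labels[k] = SecondaryStructure.HELIX
            labels = _collapse_short_segments(labels, min_len=3)
        for i, lab in zip(chain_idx, labels):
            residues[i] = replace(residues[i], ss=lab)
    return structure.with_residues(residues)


def _collapse_short_segments(
    labels: list[SecondaryStructure], min_len: int
) -> list[SecondaryStructure]:
    out = list(labels)
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] != SecondaryStructure.COIL and (j - i) < min_len:
            for k in range(i, j):
                out[k] = SecondaryStructure.COIL
        i = j
    return out
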