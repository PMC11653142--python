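"""Distance-restraint generation for CA-level flexibility simulation.

Restraints penalize a residue pair's CA–CA distance for deviating from its
value in the input structure.  The penalty is flat-bottomed: zero within
``flat_halfwidth`` (default 1 Å) of the ideal distance, then growing with
separate slopes for too-short (``min_force``) and too-long (``max_force``)
deviations.  Nine modes decide which pairs are restrained and how strongly:

* legacy secondary-structure modes — SS2 (both residues in regular SS),
  SS1 (at least one), ALL (every qualifying pair);
* pLDDT modes — MIN / MAX / MEAN use the pair's pLDDT statistic divided by
  100 as the weight (pairs below a 0.5 floor are dropped); PLDDT1 / PLDDT2
  gate full-strength restraints on one / both scores exceeding 50;
* CATEGORY — each residue gets a flexibility category 0 (fully flexible)
  to 3 (rigid) from its secondary structure refined by pLDDT confidence,
  and a 4×4 matrix maps the category pair to a weight in {0.0, 0.5, 1.0}.

Defaults are the optimized protocol: maximum distance 11.5 Å, sequence gap
3, min_force 3.5, max_force 0.5, seed 7503.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import MalformedInput, MissingScore, MissingSS, RangeError
from .structure import ProteinStructure, SecondaryStructure

__all__ = [
    "RestraintMode",
    "CategoryRules",
    "StrengthMatrix",
    "RestraintConfig",
    "Restraint",
    "RestraintSet",
    "assign_category",
    "pair_strength",
    "generate_restraints",
    "subsample_restraints",
    "restraint_energy",
    "total_restraint_energy",
    "write_restraints",
    "read_restraints",
]


class RestraintMode(str, Enum):
    SS2 = "SS2"
    SS1 = "SS1"
    ALL = "ALL"
    MIN = "MIN"
    MAX = "MAX"
    MEAN = "MEAN"
    PLDDT1 = "PLDDT1"
    PLDDT2 = "PLDDT2"
    CATEGORY = "CATEGORY"


_PLDDT_MODES = {
    RestraintMode.MIN,
    RestraintMode.MAX,
    RestraintMode.MEAN,
    RestraintMode.PLDDT1,
    RestraintMode.PLDDT2,
    RestraintMode.CATEGORY,
}
_SS_MODES = {RestraintMode.SS1, RestraintMode.SS2, RestraintMode.CATEGORY}
_REGULAR_SS = {SecondaryStructure.HELIX, SecondaryStructure.SHEET}


@dataclass(frozen=True)
class CategoryRules:
    """How a residue's flexibility category (0 flexible … 3 rigid) is assigned.

    The secondary structure sets a base category — coil 0, turn 1,
    helix/sheet 2 — and the pLDDT score bumps it: +1 at or above
    ``high_conf_cutoff``, −1 below ``low_conf_cutoff``, then clamped to
    [0, 3].  Monotone in pLDDT for fixed secondary structure.
    """

    high_conf_cutoff: float = 90.0
    low_conf_cutoff: float = 50.0
    base_category_by_ss: Mapping[SecondaryStructure, int] = field(
        default_factory=lambda: {
            SecondaryStructure.COIL: 0,
            SecondaryStructure.TURN: 1,
            SecondaryStructure.HELIX: 2,
            SecondaryStructure.SHEET: 2,
        }
    )

    def __post_init__(self) -> None:
        if not self.low_conf_cutoff < self.high_conf_cutoff:
            raise RangeError("low_conf_cutoff must be below high_conf_cutoff")
        if any(v not in (0, 1, 2) for v in self.base_category_by_ss.values()):
            raise RangeError("base categories must be in {0, 1, 2}")


def _default_strength_table() -> np.ndarray:
    # weight 0.0 when either residue is fully flexible, 1.0 when both are
    # at least slightly flexible (category >= 2), 0.5 otherwise
    t = np.empty((4, 4))
    for a in range(4):
        for b in range(4):
            m = min(a, b)
            t[a, b] = 0.0 if m == 0 else (1.0 if m >= 2 else 0.5)
    return t


@dataclass(frozen=True)
class StrengthMatrix:
    """Symmetric 4×4 table mapping a category pair to a restraint weight."""

    table: np.ndarray = field(default_factory=_default_strength_table)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (4, 4):
            raise RangeError("strength matrix must be 4x4")
        if not np.allclose(t, t.T):
            raise RangeError("strength matrix must be symmetric")
        if t.min() < 0.0 or t.max() > 1.0:
            raise RangeError("strength-matrix entries must lie in [0, 1]")
        object.__setattr__(self, "table", t)

    def __getitem__(self, key: tuple[int, int]) -> float:
        return float(self.table[key])


@dataclass(frozen=True)
class RestraintConfig:
    """All tunables of restraint generation, defaulting to the optimized protocol."""

    mode: RestraintMode = RestraintMode.CATEGORY
    max_distance: float = 11.5  # Å; candidate pairs must be closer than this
    min_seq_gap: int = 3  # residues; |j - i| must be at least this
    min_force: float = 3.5  # slope for too-short distances, energy/Å
    max_force: float = 0.5  # slope for too-long distances, energy/Å
    flat_halfwidth: float = 1.0  # Å; no penalty within this band of d0
    plddt_strength_floor: float = 0.5  # MIN/MAX/MEAN pairs below this are dropped
    plddt_pair_cutoff: float = 50.0  # PLDDT1/PLDDT2 scores must exceed this
    drop_fraction: float = 0.0  # random restraint subsampling
    seed: int = 7503
    penalty: str = "linear"  # or "quadratic"
    mean_floor: bool = True  # apply the strength floor to MEAN mode too
    include_interchain: bool = False
    category_rules: CategoryRules = field(default_factory=CategoryRules)
    strength_matrix: StrengthMatrix = field(default_factory=StrengthMatrix)

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise RangeError("max_distance must be positive")
        if self.min_seq_gap < 1:
            raise RangeError("min_seq_gap must be >= 1")
        if self.min_force < 0 or self.max_force < 0:
            raise RangeError("forces must be non-negative")
        if self.flat_halfwidth < 0:
            raise RangeError("flat_halfwidth must be non-negative")
        if not (0.0 <= self.drop_fraction <= 1.0):
            raise RangeError("drop_fraction must lie in [0, 1]")
        if self.penalty not in ("linear", "quadratic"):
            raise RangeError(f"unknown penalty shape {self.penalty!r}")
        if isinstance(self.mode, str) and not isinstance(self.mode, RestraintMode):
            object.__setattr__(self, "mode", RestraintMode(self.mode.upper()))

    _SCALAR_FIELDS = (
        "mode", "max_distance", "min_seq_gap", "min_force", "max_force",
        "flat_halfwidth", "plddt_strength_floor", "plddt_pair_cutoff",
        "drop_fraction", "seed", "penalty", "mean_floor", "include_interchain",
    )

    def scalar_items(self) -> list[tuple[str, str]]:
        out = []
        for name in self._SCALAR_FIELDS:
            v = getattr(self, name)
            out.append((name, v.value if isinstance(v, RestraintMode) else repr(v) if isinstance(v, bool) else str(v)))
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RestraintConfig":
        """Build a config from a flat mapping (YAML/JSON), coercing field types."""
        kwargs: dict[str, object] = {}
        for key, value in mapping.items():
            if key == "mode":
                kwargs["mode"] = RestraintMode(str(value).upper())
            elif key in ("min_seq_gap", "seed"):
                kwargs[key] = int(value)  # type: ignore[arg-type]
            elif key in ("mean_floor", "include_interchain"):
                kwargs[key] = bool(value)
            elif key == "penalty":
                kwargs[key] = str(value)
            elif key == "category_rules":
                sub = dict(value)  # type: ignore[arg-type]
                base = sub.pop("base_category_by_ss", None)
                if base is not None:
                    sub["base_category_by_ss"] = {
                        SecondaryStructure[k.upper()]: int(v) for k, v in base.items()
                    }
                kwargs[key] = CategoryRules(**sub)
            elif key == "strength_matrix":
                kwargs[key] = StrengthMatrix(np.asarray(value, dtype=float))
            elif key in {f.strip() for f in cls._SCALAR_FIELDS}:
                kwargs[key] = float(value)  # type: ignore[arg-type]
            else:
                raise RangeError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class Restraint:
    """One residue-pair restraint.

    ``i``/``j`` are 0-based sequence indices (``i < j``) and are ``None``
    only for sets read back from text without a structure to resolve them.
    ``slope_min``/``slope_max`` already include the pair weight.
    """

    i: int | None
    j: int | None
    id_i: tuple[str, int, str | None]
    id_j: tuple[str, int, str | None]
    d0: float
    weight: float
    slope_min: float
    slope_max: float

    def __post_init__(self) -> None:
        if self.i is not None and self.j is not None and not self.i < self.j:
            raise RangeError(f"restraint indices must satisfy i < j, got {self.i}, {self.j}")
        if not (0.0 <= self.weight <= 1.0):
            raise RangeError(f"restraint weight {self.weight} outside [0, 1]")
        if self.d0 <= 0:
            raise RangeError("ideal distance must be positive")


@dataclass
class RestraintSet:
    """Canonically (i, j)-ordered restraints plus the generating config."""

    restraints: list[Restraint]
    config: RestraintConfig | None = None

    def __post_init__(self) -> None:
        pairs = [(r.i, r.j) for r in self.restraints if r.i is not None]
        if len(pairs) != len(set(pairs)):
            raise MalformedInput("duplicate restraint pairs")

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self) -> Iterator[Restraint]:
        return iter(self.restraints)

    def pair_set(self) -> set[tuple[int, int]]:
        return {(r.i, r.j) for r in self.restraints}


def assign_category(
    ss: SecondaryStructure,
    plddt: float | None,
    rules: CategoryRules | None = None,
) -> int:
    """Flexibility category 0 (fully flexible) … 3 (rigid) for one residue."""
    if plddt is None:
        raise MissingScore("category assignment requires a pLDDT score")
    if not (0.0 <= plddt <= 100.0):
        raise RangeError(f"pLDDT {plddt} outside [0, 100]")
    rules = rules or CategoryRules()
    base = rules.base_category_by_ss[ss]
    if plddt >= rules.high_conf_cutoff:
        bump = 1
    elif plddt < rules.low_conf_cutoff:
        bump = -1
    else:
        bump = 0
    return int(np.clip(base + bump, 0, 3))


def pair_strength(
    cat_i: int, cat_j: int, matrix: StrengthMatrix | None = None
) -> float:
    """Restraint weight for a pair of flexibility categories (symmetric lookup)."""
    if not (0 <= cat_i <= 3 and 0 <= cat_j <= 3):
        raise RangeError("categories must lie in 0..3")
    matrix = matrix or StrengthMatrix()
    return matrix[cat_i, cat_j]


def _pair_weight(
    mode: RestraintMode,
    ss_i: SecondaryStructure | None,
    ss_j: SecondaryStructure | None,
    p_i: float | None,
    p_j: float | None,
    config: RestraintConfig,
) -> float | None:
    """Mode rule for one candidate pair; None means no restraint."""
    if mode is RestraintMode.ALL:
        return 1.0
    if mode is RestraintMode.SS2:
        return 1.0 if ss_i in _REGULAR_SS and ss_j in _REGULAR_SS else None
    if mode is RestraintMode.SS1:
        return 1.0 if ss_i in _REGULAR_SS or ss_j in _REGULAR_SS else None
    if mode is RestraintMode.MIN:
        w = min(p_i, p_j) / 100.0
        return w if w >= config.plddt_strength_floor else None
    if mode is RestraintMode.MAX:
        w = max(p_i, p_j) / 100.0
        return w if w >= config.plddt_strength_floor else None
    if mode is RestraintMode.MEAN:
        w = (p_i + p_j) / 200.0
        if config.mean_floor and w < config.plddt_strength_floor:
            return None
        return w
    if mode is RestraintMode.PLDDT1:
        return 1.0 if max(p_i, p_j) > config.plddt_pair_cutoff else None
    if mode is RestraintMode.PLDDT2:
        return 1.0 if min(p_i, p_j) > config.plddt_pair_cutoff else None
    if mode is RestraintMode.CATEGORY:
        cat_i = assign_category(ss_i, p_i, config.category_rules)
        cat_j = assign_category(ss_j, p_j, config.category_rules)
        w = pair_strength(cat_i, cat_j, config.strength_matrix)
        return w if w > 0.0 else None
    raise ValueError(f"unhandled mode {mode}")


def generate_restraints(
    structure: ProteinStructure, config: RestraintConfig | None = None
) -> RestraintSet:
    """Generate the restraint set for ``structure`` under ``config``.

    Candidate pairs are all CA-bearing residue pairs within one chain whose
    sequence-index separation is at least ``min_seq_gap`` and whose CA–CA
    distance does not exceed ``max_distance`` (inter-chain pairs only if
    enabled, with the gap rule applied intra-chain only).  Each candidate
    gets a weight from the mode rule; the ideal distance is the input
    distance and the effective slopes are ``weight × min_force`` /
    ``weight × max_force``.  If ``drop_fraction > 0`` the set is randomly
    subsampled with the config seed.

    Raises :class:`MissingScore` / :class:`MissingSS` when the mode needs
    annotations the structure lacks.
    """
    config = config or RestraintConfig()
    mode = config.mode
    idx = structure.ca_indices
    if mode in _PLDDT_MODES:
        if any(structure[i].plddt is None for i in idx):
            raise MissingScore(f"mode {mode.value} requires pLDDT on every CA residue")
    if mode in _SS_MODES:
        if any(structure[i].ss is None for i in idx):
            raise MissingSS(f"mode {mode.value} requires secondary structure on every CA residue")

    if not idx:
        return RestraintSet([], config)
    coords = np.stack([structure[i].ca for i in idx])
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)

    restraints: list[Restraint] = []
    for a in range(len(idx)):
        i = idx[a]
        ri = structure[i]
        for b in range(a + 1, len(idx)):
            j = idx[b]
            rj = structure[j]
            same_chain = ri.chain_id == rj.chain_id
            if same_chain:
                if j - i < config.min_seq_gap:
                    continue
            elif not config.include_interchain:
                continue
            d = float(dmat[a, b])
            if d > config.max_distance:
                continue
            w = _pair_weight(mode, ri.ss, rj.ss, ri.plddt, rj.plddt, config)
            if w is None:
                continue
            restraints.append(
                Restraint(
                    i=i,
                    j=j,
                    id_i=ri.rid,
                    id_j=rj.rid,
                    d0=d,
                    weight=w,
                    slope_min=w * config.min_force,
                    slope_max=w * config.max_force,
                )
            )
    restraints.sort(key=lambda r: (r.i, r.j))
    rset = RestraintSet(restraints, config)
    if config.drop_fraction > 0.0:
        rset = subsample_restraints(rset, config.drop_fraction, config.seed)
    return rset


def subsample_restraints(
    rset: RestraintSet, drop_fraction: float, seed: int
) -> RestraintSet:
    """Remove round(drop_fraction × N) restraints uniformly at random.

    Deterministic for a fixed seed; the survivors keep their order.
    """
    if not (0.0 <= drop_fraction <= 1.0):
        raise RangeError("drop_fraction must lie in [0, 1]")
    n = len(rset)
    n_drop = int(round(drop_fraction * n))
    if n_drop == 0:
        return RestraintSet(list(rset.restraints), rset.config)
    rng = np.random.default_rng(seed)
    dropped = set(rng.choice(n, size=n_drop, replace=False).tolist())
    kept = [r for k, r in enumerate(rset.restraints) if k not in dropped]
    return RestraintSet(kept, rset.config)


def restraint_energy(
    d: float, r: Restraint, flat_halfwidth: float = 1.0, penalty: str = "linear"
) -> float:
    """Flat-bottom penalty for one restraint at distance ``d``.

    Zero within ``flat_halfwidth`` of the ideal distance; outside, the
    excess deviation is penalized with slope ``slope_min`` (too short) or
    ``slope_max`` (too long).  Piecewise linear by default; ``penalty=
    "quadratic"`` squares the excess instead.  Continuous and non-negative
    either way.
    """
    dev = d - r.d0
    if dev > flat_halfwidth:
        excess = dev - flat_halfwidth
        slope = r.slope_max
    elif dev < -flat_halfwidth:
        excess = -dev - flat_halfwidth
        slope = r.slope_min
    else:
        return 0.0
    return slope * (excess * excess if penalty == "quadratic" else excess)


def total_restraint_energy(
    coords: np.ndarray,
    rset: RestraintSet,
    flat_halfwidth: float | None = None,
    penalty: str | None = None,
) -> float:
    """Sum of :func:`restraint_energy` over a set, on one conformation.

    ``coords`` is an (n, 3) array indexed by sequence index.  Defaults for
    the flat-bottom width and penalty shape come from the set's config.
    Evaluating the input structure's own coordinates yields exactly zero.
    """
    cfg = rset.config or RestraintConfig()
    w = cfg.flat_halfwidth if flat_halfwidth is None else flat_halfwidth
    shape = cfg.penalty if penalty is None else penalty
    coords = np.asarray(coords, dtype=float)
    total = 0.0
    for r in rset:
        if r.i is None or r.j is None or r.j >= len(coords):
            raise IndexError(f"restraint {r.id_i}-{r.id_j} lacks resolvable coordinates")
        d = float(np.linalg.norm(coords[r.i] - coords[r.j]))
        total += restraint_energy(d, r, w, shape)
    return total


def _format_rid(rid: tuple[str, int, str | None]) -> str:
    chain, num, icode = rid
    return f"{chain}:{num}{icode or ''}"


_RID_RE = re.compile(r"^(?P<chain>[^:]+):(?P<num>-?\d+)(?P<icode>[A-Za-z]?)$")


def _parse_rid(token: str, lineno: int) -> tuple[str, int, str | None]:
    m = _RID_RE.match(token)
    if not m:
        raise MalformedInput(f"line {lineno}: bad residue identifier {token!r}")
    return (m["chain"], int(m["num"]), m["icode"] or None)


def write_restraints(rset: RestraintSet) -> str:
    """Serialize a restraint set to text.

    A ``#``-prefixed header carries the scalar config fields; each body
    line is ``<chain>:<res_num> <chain>:<res_num> <d0:.3f> <weight:.3f>``.
    Byte-identical for identical inputs.
    """
    cfg = rset.config or RestraintConfig()
    lines = ["# flexrestrain restraint set"]
    for key, val in cfg.scalar_items():
        lines.append(f"# {key}={val}")
    lines.append(f"# n_restraints={len(rset)}")
    for r in rset:
        lines.append(
            f"{_format_rid(r.id_i)} {_format_rid(r.id_j)} {r.d0:.3f} {r.weight:.3f}"
        )
    return "\n".join(lines) + "\n"


def read_restraints(
    text: str, structure: ProteinStructure | None = None
) -> RestraintSet:
    """Parse restraint text written by :func:`write_restraints`.

    Residue identities, ideal distances and weights round-trip (d0/weight
    at 3 decimals).  Sequence indices are resolved against ``structure``
    when one is supplied, otherwise left as ``None``.  Slopes are rebuilt
    from the header's forces.
    """
    header: dict[str, str] = {}
    body: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                header[key.strip()] = val.strip()
            continue
        body.append((lineno, line))

    cfg_kwargs: dict[str, object] = {}
    _coerce = {
        "mode": str, "max_distance": float, "min_seq_gap": int, "min_force": float,
        "max_force": float, "flat_halfwidth": float, "plddt_strength_floor": float,
        "plddt_pair_cutoff": float, "drop_fraction": float, "seed": int,
        "penalty": str, "mean_floor": lambda s: s == "True",
        "include_interchain": lambda s: s == "True",
    }
    for key, conv in _coerce.items():
        if key in header:
            cfg_kwargs[key] = conv(header[key])
    config = RestraintConfig.from_mapping(cfg_kwargs) if cfg_kwargs else RestraintConfig()

    rid_to_index = None
    if structure is not None:
        rid_to_index = {r.rid: i for i, r in enumerate(structure)}

    restraints: list[Restraint] = []
    for lineno, line in body:
        parts = line.split()
        if len(parts) != 4:
            raise MalformedInput(f"line {lineno}: expected 4 fields, got {len(parts)}")
        id_i = _parse_rid(parts[0], lineno)
        id_j = _parse_rid(parts[1], lineno)
        try:
            d0 = float(parts[2])
            weight = float(parts[3])
        except ValueError:
            raise MalformedInput(f"line {lineno}: non-numeric distance/weight in {line!r}")
        i = j = None
        if rid_to_index is not None:
            try:
                i, j = rid_to_index[id_i], rid_to_index[id_j]
            except KeyError as exc:
                raise MalformedInput(f"line {lineno}: residue {exc.args[0]} not in structure")
            if i > j:
                i, j = j, i
                id_i, id_j = id_j, id_i
        restraints.append(
            Restraint(
                i=i, j=j, id_i=id_i, id_j=id_j, d0=d0, weight=weight,
                slope_min=weight * config.min_force,
                slope_max=weight * config.max_force,
            )
        )
    return RestraintSet(restraints, config)
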