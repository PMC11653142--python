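# Methods

`flexrestrain` implements the restraint-generation layer of a CABS-flex-style
protein flexibility protocol — the part that decides *which* residue pairs of
an input structure are distance-restrained during coarse-grained sampling and
*how strongly* — together with a deliberately simple off-lattice CA Monte
Carlo sampler to exercise those restraints end-to-end, and the evaluation
machinery (superposition, RMSF, best-of-replicas correlation) used to score
flexibility predictions. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The restraint model

A restraint on residue pair *(i, j)* penalizes the CA–CA distance *d* for
deviating from its value *d₀* in the input structure, with a flat bottom:

```
E(d) = 0                                  |d − d₀| ≤ w
E(d) = s_min · (d₀ − w − d)               d < d₀ − w
E(d) = s_max · (d − d₀ − w)               d > d₀ + w
```

with flat half-width *w* = 1 Å. The two slopes are asymmetric:
`s_min = weight × min_force` punishes compression and
`s_max = weight × max_force` punishes stretching, with the optimized defaults
`min_force = 3.5`, `max_force = 0.5` (energy per Å, in kT units of the
sampler). The energy is continuous, non-negative, and zero on the input
structure itself, so restraints only discourage non-ideal moves — they never
pull the model toward a specific conformation.

*Penalty shape.* The published description fixes the flat bottom and the two
strength parameters but not the functional form of the arms. We use
piecewise-linear arms — the simplest shape consistent with one strength
parameter per side — and expose `penalty="quadratic"` as an alternative.

*Strength composition.* Per-pair mode weights (0–1) multiply **both** global
slopes. This keeps the per-pair knob (restraint weight) and the global knobs
(min/max force) independent and reduces exactly to the legacy full-strength
behavior at weight 1.

## Candidate pairs and the nine modes

Candidate pairs are all CA-bearing residue pairs within one chain with
sequence-index separation ≥ `min_seq_gap` (default 3, inclusive: a pair
qualifies when `j − i ≥ gap`) and input CA–CA distance ≤ `max_distance`
(default 11.5 Å, the value at which benchmark correlation was found to
plateau). Inter-chain pairs are excluded by default; a flag enables them,
with the gap rule applied intra-chain only.

Weights per mode:

| mode | rule |
|---|---|
| SS2 | 1.0 iff both residues are helix or sheet |
| SS1 | 1.0 iff at least one residue is helix or sheet |
| ALL | 1.0 for every candidate pair |
| MIN | min(pLDDT_i, pLDDT_j)/100; pair dropped if < 0.5 |
| MAX | max(pLDDT_i, pLDDT_j)/100; same floor |
| MEAN | mean/100; same floor (configurable off, see below) |
| PLDDT1 | 1.0 iff at least one pLDDT > 50 |
| PLDDT2 | 1.0 iff both pLDDT > 50 |
| CATEGORY | pair-strength matrix over flexibility categories |

Floor and cutoff comparisons are deliberate: the strength floor drops a pair
only when its weight is strictly *below* 0.5 (so 0.50 itself survives), and
the PLDDT1/PLDDT2 cutoffs are strictly *greater than* 50. The MEAN floor is
applied by default for consistency with MIN/MAX, but the published rule text
is silent for MEAN, so `mean_floor=False` restores the unfloored variant.

## The Category mode

Each residue receives a flexibility category 0 (fully flexible) … 3 (rigid):
secondary structure sets a base — coil 0, turn 1, helix/sheet 2 — and the
pLDDT score bumps it by +1 at or above `high_conf_cutoff` (90), by −1 below
`low_conf_cutoff` (50), clamped to [0, 3]. The assignment is monotone in
pLDDT for fixed secondary structure. A symmetric 4×4 matrix then maps the
category pair to a weight; the default is

```
weight = 0.0   if min(cat_i, cat_j) == 0   (either fully flexible)
weight = 1.0   if min(cat_i, cat_j) >= 2   (both at most slightly flexible)
weight = 0.5   otherwise
```

The exact published cutoffs and matrix cells are figure content not given
numerically in the text; the defaults above reproduce the stated monotone
structure (higher confidence ⇒ lower flexibility; strengths limited to
{0.0, 0.5, 1.0}) and both the cutoffs and the full matrix are overridable
from a config file, so reference values can be dropped in verbatim.

## Structure input

PDB parsing is delegated to biotite. Residues lacking a CA atom are retained
in the container but never restrained and never counted in RMSF profiles.
pLDDT arrives either from the B-factor column (AlphaFold model convention,
validated to [0, 100]) or from a 3-column TSV sidecar. Secondary structure
comes from a DSSP 8-state string (or full dssp output file), collapsed
H/G/I→helix, E/B→sheet, T/S→turn, else coil; the B→sheet and S→turn choices
keep the moderately-flexible turn class populated. A fixture-grade geometric
fallback classifies 5-residue windows by their i→i+3 / i→i+4 CA distance
signature (ideal helix ≈ 5.1/6.2 Å; highly extended ≈ 11.4/15.2 Å) so tests
and casual use need no external DSSP run — it is not a DSSP replacement and
labels any extended strand-like run as sheet.

## The stand-in sampler

The sampler is **not** the CABS lattice engine and makes no force-field
claims. It exists so restraint schemes can be exercised end-to-end at desk
scale: beads are CAs; the energy is a harmonic virtual-bond term
(`bond_k = 20 /Å²` about 3.8 Å), a soft excluded-volume term (`ev_k = 5 /Å²`
inside 3.5 Å), and the total restraint energy; moves displace one bead by an
isotropic Gaussian (σ = 0.35 Å) and are accepted by Metropolis at fixed kT.
Snapshots are taken every `snapshot_every` *attempted* moves so frame
indexing never depends on acceptance history; the first frame is always the
input conformation; a fixed seed makes runs byte-reproducible (the package
default seed is 7503 everywhere).

*Temperature.* Energies are expressed in kT units and the default
temperature is kT = 0.3. With the restraint slopes fixed at 3.5/0.5 per Å, a
unit temperature leaves thermal noise comparable to the restraint penalties
in this simple off-lattice model, washing out the rigid-core/flexible-loop
contrast the restraints encode; at kT = 0.3 restrained cores are clearly
stiffer than unrestrained segments while acceptance stays near 0.1–0.3 on
the bundled fixtures. This is a property of the stand-in sampler, not a
statement about any published engine.

*Rigidification limit.* Because the flat bottom leaves every pair distance
free within ±1 Å, infinitely strong forces do not freeze the system: a
densely restrained compact fold equilibrates at a mean RMSF of ≈ 0.45–0.50 Å
— the slack floor set by the flat-bottom width — and force magnitude stops
mattering beyond roughly 10. The rigidification checks therefore assert the
*mean* RMSF over restrained residues on a dense fixture (the serpentine
fold, ~23 restraints per residue) at the suite's standard run length of
40k attempted moves; individual weakly-oriented residues can sit at
0.6–0.7 Å within their slack and no force value can push them below 0.5 Å.

*Problem sizes.* Tests and the acceptance script run ~30-residue fixtures:
40k attempted moves for directional and limit checks, and the library
default of 200k moves (snapshots every 500) for the cohort comparison.
These sizes are the package's desk-scale choice; the restraint layer itself
is size-agnostic.

## Evaluation

RMSF is computed per residue as the root-mean-square displacement from the
residue's mean position over frames, after optional rigid-body superposition:
frames are first aligned to the initial frame (the raw ensemble mean is
meaningless when frames carry arbitrary rigid motion), then re-aligned to
the resulting mean structure in one refinement pass. Superposition is the
Kabsch least-squares fit via `scipy.spatial.transform.Rotation.align_vectors`;
rotations are always proper, so mirror images keep a nonzero residual. All
evaluation is CA-based.

Predicted profiles are scored against one or more reference replica profiles
with the Pearson product-moment correlation, reporting the **best** (highest)
r across replicas — the convention used when benchmarking against
multi-replica MD reference sets. Spearman is available behind a flag. Method
comparisons over a cohort use a two-sided paired t-test
(`scipy.stats.ttest_rel`); degenerate inputs follow a documented convention
(identical lists → statistic 0, p = 1; constant nonzero difference →
±inf, p = 0, treating the effect as overwhelming). p-values are reported,
not used as gates.

## Synthetic fixtures: what they emulate and what they do not

`make_toy_structure` builds CA traces from segment specs: ideal α-helix
geometry (1.5 Å rise, 2.3 Å radius, 100° twist per residue), extended 3.8 Å
steps for sheet/coil, smooth 90° arcs for turns, chained so consecutive CA
distances stay in [3.6, 4.0] Å. A segment's trace shape can be decoupled
from its label (`geometry=`) — used to lay a flexible coil loop on a U-turn.
The benchmark fixture is a 30-residue helix hairpin: two antiparallel
9-residue helices (pLDDT 95) joined by a 4-residue low-confidence loop, with
4-residue low-confidence coil termini. The hairpin is deliberately compact:
antiparallel packing puts many cross-helix pairs inside the 11.5 Å cutoff,
so Category-mode restraints knit the two helices into one rigid core — a
collinear helix–coil–helix chain would let the helices hinge freely and
carry no core-rigidity signal at all.

`make_planted_trajectory` adds i.i.d. isotropic Gaussian noise with per-axis
s.d. σᵢ/√3 to the reference, so the expected RMSF of residue *i* is exactly
σᵢ (closed-form oracle for the RMSF estimator); optional per-frame random
rigid motion exercises superposition. The default planted map is σ = 1.2 Å
for coil, 0.7 Å for turn, 0.3 Å for helix/sheet — flexible low-confidence
loops and termini, rigid high-confidence cores — and is overridable to
construct counter-examples (e.g. a rigid low-pLDDT helix).

These fixtures are statistical stand-ins, not physics: planted noise is
uncorrelated between residues and frames, real loops move collectively; the
pLDDT profiles are piecewise-constant with Gaussian jitter, real profiles
ramp smoothly; and the sampler's ensembles are those of the toy energy
above, not of any calibrated force field. Passing tests therefore certify
the correctness and the qualitative behavior of the restraint machinery —
restraints generated by the stated rules, energies obeying the stated laws,
restrained cores rigid relative to unrestrained segments, Category-mode
runs correlating with planted flexibility far better than unrestrained runs
— not quantitative accuracy on real proteins against real MD.

## Numerical choices and degenerate inputs

- Restraints are canonically ordered by (i, j); subsampling removes exactly
  `round(drop_fraction × N)` members uniformly at random with a seeded
  generator, survivors keeping their order.
- Restraint files are plain text, 3 decimals for distance and weight; the
  header carries the scalar config, so round-trips restore identities
  exactly and numerics to 1e-3. Identical inputs yield byte-identical files.
- Superposition raises on coincident/collinear references (rank < 2 after
  centering) instead of returning an arbitrary rotation.
- Correlations raise on constant profiles and length mismatches rather than
  returning NaN.
- The sampler tracks energy incrementally (O(n) per move via neighbor lists)
  and the tracked value agrees with a from-scratch recomputation to 1e-6 at
  every snapshot; a coordinate drifting 1000 Å from the initial centroid
  aborts the run with a divergence error.
- pLDDT is stored on the 0–100 scale as AlphaFold emits it; mode formulas
  divide by 100 at the point of use. Coordinates are Å throughout.

## Known limitations

- The sampler is a stand-in: single-bead moves, no secondary-structure
  bias, no side chains, no lattice, kT-unit energies. Absolute RMSF
  magnitudes from it are not comparable to MD.
- The geometric secondary-structure fallback cannot distinguish extended
  coil from β-strand and assigns no turns.
- Altlocs beyond the first are ignored; no mmCIF output; no disorder or
  occupancy handling.
- The category cutoffs and strength matrix are monotone-consistent defaults,
  not extracted reference values; use the config override to supply exact
  published tables where available.
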