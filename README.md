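# flexrestrain

Confidence-aware distance restraints for coarse-grained protein flexibility
simulation.

Fast CA-level flexibility methods keep a protein near its input structure by
restraining residue-pair distances, then sample conformations by Monte Carlo
and read per-residue flexibility off the ensemble as RMSF (root-mean-square
fluctuation). How well that works depends almost entirely on *which* pairs
are restrained and *how strongly*. `flexrestrain` implements that
restraint-generation layer for structural bioinformaticians who want to
build, inspect, perturb, or benchmark restraint schemes — in particular
schemes that exploit AlphaFold's per-residue pLDDT confidence scores, which
correlate strongly (though not perfectly) with local rigidity.

## The model

A restraint on pair *(i, j)* with input CA–CA distance *d₀* adds a
flat-bottomed, piecewise-linear penalty in kT units:

```
E(d) = 0                          for |d − d₀| ≤ 1 Å
E(d) = w·min_force · (d₀ − 1 − d) for d < d₀ − 1 Å     (compression)
E(d) = w·max_force · (d − d₀ − 1) for d > d₀ + 1 Å     (stretching)
```

with optimized defaults `min_force = 3.5`, `max_force = 0.5`, a maximum
restraint distance of 11.5 Å, and a minimum sequence separation of 3. The
pair weight *w* ∈ [0, 1] comes from one of nine modes: legacy
secondary-structure modes (SS2 / SS1 / ALL), pLDDT-statistic modes
(MIN / MAX / MEAN with a 0.5 strength floor, and the PLDDT1 / PLDDT2 gates
at pLDDT > 50), and the **Category mode**, which assigns each residue a
flexibility category 0 (fully flexible) … 3 (rigid) from its secondary
structure refined by pLDDT — coil 0 / turn 1 / helix–sheet 2 as the base,
±1 for very high (≥ 90) or low (< 50) confidence — and maps category pairs
through a 4×4 matrix to weights in {0.0, 0.5, 1.0}.

The package also ships a clearly-labelled stand-in CA Monte Carlo sampler
(harmonic virtual bonds + soft excluded volume + the restraint energy,
Metropolis acceptance; **not** a lattice engine and not a force field) so
restraint sets can be exercised end-to-end, plus the evaluation stack:
Kabsch superposition, RMSF profiles, best-of-replicas Pearson correlation,
and paired t-tests for method comparison. A fixtures module generates
synthetic structures with segment-wise secondary structure and pLDDT, and
trajectories with *planted* per-residue fluctuation magnitudes, so the whole
pipeline is testable without downloading anything. See `docs/methods.md`
for the full model description and design rationale.

## Worked example

Generate a synthetic AlphaFold-style hairpin (two high-confidence helices,
low-confidence loop and termini), a reference trajectory whose flexibility
is planted to match that layout, and its true secondary structure; then run
the full Category-mode pipeline against it:

```bash
flexrestrain fixtures -o toy.pdb --trajectory ref.pdb --frames 200 \
    --ss-out toy.ss --seed 7503
flexrestrain pipeline --pdb toy.pdb --dssp toy.ss --ref ref.pdb \
    --steps 50000 --snapshot-every 250 -o report.json
```

which logs

```
[flexrestrain] pipeline.restraints mode=CATEGORY n=61
[flexrestrain] pipeline.simulate frames=201
[flexrestrain] pipeline.evaluate best_r=0.766 out=report.json
```

and writes `report.json` containing (abridged):

```json
{
  "mode": "CATEGORY",
  "n_restraints": 61,
  "per_replica_r": [0.7663938929828309],
  "best_r": 0.7663938929828309,
  "mean_pred_rmsf": 1.195400030755271,
  "mean_ref_rmsf": 0.6463615100786666,
  "n_residues": 30
}
```

Reading the numbers: the Category mode emitted 61 restraints — the
low-confidence coil termini and loop are category 0 and left free, the
helix cores are knitted together at full strength. The sampled ensemble's
RMSF profile correlates with the planted reference at Pearson r = 0.77
(`best_r` is the maximum over however many reference replicas you pass with
repeated `--ref`). The mean predicted RMSF (1.20 Å) exceeds the reference
mean (0.65 Å): the sampler explores more broadly than the reference noise
model, which is why correlation of the *profile shape*, not absolute
magnitude, is the score. Running the same pipeline with an empty restraint
set (or `--mode` variants) shows the contrast: unrestrained runs correlate
near 0.1–0.3 on the same fixtures.

The same operations are available as a library (`parse_structure`,
`generate_restraints`, `run_sampler`, `compute_rmsf`,
`best_replica_correlation`, …); every CLI output is accompanied by a
manifest JSON and `flexrestrain rerun --manifest <file>` reproduces it
byte-identically.

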