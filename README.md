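# nacdyn

Post-simulation analysis toolkit for designer-enzyme structure and dynamics:
how a homodimeric scaffold carrying a catalytic *para*-aminophenylalanine
(pAF) residue steers its reactions, read out from crystal structures and MD
trajectories after the simulations are done.

It is written for structural bioinformaticians and computational enzymologists
who have coordinates and energies in hand and need the downstream numbers:
stereoselectivity predictions from near-attack-conformer counting,
quaternary-structure metrics, pocket volumes, interaction occupancies,
conformational cluster prevalences, and rate interpretations of barrier
differences. No simulation engine, docking or quantum chemistry is run here;
those results are inputs.

## What it computes

**Near-attack conformers (NAC).** A frame is a reactive encounter when the
bond-forming carbons are close and the attack geometry selects one prochiral
face. The diagnostic is the torsion φ over (iminium C, enal Cα, enal Cβ,
indole C3) together with the Cβ–C3 distance d: a frame is counted

- pro-(S) iff |wrap(φ − 90°)| ≤ w and d ≤ d_max,
- pro-(R) iff |wrap(φ + 90°)| ≤ w and d ≤ d_max,

with configurable window half-width w (default 30°) and d_max (default
4.0 Å). Counts over replicated trajectories, 2-D Gaussian-kernel density maps
(periodic in φ), and substrate-retention fractions per replicate summarise
the stereochemical bias and pocket residence.

**Geometry.** Distances, IUPAC-signed torsions, Kabsch superposition,
per-frame RMSD and per-atom RMSF, PCA of coordinate fluctuations, helix axes
(principal component of a turn-smoothed Cα trace, oriented N→C) and
inter-helix angles — the quantities that expose quaternary-structure changes
such as the α1/α4 packing angle and the W96↔W96′ closing of the
dimer-interface pocket.

**Pocket volume.** Two-probe grid flood fill: voxels outside every
van-der-Waals sphere inflated by a solvent probe (1.4 Å), connected to a
seed point, and not reachable by a large probe (3.4 Å) rolling in from bulk.

**Interactions.** Donor–acceptor distance series; H-bond occupancy with
persistent (≥ 0.5) / transient (0.05–0.5) / absent classes; forward/backward
states of a mobile arginine per monomer and the derived cis-forward / trans /
cis-backward dimer states; cation-π stacking geometry; radius-based
residue-sphere selection for carving quantum-cluster models.

**Clustering.** Greedy largest-neighborhood clustering on pairwise best-fit
RMSD matrices, with prevalences and representative frames.

**Energetics.** Reaction profiles as alternating minima and transition
states (kcal/mol). Step barriers (TS − preceding minimum), limiting barriers
in step or span mode (span: TS − lowest preceding minimum), pathway
comparison, and transition-state-theory conversion between barrier
differences and rate ratios, k₂/k₁ = exp(ΔΔG‡/RT).

**Synthetic data.** Every analysis ships with a seeded generator producing
data whose ground truth is known by construction (mixture-drawn reactive
geometries placed by exact internal-coordinate construction, two-state
Markov H-bond traces, jittered conformer trajectories, ideal helix pairs,
hollow shells of analytic cavity volume), so all estimators are validated by
parameter recovery.

## Worked example

```python
from nacdyn import synthdata, nac_stats, energetics

cfg = synthdata.NacMixtureConfig(n_frames=10_000, n_replicates=6, seed=1)
sample = synthdata.make_nac_trajectory(cfg)
records = nac_stats.extract_replicates(sample.trajectories, sample.spec)
labeled = nac_stats.classify_nac(records, sample.windows)
c = nac_stats.nac_counts(labeled)
print(f"frames analysed : {c.n_total}")
print(f"pro-(S) NACs    : {c.n_proS}  ({100*c.frac_proS:.2f} %)")
print(f"pro-(R) NACs    : {c.n_proR}  ({100*c.frac_proR:.2f} %)")
ret = nac_stats.retention_fraction(labeled)
print(f"in-pocket frames: {100*ret.overall_fraction:.1f} %")
fold = energetics.fold_change_from_ddG(2.1, T=298.15)
print(f"2.1 kcal/mol at 298.15 K -> {fold:.1f}-fold rate change")
```

prints

```
frames analysed : 60000
pro-(S) NACs    : 2954  (4.92 %)
pro-(R) NACs    : 0  (0.00 %)
in-pocket frames: 27.7 %
2.1 kcal/mol at 298.15 K -> 34.6-fold rate change
```

The generator planted a 5 % pro-(S) population on a diffuse background with
no pro-(R) component; the counter recovers 4.92 % (within binomial noise of
the planted weight), and a 2.1 kcal/mol barrier difference corresponds to a
~30-fold rate change at room temperature.

The same analyses are available from the shell — `nacdyn simulate`,
`nacdyn nac`, `nacdyn hbond`, `nacdyn conformers`, `nacdyn cluster`,
`nacdyn metrics`, `nacdyn pocket`, `nacdyn energetics` — each writing
per-frame TSV tables and a JSON summary that embeds the full effective
configuration and seed.

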