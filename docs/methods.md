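# Methods

This note records the models, conventions, parameter choices and known
limitations behind each analysis, and what the synthetic-data validation
does and does not establish about real data.

## Coordinate model and PDB handling

Structures are fixed-column PDB v3.3; each model becomes an ordered atom
table. Alternate locations are resolved at parse time to a single
conformer — highest occupancy wins, ties break to the lexicographically
first altloc — so that downstream geometry is deterministic; ensemble
treatment of crystallographic disorder is out of scope. Hydrogens are kept
when present, and every "heavy-atom" selection excludes elements H/D.
Residue numbering and insertion codes are taken verbatim from the file
(author numbering such as pAF15 or R92 is assumed). Because the residue
name of the noncanonical pAF residue varies between depositions, all atom
identities are user-supplied (chain, residue number, atom name) rather than
matched by residue name.

Trajectories are a fixed topology plus an `(n_frames, n_atoms, 3)`
coordinate array with a frame interval `dt` in ps. The default `dt` of
10 ps makes six replicates of 500 ns come to exactly 3 × 10⁵ frames, the
replication scheme the analyses are sized for. Multi-model PDB is the
interchange format; binary trajectory formats are out of scope.

## Geometry

Torsions use the IUPAC sign convention (clockwise positive viewed from the
second atom toward the third), range (−180°, 180°], computed as
atan2((n₁×n₂)·b̂₂, n₁·n₂) with n₁, n₂ the plane normals. The sign
convention matters: it maps +90° to the pro-(S) face, and a mirror-image
error would silently swap predicted enantiomers, so the test suite pins the
convention with an explicitly constructed rotation and against an
independent formula.

Superposition is Kabsch via SVD, always a proper rotation (determinant +1).
The reported RMSD is computed from the actual residuals rather than the
trace identity, which loses half the significant digits to cancellation
when the fit is near-exact. The batched per-frame path (RMSD series,
pairwise matrices) does use the trace identity for speed; its error is
below 10⁻⁶ Å, far under any decision threshold used here.

RMSF is the per-atom root-mean-square deviation about the mean position,
by default on frames already superposed on the selection; a two-pass
superposition onto the mean structure is available (`presuperposed=False`).
For isotropic per-axis noise of width σ the expected RMSF is σ√3, the
closed form used in validation.

Helix axes are the first principal component of the Cα trace after a
one-turn (4-residue) moving average. The smoothing is needed because a
helix spanning a non-integer number of turns has a lopsided Cα cloud whose
raw principal axis tilts by up to ~3°; after smoothing, recovery on ideal
helices is within 1° down to ~8 residues. Segments shorter than 8 residues
fall back to the raw trace. Axes are oriented N→C so inter-helix angles are
defined on [0°, 180°] without line ambiguity. Helix residue ranges are
configuration, not auto-detected; measured angles can still deviate a few
degrees from values obtained with rotational-fit axis definitions, so
inter-helix angles on real structures are reported as diagnostics rather
than gated quantities.

## Near-attack-conformer statistics

The classification windows default to centers ±90°, half-width 30°, and a
reactive-distance gate of 4.0 Å. The exact cutoff boxes behind published
counts are typically given only in supporting material; all window
parameters are therefore exposed in configuration and echoed alongside
every count, and mixing records labelled under different windows is an
error. The 15 Å distance truncation applies to density plots only, never
to counts.

The density map is an explicit Gaussian product kernel (per-axis Scott
bandwidth n^(−1/6)·σ̂) rather than a full-covariance KDE, because the
dihedral axis is periodic: data are replicated at ±360° and the grid spans
one full period, so probability mass flows across the ±180° seam and the
grid integral is 1 to discretization error. Degenerate (zero-spread)
samples raise with a suggestion to set an explicit bandwidth floor.

Substrate retention is the fraction of frames with reactive distance at or
below a cutoff (default 7 Å — inside the pocket but beyond bonding range),
and a replicate counts as "retained" when that fraction is at least 0.5.
Both values are conventions for making qualitative "stayed in the pocket"
statements quantitative, and both are configuration.

## Interactions

The H-bond criterion is a plain donor-heavy-atom↔acceptor distance cutoff,
default 3.5 Å, with no angular term — matching how such interactions are
commonly read off distance traces; occupancies are therefore slight
overestimates relative to angle-aware definitions. Persistence classes are
occupancy thresholds: ≥ 0.5 persistent, (0.05, 0.5) transient, otherwise
absent. The forward/backward state of the mobile arginine uses the
side-chain-nitrogen↔guanidinium-carbon distance with a 6.0 Å boundary.
All three numbers are conventions, config-exposed and echoed in output.

Cation-π stacking is flagged when the ring-centroid↔CZ distance is ≤ 6 Å
and the angle between the ring normal and the centroid→CZ vector is ≤ 30°.
An in-plane approach (offset near 90°) is the geometry of an H-bond to a
ring-plane donor, which is why stacking and in-plane H-bonding to the same
face are mutually exclusive — asserted on a sphere sweep in the tests.

## Pocket volume

Cavity voxels are (a) outside every van-der-Waals sphere inflated by the
small probe, (b) 6-connected to the seed, and (c) not reachable from bulk,
where bulk is the large-probe-accessible region grown back geodesically by
the probe-radius difference. Defaults: 0.5 Å spacing, 1.4 Å solvent probe,
3.4 Å bulk probe, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 Å
(unknown elements fall back to carbon). For the dimer-interface pocket of
an LmrR-type structure the natural seed is the midpoint of the two Trp96
CZ2 atoms (`pocket.w96_seed_point`). Grid methods are alignment-sensitive
at the ~2–3 % level and different cavity definitions (e.g. surface-based
tools) differ at the tens-of-percent level, so absolute volumes should be
compared only to one significant figure; on the analytic hollow-sphere
fixture the estimator is within 5 % at default spacing.

## Clustering

The classic greedy largest-neighborhood scheme: the frame with the most
neighbors within the RMSD cutoff (default 1.5 Å) founds a cluster
containing those neighbors; members are removed and the procedure repeats.
Ties break to the lowest frame index, making the partition deterministic;
clusters are numbered by decreasing size and represented by their founding
frame. The O(n²) matrix is capped at 5,000 frames; longer trajectories
must supply a uniform subsampling stride, which is recorded in the output.

## Energetics

Profiles are ordered alternations of minima and transition states on a
common kcal/mol reference, typed in from quantum-chemistry results — no
electronic-structure computation is performed. The limiting barrier
defaults to "span" mode (each TS measured from the lowest minimum anywhere
before it) because rate-determining barriers are conventionally quoted
above the resting state, not the immediately preceding intermediate; step
mode is available. Rate conversion uses k₂/k₁ = exp(ΔΔG‡/RT) with
R = 1.987204 × 10⁻³ kcal mol⁻¹ K⁻¹ and a default temperature of 298.15 K
(exposed as a parameter). This is the exponential factor of
transition-state theory; transmission coefficients and tunneling are
ignored, as is standard when interpreting barrier differences of a few
kcal/mol.

## Synthetic data: what it emulates and what it does not

Each generator is a pure function of its configuration including the seed,
and returns its own ground truth, so downstream estimators are validated
by parameter recovery at known truth:

- **Reactive-fragment trajectories** place a 6-atom fragment by exact
  internal-coordinate construction (the fourth atom rotated about the
  central bond), so the measured torsion and distance equal the sampled
  values to machine precision. Mixture values are sampled as wrapped
  normals (angles; adequate for σ ≤ 60°) and zero-truncated normals
  (distances), and each component is resampled into its designated region
  — inside the pro-(S)/pro-(R) box, or outside both for background — so
  component labels are the exact classification ground truth. Default
  mixture: 95 % diffuse background, 5 % pro-(S), six replicates of 50,000
  frames.
- **H-bond traces** are two-state Markov chains with geometric dwell times
  (mean bound dwell 50 frames) and state-conditional Gaussian distances
  (bound 2.9 ± 0.15 Å, unbound 6.0 ± 0.8 Å), separated enough that the
  3.5 Å cutoff misclassifies a negligible fraction. Recovery is judged
  against the realized occupancy: with ~50-frame dwells, a 10⁴-frame
  realization fluctuates around the target by several percent.
- **Two-state conformational trajectories** draw frames i.i.d. from
  jittered reference conformers (jitter 0.2 Å per axis against several Å
  between conformers).
- **Ideal helices** use rise 1.5 Å, twist 100°/residue, radius 2.3 Å;
  **hollow shells** tile Fibonacci-sphere layers so the probe-accessible
  cavity is a sphere of exactly the requested radius (scalloping < 0.05 Å
  at ≤ 1 Å atom spacing).

These generators reproduce the statistical structure the estimators assume
— not real force-field physics. Passing recovery tests shows the
estimators are correct and correctly sized for the stated replication
(6 × 500 ns at 10 ps), not that any particular enzyme behaves as the
mixtures do: real trajectories have autocorrelation in the reactive
geometry (the NAC generator draws frames independently), anisotropic
fluctuations, and H-bond distance distributions with heavier tails.
Accession-dependent metrics (closest-atom distances, pocket volumes and
helix angles of deposited crystal structures) run through the same code
paths but require the user to supply the coordinate files.

## Numerical choices and degenerate inputs

Coincident or collinear points make torsions undefined and raise; point
sets of rank < 2 make the optimal rotation non-unique and raise; a
near-isotropic Cα cloud flags the helix axis as ill-defined rather than
raising. Minimum-distance ties resolve to the lexicographically lowest
index pair. Wrapped angles use the half-open interval (−180°, 180°].
Seeds below 2³¹ are accepted everywhere; all generators are reproducible
bit-for-bit given the seed.

Problem sizes used in the shipped validation (10⁵ random quadruples for
the torsion oracle, 10⁵ frames for RMSF recovery, 3 × 10⁵ records for
frame accounting, 10³ frames for clustering recovery) were chosen so every
statistical tolerance is several standard errors wide at desk scale.
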