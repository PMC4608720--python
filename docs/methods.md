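# Methods

This note documents the models, conventions and free parameters behind
`kinastate`, and what the synthetic benchmarks do and do not establish.

## Coordinate and numbering conventions

All in-memory coordinates are Ångström (XTC's nm convention is converted on
read/write), times are nanoseconds, and residue identifiers are the author
numbering of the ZAP-70 kinase domain (DFG aspartate = 479, regulatory salt
bridge K369–E386, αC helix D379–Q392, gate tryptophan 505). Atom indices
are 0-based. Van der Waals radii and masses come from a bundled per-element
table (Bondi-style radii) shipped as JSON so it can be overridden.

## Descriptors

**Superposition.** Rigid-body fits are least-squares (Kabsch via SVD) with
a proper rotation enforced (det = +1). The test suite checks the fit
against an independent closed-form quaternion (Horn) solution.

**B-factors.** `B = (8π²/3)·⟨|Δr|²⟩` per residue Cα. The default alignment
reference is an iterated mean structure (first-frame pass plus two mean
passes), the standard RMSF practice; a first-frame reference is available
by flag. The convergence diagnostic splits the trajectory into 10
sequential segments of equal length (remainder frames in the last segment)
and computes segment-local B with segment-local means; the across-segment
variance (ddof = 1) per residue is reported.

A caveat worth knowing: a per-frame least-squares fit absorbs six degrees
of freedom, biasing B low by roughly the factor (1 − 2/N) for N fitted
atoms. This is negligible at protein size but visible on small test
systems, so `bfactor_profile(..., prealigned=True)` skips the fit for
trajectories aligned upstream (the original workflow aligns once, then
computes B-factors) or for synthetic jitter with no rigid motion. The
closed-form benchmark (isotropic jitter with per-axis σ ⇒ B = 8π²σ²) uses
this path.

**Distances and contacts.** Three modes: `atom` (singleton to singleton),
`com` (mass-weighted centres of mass), `min` (minimum pairwise heavy-atom
distance; hydrogens excluded). Contact occupancy is the fraction of frames
with minimum distance strictly below the cutoff. The salt-bridge cutoff
defaults to 4.0 Å between charged-group heavy atoms (NZ vs OE1/OE2); no
angular criteria are used anywhere.

Panel-specific conventions:

* *DFG cyclization* is the D479 side-chain carboxylate carbon to the G481
  backbone amide hydrogen, atom mode. "Carboxylate carbon" is read as the
  CG atom of the aspartate side chain; the role map can override the atom
  name. When the structure has no amide hydrogen (crystal structures), the
  series falls back to the amide nitrogen minus a nominal 1.0 Å bond
  correction and flags this in metadata.
* *αC positioning* is the mass-weighted COM distance between the Cα atoms
  of the helix range and the Cα atoms of the C-lobe residue range in the
  role map — the source analysis says "centre of mass of the C-lobe"
  without fixing a selection, so the Cα-range reading is recorded in the
  output metadata.
* *W505 gate* is the minimum distance from the W505 side-chain heavy atoms
  to the bound ligand; lacking a ligand, to a configured anchor role
  (flagged in metadata). Side-chain-only, because the gating motion is a
  side-chain reorientation.

## State fingerprinting

Per-frame DFG states use midpoint boundaries between the three reported
distance levels (≈3 / ≈6 / ≈8 Å): closed < 4.5 Å ≤ semi-closed < 7.0 Å ≤
open. αC states likewise (≈13.5 / ≈14.5–15 / ≈15.5 Å): buried < 14.25 Å ≤
intermediate < 15.25 Å ≤ displaced. Intervals are left-closed on the upper
side, so every non-negative distance belongs to exactly one state and the
occupancy fractions partition to 1. The boundaries are this package's
stated convention — the underlying study reports state centres, never a
decision rule — and are configurable. Dominant-state ties break toward the
more closed/buried state. No temporal smoothing or hidden-Markov modelling
is applied.

## Collective modes

"Normal modes" are quasi-harmonic: eigenvectors of the covariance of
centered Cα coordinates after all frames (concatenated across states, in
mapping insertion order) are aligned to an iterated global mean structure.
Rigid-body motion is removed by that alignment, not by discarding six
eigenmodes; near-zero residual modes are reported. No mass weighting by
default. Eigenvalues are variances (Å²); projections are per-frame scalars
carrying the state label; the full spectrum is retained so the trace
identity Σλ = total coordinate variance can be asserted.

**Discrimination score.** Per mode, a one-way ANOVA F statistic over
states computed on *squared* projections. Squaring matters: a
state-specific motion can be a zero-mean oscillation whose amplitude —
not mean — differs by state, and a mean-based F is blind to it; the
squared-projection F responds to both amplitude differences and mean
shifts. Significance is calibrated with a label-permutation null
(p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1)); with 200 permutations the
smallest attainable p is ≈ 0.005. This statistic is the package's
formalisation of "mode amplitudes correlated with state"; it is an
extension, not a reproduction of any published number.

## Cavity scan

A frame is rasterised at 1.0 Å spacing: a voxel is protein if its centre
lies within (vdW radius + 1.4 Å water probe) of any atom; the grid margin
exceeds the largest inflated radius plus a probe diameter so cavities never
touch the boundary. An empty voxel is a cavity candidate if a ray along at
least `min_blocked` of the six axis directions hits protein (default 6, the
strictest buriedness); candidates are grouped by 26-connectivity and
components under 27 Å³ (one 3×3×3 voxel cube) are dropped. Volume is voxel
count × spacing³. None of these parameters is published for the original
pocket screen; they are configuration keys with these defaults.

Pocket tracking records, per (optionally strided) frame, the single largest
component having a voxel centre within 5 Å of any atom of the seed
selection (default: the ten pocket-lining residues) — the
largest-qualifying-component rule matches the singular "the pocket" usage —
with 0 Å³ when none qualifies. The open/close reporting threshold defaults
to 100 Å³: above the ≤ 40 Å³ discretisation/noise floor observed on
non-gated synthetic states and below the 125 Å³ planted void, so the
boolean series is unambiguous on the benchmark. It is purely a reporting
convention.

Discretisation notes: planted rectangular voids are recovered within a
one-voxel-shell tolerance, |V − edge³| ≤ ((edge + 2·spacing)³ − edge³)/2;
volumes are rotation-robust (< 15 %) for generic orientations, while the
exactly grid-axis-aligned pose of a flat-walled void is degenerate (whole
boundary-voxel layers flip with the grid origin) and excluded from that
property.

## Synthetic generator

The generator exists to give every analysis stage a ground truth without
molecular dynamics. It is explicitly *not* physics: no force field,
solvent, thermostat or realistic kinetics.

**Scaffold.** Residues 336–600 (265 residues; the minimum that hosts all
functional roles). Two compact pseudo-lobes of Cα atoms on a 3.8 Å cubic
lattice (sphere-covering, so the lobes are voxel-solid), an activation-loop
arc on the C-lobe surface, a 14-residue straight αC helix in the inter-lobe
gap, and pseudo-side-chain atoms for every role (carboxylate C/O pairs, NZ,
CZ, amide N/H, hydroxyls). The W505 side chain is a rigid 9-atom
indole-like cluster; a sealed 6-faced box of wall atoms assigned to the ten
pocket-lining residues encloses a 5×5×5 Å void that the cluster fills
("in") or vacates ("out"). A single-carbon pseudo-ligand marks the ATP
site. Wall, gate and anchor atoms carry no thermal noise, so the planted
cavity geometry is exact.

**Processes per frame** (all from one seeded generator; identical seed ⇒
bit-identical trajectory):

* Baseline iid Gaussian jitter, default σ = 0.3 Å; activation-loop and
  flap (537–569) atoms scaled by the profile's `loop_flex_scale`.
* DFG and αC distances follow Ornstein–Uhlenbeck processes (relaxation
  time 1 ns, matching the 0.1 ns frame interval) around the profile target,
  realised exactly: the D479 CG atom is placed at the drawn distance from
  the G481 H along a fixed direction, and the helix is rigidly translated
  so its Cα COM sits at the drawn distance from the C-lobe Cα COM.
  Scheduled transitions are step changes of the OU mean.
* The salt bridge is a two-state telegraph process realised as exact
  formed (3.0 Å) / broken (8.0 Å) NZ–OE1 geometries. The propagation uses
  the exact two-state CTMC transition matrix over one frame interval, which
  preserves the stationary occupancy at any time step (naive
  1 − exp(−k·dt) hazards do not). The switching rate (inverse correlation
  time) defaults to 20 /ns — correlation time half a frame interval — so
  occupancy estimates converge at the binomial rate the recovery benchmarks
  assume; the source study reports no switching kinetics.
* Collective modes displace Cα atoms along fixed orthonormal directions
  (deterministic per topology, drawn direction-by-direction so every state
  shares the same basis, and orthogonalised against the six rigid-body
  motions of the reference so alignment cannot mix them) with
  sinusoid-plus-noise amplitudes (periods 4–7 ns, amplitude noise 0.3 Å).
* Pocket gating is a dwell-time telegraph (default mean open/closed dwell
  2 ns each, non-phosphorylated state only), chosen so open-fraction
  statistics converge within the few-hundred-ns windows the examples use.

**Default state profiles** (the study conditions): STA — DFG 3.0 Å, αC
15.0 Å, bridge occupancy 1.0; Y⁰Y⁰ — 5.0 Å, 14.5 Å, 0.5, gated pocket;
YᴾY⁰ — DFG 5.0→8.0 Å stepping at 0.4 of the run (the reported ~600 ns mark
of a 1.5 μs trajectory) with αC 13.5→14.5 Å at one third, bridge 0.1;
Y⁰Yᴾ — 5.0 Å, 15.5 Å, 0.0; YᴾYᴾ — 8.0 Å, 15.5 Å, 0.0. Descriptor standard
deviations default to 0.3 Å — the source reports no variances, so these
are free parameters. Loop-flexibility multipliers (1.0 / 1.2 / 2.0 / 2.5 /
3.0) encode the reported flexibility ordering, not measured values.
`n_frames` defaults to 15,000 (0.1 ns interval); tests and the analysis
scripts use 400–5,000 frames, which is where the planted statistics have
already converged.

**What passing means.** The benchmarks establish that the analysis stack
measures what is planted: exact geometric placement, stationary laws,
subspace recovery, analytic volumes. They do not establish anything about
force-field physics, real kinase kinetics, solvent effects, or the
behaviour of the descriptors on crowded all-atom geometries; in real data
the descriptor atoms are noisy measurements, not exact placements, and
pocket volumes depend on the (unpublished) screening parameters.

## Pipeline

`run_pipeline` composes simulate/load → descriptors → fingerprint → cavity
→ modes → report with deterministic filenames; each stage consumes only
earlier outputs. CSV floats are written with fixed formats and JSON with
sorted keys, so a rerun with identical config and seed is byte-identical.
The provenance block records package version, seed, and a SHA-256 hash of
the canonicalised config. The CLI (`kinastate`) exposes the stages as
subcommands over YAML configs; the numbered scripts under `analysis/` run
the same library calls as a narrative workflow.

## Problem sizes

Defaults in the analysis scripts and acceptance script: 2,000 frames per
state (five states), collective modes over the 10,000 concatenated frames
on 265 Cα atoms, cavity tracking on every 10th–25th frame, 200 label
permutations, occupancy recovery at 10,000 frames, the Gaussian B-factor
benchmark at 5,000 frames. These sizes are where the planted statistics
sit well inside their tolerance bands; larger runs change nothing but
runtime.

## Known limitations

* The selection grammar is deliberately minimal (names, residue ranges,
  roles, `protein`, AND); no OR/NOT, no distance-based selections.
* No PBC unwrapping, no mmCIF, no altloc occupancy logic beyond
  keep-first.
* Hydrogen-bond occupancies are distance-only; no angular criteria, no
  side-chain rotamer analysis.
* The fingerprint thresholds are conventions over reported state centres;
  on real data hysteresis (available, off by default) may be preferable
  near boundaries.
* Quasi-harmonic modes assume the alignment fully separates internal from
  rigid-body motion; for large conformational changes this is approximate.
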