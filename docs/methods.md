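# Methods

This note records the models implemented by `mutscan`, their assumptions,
the defaults and why, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Scope and data model

The package analyses *existing* trajectories; it performs no molecular
dynamics. A `MolecularSystem` holds one receptor-ligand complex as
parallel per-atom arrays (identity, coordinates in Å, partial charge in
e, 12-6 Lennard-Jones epsilon in kcal/mol and r_min/2 in Å, a PB radius in
Å). Ligand atoms are identified as HETATM records by default, overridable
by residue name or chain. A `Trajectory` is a frame stack in the system's
atom order with per-frame replica and section labels; sections (one per
receptor form in a concatenated pool) must be contiguous. Structures and
trajectories travel as PDB v3.3 text (multi-model dialect for
trajectories, with a `REMARK 250 FRAME_SPACING_PS` header), chosen over
binary MD formats so fixtures stay diffable; the reader interface is
narrow enough that binary readers can be added without touching analysis
code. Nonbonded parameters come from a TSV table keyed by
(residue_name, atom_name) — a desk-scale stand-in for a force-field
assignment; atoms without entries are a hard error, except hydrogens,
which may be dropped with a warning when a heavy-atom-only energy model is
configured.

Replica concatenation removes frames with time < `discard_ps` from the
head of each replica (frame *i* of a replica sits at *i* × spacing), so
two 5000-frame replicas at 10 ps with a 5 ns discard leave exactly 9000
analysis frames — the frame-bookkeeping identity the test suite pins
down, together with the 36000- and 18000-frame multi-form pools.

## Trajectory statistics

Fits are mass-unweighted Kabsch least squares (SVD with a determinant
correction; a degenerate — collinear — fit mask raises). RMSD series fit
each frame on a fit mask and measure on a measure mask; a helper drops
the last *n* residues of each receptor chain from a mask, because
flexible C-terminal tails otherwise dominate RMSD. RMSF is measured about
the trajectory-average structure, computed self-consistently
(fit-to-average, re-average, three iterations), and reported per residue
as the mean of its masked atoms' RMS deviations; the backbone is
N/CA/C/O, with a Cα-only mode for clustering parity. Positional PCA
eigendecomposes the 3N×3N covariance of the fitted frames; eigenvalues
(Å², descending) sum to the total positional variance. Rigid-body motion
applied uniformly to all frames leaves RMSF and PCA invariant (tested).

Note the estimator bias that the tests account for: the 6 rigid-body
degrees of freedom absorbed by fitting shave ~6/(3N) of the variance, so
planted amplitudes are recovered to within a few percent on a 12-residue
system but visibly low on very small ones.

## Conformational clustering

Phase 1 draws a reference uniformly from the still-unbinned frames and
bins every unbinned frame with RMSD strictly below the cutoff (2.0 Å
default, Cα atoms, per-pair Kabsch fit); this repeats until the pool is
empty, so the reference count is data-driven. Phase 2 reassigns every
frame to its nearest reference with no cutoff. Binned frames leave the
pool entirely (they are neither drawn nor re-binned). The draw order is
the only randomness and is fully determined by the seed; ties (equal
RMSD, equal counts) resolve to the lowest reference index. Per-section
membership counts identify each form's most-represented reference — that
reference frame is the form's representative conformation, by design the
structure most typical of that form rather than one visited by all forms.
Equivalence with a brute-force nearest-reference search over the full
pairwise RMSD matrix is tested across 20 seeds.

## Contact occupancies

A contact's occupancy is the percentage of frames in which a geometric
predicate holds. H-bonds: donor-acceptor heavy-atom distance <= 3.5 Å
and, when hydrogen positions are available, D-H···A angle >= 120°, both
inclusive at the boundary; a heavy-atom-only mode exists for
hydrogen-free fixtures. These are common literature defaults — the
criteria are configurable, and no occurrence filter is applied to H-bond
tables. Salt bridges: candidate pairs are all (cation, anion) group
combinations among charged residues (Asp/Glu anions; Lys/Arg and
explicitly protonated His cations; the ligand's protonated amine) with a
heavy atom within 10 Å of any ligand heavy atom, evaluated on the first
analysis frame by default (an option unions the selection over frames);
a bridge is present when the minimum side-chain N···O distance is
<= 4.0 Å (configurable; 3.2 Å gives parity with a common
visualization-tool default), and rows under a 10% merged occurrence are
discarded. Because "averaged over replicas" is ambiguous for unequal
replica lengths, tables carry both the pooled-frame percentage (the
frame-weighted mean, used by the filter) and the plain mean of replica
percentages; they coincide for equal-length replicas.

## Binding energetics

Single-trajectory MM/PBSA. The bound and unbound states share
conformations, so the internal (bonded) term is an exact zero, and the
entropy term is neglected (the report schema carries it as an explicit
null): values are *relative* binding energies, meaningful for comparing
complexes of the same ligand with similar binding modes.

* **Coulomb**: k q_i q_j / r_ij summed over receptor-ligand pairs,
  k = 332.0636 kcal·Å/(mol·e²), no cutoff, no periodicity (desk-scale
  systems; a production-MD cutoff belongs to the simulation stage, not
  the analysis).
* **Lennard-Jones 12-6**: eps_ij[(r_min,ij/r)^12 − 2(r_min,ij/r)^6] with
  eps_ij = sqrt(eps_i eps_j) and r_min,ij = r_min,i/2 + r_min,j/2 (the
  parameter table's r_min/2 convention).
* **Polar solvation**: finite-difference linearized Poisson-Boltzmann on
  a node-centred grid. Defaults: solute dielectric 2, solvent 80, 0.15 M
  monovalent salt at 310 K (physiological), 0.5 Å spacing, 10 Å padding,
  Dirichlet boundary from the Debye-Hückel screened Coulomb sum. The
  dielectric is assigned per *edge* as the series (harmonic) combination
  of the exact inside-solute fraction of that edge (van der Waals
  surface; overlapping atoms combine by the maximum single-atom
  fraction) — this fractional-edge scheme is what makes the energy
  converge smoothly and monotonically under grid refinement, where a
  sharp midpoint dielectric oscillates. Charges spread trilinearly; the
  grid self-energy cancels by subtracting a uniform-solute-dielectric
  solve on the identical grid with identical spreading; per-atom
  reaction-field energies ½q(Δφ) are interpolated at the atom centres.
  The linear system is solved by Jacobi-preconditioned conjugate
  gradients (rtol 1e-8) started from the boundary-condition guess;
  non-convergence raises with the residual. Validation: the single-ion
  case reproduces the Born closed form within 0.31% at 0.4 Å spacing,
  with monotone improvement from 0.8 to 0.4 Å.
* **Nonpolar solvation**: gamma × buried SASA with
  gamma = 0.00542 kcal/(mol·Å²) and an additive constant b (default 0)
  that cancels in all delta-delta comparisons. SASA is Shrake-Rupley with
  deterministic golden-spiral points (960 default; 240 in trajectory
  loops), probe 1.4 Å; validated against the closed-form sphere and
  two-sphere cap areas and cross-checked against an independent
  implementation.
* **Complex/receptor/ligand terms** are evaluated on the identical grid
  (box enclosing the complex), so grid placement cancels in the
  difference.

**Per-residue decomposition** accumulates per-atom energies — half of
each pairwise Coulomb/LJ term to each partner atom (symmetric and
total-conserving; the attribution of a pair term to its two residues is
a convention, and 50/50 is the neutral choice), per-atom reaction-field
differences for polar, per-atom buried area × gamma for nonpolar — and
sums within residues. Because the total is accumulated from the same
arrays, residue contributions reproduce the total to float roundoff
(~1e-14 kcal/mol observed; the tests require 1e-6). ddG maps subtract
wild-type from mutant per matched (chain, residue-index) pairs,
are antisymmetric under swapping, exclude unmatched residues with a
warning, and flag residues beyond ±1 kcal/mol.

Component-vs-total Pearson correlations across a set of complexes use at
least three reports and raise on zero variance. On the six published
(electrostatic, total) component pairs of the motivating study, the
independent hand computation gives r = 0.9886; the test suite freezes
that value (the study prints 0.89 for this correlation without stating
the aggregation level, and the printed value is not recoverable from the
six table rows — flagged, not targeted).

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the analyses
consume, with exact ground truth:

* Study-design defaults: 2 replicas × 5000 frames at 10 ps (50 ns runs
  recorded every 10 ps); the first 5 ns are discarded downstream, not by
  the generator.
* Geometry: an ideal α-helical backbone (100°/1.5 Å per residue, Cα
  radius 2.3 Å) with a two-atom pseudo side chain per residue; the tip
  atom carries the residue's formal charge (−1 "ASP"/OD1, +1 "LYS"/NZ,
  0 "ALA"/CG) and sits at the same position in every charge plan, so
  variants share identical geometry and a "mutation" is a pure charge
  change. A rigid 5-atom ligand with a +1 amine nitrogen (a
  protonated-inhibitor mimic) sits against the pocket residue's tip at
  ~3 Å minimum heavy-atom separation.
* Dynamics: per frame, a conformer template is drawn by mixing weights
  (or a two-state Markov chain, switch rate 0.05/frame, for
  autocorrelation tests); zero-mean Gaussian noise with per-residue RMS
  amplitude a (per-coordinate sigma a/√3; default 0.5 Å, the scale of
  stable-core backbone fluctuations) is added, the ligand moving rigidly
  (0.3 Å); then each planned contact's donor is pinned at the bound or
  unbound distance from its acceptor by a Bernoulli draw at the target
  occupancy. Contacts are imposed geometrically, not dynamically —
  that is the price of exact, analyzable truth.
* Reproducibility: replica r uses seed + r (1-based); everything is
  bit-reproducible given the spec.
* The sensitive/wild-type/resistant variant trio plants one pocket
  aspartate (wild type), adds a second (sensitive), or neutralizes it
  (resistant), with ±1 e charges at 3–7 Å from the +1 ligand — tens of
  kcal/mol of electrostatic separation, the toy analogue of the D→V
  resistance substitution abolishing a ~−8 kcal/mol residue
  contribution.

What it does *not* emulate: real force-field energetics, solvent and
counterions, bonded strain, correlated side-chain/backbone motion,
induced fit, or trajectory autocorrelation (except the optional Markov
basins). Passing tests therefore demonstrate that the *estimators and
bookkeeping* are correct — occupancies converge to planted values at the
binomial rate, clustering recovers planted basins, decomposition
conserves totals, rankings follow planted energetics — not that the
physical model reproduces any particular experimental affinity.

## Pipeline and determinism

`run_pipeline` executes ingest → concatenate (discard) → cluster →
metrics → contacts → energetics from a flat `key = value` config (CLI
flags override), writing TSV/CSV reports and a manifest (config hash,
seeds, per-stage frame counts, output inventory). Identical configs
reproduce identical files byte for byte. Energetics may be strided
independently of the other stages (grid solves are the cost centre);
warnings never silently change numbers — errors abort with the stage
name.

## Problem sizes in tests and the acceptance script

Test fixtures use 8–12-residue receptors, 2–4500 frames per replica, and
PB grids of 1.0–1.2 Å spacing with 7–8 Å padding; the acceptance script
uses 20 seeds for the ranking suite and the full 2 × 4500-frame design
for occupancy recovery. These sizes were chosen so the planted effects
dominate estimator noise by comfortable margins at desk scale; the Born
validation runs at the 0.4 Å spacing where the solver's discretization
error is a fraction of a percent.

## Known limitations

* The PB dielectric uses the van der Waals surface (fractional-edge),
  not a molecular (solvent-excluded) surface; buried inter-atom crevices
  are treated as solvent. Adequate at toy scale; a real-protein polar
  term would need a molecular-surface map.
* The maximum-over-atoms combination of edge fractions underestimates
  coverage where two atoms cover an edge from opposite ends.
* SASA point sampling (not analytic); 960 points give ~1–2% per-atom
  accuracy.
* Occupancy confidence intervals assume independent frames; for
  Markov-correlated synthetic data the binomial sigma understates the
  estimator spread (the tests use the iid mode when asserting binomial
  bounds).
* Single-trajectory MM/PBSA with neglected entropy yields relative, not
  absolute, binding energies; magnitudes are much larger than
  experimental affinities by construction.
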