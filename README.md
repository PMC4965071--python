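# mutscan

Post-MD analysis of receptor tyrosine kinase / inhibitor complexes —
conformational clustering with representative-structure selection,
RMSD/RMSF/PCA trajectory statistics, hydrogen-bond and salt-bridge
occupancy tables, and an MM/PBSA-style binding free energy with
per-residue decomposition and mutant-vs-wild-type ddG maps.

## Who it is for

Structural bioinformaticians studying drug-resistance mutations in
kinase-inhibitor systems (the motivating case is Imatinib bound to the
type-III receptor tyrosine kinases KIT and CSF-1R, in wild-type and
resistant/sensitizing point-mutant forms). The package takes ordered
coordinate frames from MD simulations (multi-model PDB), concatenates
replicas with an equilibration discard, and answers the questions that
drive a resistance analysis: which conformation best represents each
receptor form? Which contacts hold the inhibitor in place, and how often?
How does the binding free energy split into components, and which residues
carry the difference between mutant and wild type?

Because MD trajectories of real kinases are rarely shareable, the package
includes a first-class synthetic-data generator that plants known
statistical structure (contact occupancies, fluctuation amplitudes,
conformational basins, charge layouts) into toy receptor-ligand
trajectories, so every stage is testable end to end against exact ground
truth.

## The methods

**Clustering.** Fast random-reference RMSD clustering: a reference frame
is drawn at random, every unbinned frame within a cutoff RMSD (default
2.0 Å, Cα atoms, Kabsch-fitted) joins its bin, and the draw repeats until
no frames remain; each frame is then reassigned to its nearest reference.
On a pool concatenated from several receptor forms ("sections"), the
reference most populated by a given form is that form's representative
conformation.

**Energetics.** Single-trajectory MM/PBSA:

    dG_bind ~= dE_MM + dG_sol - T dS,      dE_MM = dE_int + dE_elect + dE_vdw

with dE_int = 0 (bound and unbound conformations are identical) and the
entropy term neglected (carried as an explicit null), so values are
relative binding energies. dE_elect and dE_vdw are cutoff-free Coulomb
(k = 332.0636 kcal·Å/mol/e²) and 12-6 Lennard-Jones receptor-ligand
interaction energies. dG_sol = dG_polar + dG_nonpolar: the polar part from
a finite-difference linearized Poisson-Boltzmann solver (complex minus
receptor minus ligand on the identical grid, validated against the Born
ion closed form), the nonpolar part as gamma * buried SASA
(Shrake-Rupley). Per-residue contributions follow the atomwise
bound-minus-free convention, dRxBE = sum_i (A_i^bound - A_i^free), with
pairwise terms split half-and-half, so residue contributions sum exactly
to the total; ddG maps subtract wild-type from mutant contributions per
residue and flag residues beyond ±1 kcal/mol.

**Contacts.** H-bond occupancy (% of frames; donor-acceptor <= 3.5 Å and,
when hydrogens exist, D-H···A >= 120°) per replica and merged; salt
bridges among charged residues within 10 Å of the ligand (side-chain
N···O <= 4.0 Å), filtered at 10% minimum occurrence.

## Worked example

```python
import numpy as np
from mutscan import (SyntheticSpec, make_toy_complex, simulate_trajectory,
                     fast_reference_clustering, calpha_mask,
                     binding_energy_trajectory, PBGridSpec)
from mutscan.synthetic import variant_charge_plans

spec = SyntheticSpec(n_residues=9,
                     charge_plan=variant_charge_plans(9)["wildtype"],
                     replica_count=2, frames_per_replica=100, seed=11)
system = make_toy_complex(spec)          # helical receptor + cationic ligand
traj, truth = simulate_trajectory(system, spec)

clusters = fast_reference_clustering(traj, calpha_mask(system),
                                     cutoff=2.0, seed=0)
print(len(clusters.reference_frames))    # -> 1   (single planted basin)

grid = PBGridSpec(spacing=1.0, padding=8.0, ionic_strength=0.0)
report = binding_energy_trajectory(traj, system, grid, stride=20)
print(report.to_series().round(1))
```

prints (kcal/mol):

```
dG_vdw          3.1
dG_elect      -78.5
dG_polar       38.7
dG_nonpolar    -0.3
dG_sol         38.4
dE_int          0.0
dG_bind       -37.0
```

i.e. binding of the +1 ligand to the pocket aspartate is driven by
electrostatics (−78), roughly half paid back by desolvation (+39), with
dG_bind the exact sum of the components. Neutralizing the pocket
aspartate (`variant_charge_plans(9)["resistant"]`) collapses dG_bind to
about −0.5 kcal/mol — the package's toy-scale analogue of a
resistance-conferring D→V substitution.

The same analysis runs from a shell:

```bash
mutscan simulate --n-residues 9 --frames 100 --seed 11 --out run/
mutscan cluster --structure run/system.pdb --trajectory run/trajectory.pdb \
        --cutoff 2.0 --seed 0 --out run/clusters.tsv
mutscan run --config config.txt --out run/        # full pipeline + manifest
```

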