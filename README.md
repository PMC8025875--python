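# cryofit

Multi-scale flexible fitting of protein structures into cryo-EM density
maps at medium resolution (~5-8 Å).

At such resolutions a single long flexible-fitting simulation often
fails for multi-domain proteins: a biasing force strong enough to drive
a large conformational transition also distorts secondary structure
(overfitting), while a weak force leaves the structure trapped far from
the map. `cryofit` implements a three-step protocol that addresses this
by separating the problems:

1. **Step 1 — REUSfit.** Coarse-grained (one bead per residue, at the
   Cα position) structure-based ("Go-model") molecular dynamics with a
   density-fitting bias, run as a replica-exchange ensemble over the
   bias force constant. Each replica feels the potential

       V_EM = k (1 − CC),   CC = Σ ρ^targ ρ^calc / √(Σ (ρ^targ)² Σ (ρ^calc)²)

   where CC is the voxel-wise cross-correlation between the target map
   and a map simulated from the moving structure (one Gaussian per
   bead, recomputed every step). Neighbouring replicas on the force
   constant ladder k₁ < … < k_M swap force constants with Metropolis
   probability w = min(1, e^(−Δ)), Δ = β (k_n − k_m)(CC_j − CC_i), which
   routes strong biases to the replicas that currently fit best. The
   highest-CC frame over all replicas is the step-1 model (M1).
2. **Step 2 — targeted MD.** The original structure is driven to the M1
   Cα coordinates by a restraint on the best-fit RMSD that follows a
   linear schedule Δρ = Δt (ρ₀ − ρ_f)/T. The density map is not used in
   this step. The result, rigid-aligned onto M1, is M2.
3. **Step 3 — refinement.** Fixed-k flexible fitting from M2 polishes
   the model against the map; the highest-CC frame is M3.

The **simple protocol (SP)** — one fixed-k fitting run from the initial
structure — is included as the baseline the three-step protocol is
measured against.

Because the Go model's minimum is the native (initial) structure, native
secondary and tertiary contacts resist deformation during the aggressive
CG search, and replica exchange removes the need to guess the right
force constant. Quality metrics: CC, RMSDt/RMSDi (best-fit Cα RMSD to
the target/initial structure), and a secondary-structure score — the
length-normalized Hamming distance (in %) between per-residue DSSP code
strings of model and target.

## Worked example

The package ships a deterministic two-state toy: two ideal Cα helical
arms joined at a hinge, with states differing only by hinge angle
(150° open → 90° closed). Fitting the open state into a 5 Å map
simulated from the closed state exercises the full pipeline in seconds:

```
$ cryofit make-toy toy
wrote toy system (30 residues) to toy

$ cryofit reusfit toy/initial.pdb toy/target.mrc --n-steps 20000 --seed 1 -o best.pdb
best CC 0.9985 (replica 7); exchange acceptance 0.35; wrote best.pdb

$ cryofit tmd toy/initial.pdb best.pdb -o m2.pdb
final RMSD to target 0.113 A; wrote m2.pdb

$ cryofit refine m2.pdb toy/target.mrc -o m3.pdb --n-steps 10000
best CC 0.9981 at step 0; wrote m3.pdb
```

The initial structure starts 4.54 Å (Cα RMSD) from the answer; the
step-1 model lands at 0.57 Å with CC 0.9985, targeted MD transfers those
coordinates to within 0.11 Å, and refinement holds the model at 0.59 Å
RMSDt / CC 0.998. The `multiscale` and `simple` subcommands run the
whole protocol (and the baseline) from a YAML config with per-stage
logs, resumable run directories, and ranked model reports; the same
functionality is available as a library (`cryofit.run_multiscale`,
`cryofit.run_reusfit`, ...).

Real density maps are read from MRC/CCP4 or Situs ASCII files (negative
voxels are clamped to zero first); simulated maps are generated from a
target structure with `cryofit simulate-map` (default 5 Å resolution,
2 Å voxels).

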