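# Methods

This note documents the models, numerical choices and limitations of
`cryofit`. Units throughout: length Å, energy kcal/mol, mass amu, time
ps (1 (kcal/mol/Å)/amu = 418.4 Å/ps²; k_B = 0.0019872041 kcal/mol/K).

## Coarse-grained force field

One bead per residue at the Cα position; the potential's global minimum
is the native (input) structure.

- **Pseudo-bonds** between consecutive beads at their native lengths
  (not a uniform 3.8 Å). During dynamics they are constrained by SHAKE,
  so the harmonic constant (default 100 kcal/mol/Å²) matters only for
  unconstrained (NVE test) runs.
- **Angles**: harmonic at native values, k_a = 20 kcal/mol/rad².
- **Dihedrals**: Fourier form k₁[1−cos(φ−φ₀)] + k₃[1−cos 3(φ−φ₀)] with
  native phase, k₁ = 1.0 and k₃ = 0.5 kcal/mol — the common Cα Go-model
  parameterization.
- **Native contacts**: residue pairs at sequence separation ≥ 4 (any
  separation across chains) whose heavy atoms approach within 4.5 Å in
  the native structure (Cα–Cα < 6.5 Å when only Cα coordinates exist;
  both configurable). The pair potential is the 12-10-6 well
  ε[13(σ/r)¹² − 18(σ/r)¹⁰ + 4(σ/r)⁶] with σ = r₀ (native distance), so
  the minimum is exactly −ε at r₀. Well depths are weighted by
  statistical contact energies of the residue-type pair and renormalized
  so their mean equals `base_epsilon` (default 1.0 kcal/mol). The
  shipped table holds like-pair energies of the Miyazawa–Jernigan type;
  cross terms use the one-body factorization e_ij = −√(e_ii·e_jj), which
  is known to reproduce such statistical potentials closely. Unknown
  residue types fall back to the mean energy with a warning. Only the
  relative magnitudes matter after renormalization.
- **Non-native pairs** (same separation rule, not in contact) repel via
  a WCA-style term ε_nn[(σ_nn/r)¹² − 2(σ_nn/r)⁶ + 1] for r < σ_nn and
  exactly zero (value and force) beyond, with σ_nn = 4.0 Å,
  ε_nn = 0.1 kcal/mol. The compact support is deliberate: no non-contact
  pair sits closer than σ_nn in a native structure, so the native state
  is an exact stationary point of the total potential (verified to
  ≤ 1e-6 kcal/mol/Å per bead).
- **Cutoff**: pair terms are switched smoothly (CHARMM switching
  function) between 18 and 20 Å, keeping energy and force continuous.
- Multi-chain assemblies: per-chain models are merged with bead-index
  offsets; inter-chain native contacts are detected on the assembled
  complex; contact strengths between chosen residue sets can be rescaled
  (e.g. threefold) to pin interfaces that must not detach.

## Simulated density maps and the fitting bias

ρ^calc is a sum of isotropic Gaussians, one per bead, unit weight. The
width follows the FWHM convention: σ = resolution / (2√(2 ln 2)), with a
configurable multiplier, so the Gaussian FWHM equals the nominal
resolution. During fitting each Gaussian is truncated to zero below 1%
of its peak, i.e. hard-cut at radius σ√(−2 ln 0.01); this bounds each
bead's voxel support (the force stencil) and is applied per Gaussian,
not to the summed map. ρ^calc is always synthesized on the target map's
lattice — required for the voxel-wise CC sum — and is recomputed every
integration step by default (configurable cadence).

The bias is V_EM = k(1 − CC); its force k·∂CC/∂r_b is analytic:

    ∂CC/∂r_b = Σ_v [ t_v/√(B·C) − (A/(√B·C^{3/2})) c_v ] · g_b(v) (x_v − r_b)/σ²

with A = Σ t·c, B = Σ t², C = Σ c², verified against central finite
differences to ~1e-9 relative (away from the truncation sphere, where a
hard-truncated model is legitimately non-differentiable). Beads whose
support misses the grid feel zero bias force. CC is computed over the
full grid with no masking. Experimental maps are clamped to non-negative
values before use, after which CC ∈ [0, 1].

MRC/CCP4 maps are read through gemmi with the axis order normalized to
x,y,z from the file's MAPC/MAPR/MAPS mapping; the ORIGIN record is
preferred, falling back to NCSTART × spacing; voxel values sit at voxel
centers. Maps are written as mode-2 float32. The Situs ASCII format is
read and written directly (it is a seven-number header plus values).

## Dynamics

Velocity Verlet with SHAKE on the pseudo-bonds (Gauss–Seidel iteration,
tolerance 1e-8 Å, verified to hold every bond within 1e-6 Å of native
length over 10⁴-step runs) and a RATTLE velocity projection. Temperature
is controlled by the Berendsen weak-coupling rescale, default coupling
time 0.2 ps. Defaults mirror the regime the method targets: dt = 20 fs,
200 K, 20 Å pair cutoff. Initial velocities are Maxwell–Boltzmann with
net linear and angular momentum projected out (standard for in-vacuo
simulations; without it the molecule drifts off the density grid).
No random numbers are drawn during integration, so trajectories are
bit-reproducible on one platform given the velocity seed.

## Replica exchange over force constants

The default ladder is the 32-value series 500…5000 kcal/mol; reduced
ladders are geometric over the same range. All replicas share β (same
temperature). Every exchange period (default 2 ps = 100 steps) adjacent
ladder slots attempt swaps with alternating even/odd pairing; the
Metropolis rule on Δ = β(k_n − k_m)(CC_j − CC_i) exchanges the force
constants, not the coordinates, so each trajectory is continuous. For
frozen CCs the induced chain on k-assignments provably targets
P(π) ∝ exp(β Σ k_slot CC_π(slot)); the test suite verifies this
stationary distribution by χ² against exact enumeration, and verifies
empirical acceptance frequencies against the closed-form w. The best
model is the globally highest-CC frame across replicas (earliest frame
wins ties). Disabling exchange reproduces independent fixed-k runs
bit-identically.

## Targeted MD

The restraint is a stiff harmonic ½K(RMSD − ρ_t)² on the best-fit
(Kabsch-superposed, mass-unweighted) RMSD to the reference — an
internal-coordinate restraint, insensitive to rigid motion — rather than
an exact Lagrange constraint; its contract (tracking the schedule within
tolerance) is directly testable and the realization is numerically
simpler. ρ_t decreases by Δρ = Δt(ρ₀ − ρ_f)/T each step, clamped at
ρ_f. The force on bead i is −K(RMSD − ρ_t)(r_i − r_{F,i})/(N·RMSD),
exact at the superposition optimum where the rotation's derivative
vanishes. Defaults K = 2×10⁴ kcal/mol/Å², dt = 10 fs, ρ_f = 0.1 Å over
100 ps were calibrated on the hinge-toy fixtures so the final RMSD lands
within 0.1 Å of ρ_f against the Go forces pulling back toward the
native state; K trades schedule fidelity against stiffness (the
effective per-bead frequency scales as √(K/N), so very stiff restraints
need the smaller step). After the run the structure is rigid-aligned
onto the target and translated so the Cα centers of mass coincide
exactly.

## Protocol orchestration

Step 1 runs `n_runs` independent REUSfit simulations and keeps the
highest-CC model of each (M1, up to `n_best`). Step 2 targets the
initial structure to each M1 (no map). Step 3 refines each M2 at a fixed
force constant, default the ladder median, for the same trajectory
length class as one step-1 replica segment; models are ranked by CC
(M3). The simple protocol runs `simple_n_replicates` fixed-k fittings
from the initial structure. All stages write models with provenance
(stage, seed, k at capture, frame) to a run directory; re-invocation
with an identical configuration (SHA-256 digest of the config) reuses
completed stages. Every step here operates at Cα resolution with the Go
model — including steps 2 and 3, which in the original formulation are
all-atom stages — so the pipeline demonstrates the protocol logic, not
all-atom side-chain refinement. Configuration is YAML mapped onto a
typed dataclass with explicit units in key names; unknown keys are
rejected.

## Synthetic test system

The hinge toy is two ideal Cα helices (rise 1.5 Å/residue, radius
2.3 Å, 100°/residue), 15 residues per arm by default, joined so the
junction Cα–Cα distance equals the helical step (≈3.83 Å) for any hinge
angle; the two states differ only by that angle (defaults 150° vs 90°,
initial best-fit RMSD ≈ 4.5 Å — comparable to the easier end of real
open/closed transitions). Residue types cycle through a fixed
hydrophobic/polar decad so contact weighting is exercised. What it
shares with real systems: a genuine two-state hinge transition, native
contacts resisting the move, a medium-resolution (5 Å, 2 Å voxel)
target map with a known answer. What it lacks: tertiary-domain
complexity, map noise and anisotropy, symmetry-induced density
degeneracy, and size (30 vs 10³ residues) — so passing end-to-end tests
demonstrates correctness and the qualitative protocol contrasts
(exchange lowers run-to-run variance; the three-step protocol matches or
beats the single-run baseline), not performance on experimental data.

Scaled-down study conditions used by the tests and the acceptance
script: 8-constant geometric ladder (500–5000 kcal/mol), 2.5×10⁴ steps
per replica (2×10⁵ integration steps per run), exchanges every 100
steps, dt = 20 fs at 200 K; the baseline gets a 4.5×10⁴-step single
trajectory, matching the length of the longest multi-scale trajectory
chain. These sizes were chosen so the whole suite runs on one CPU in
minutes while leaving the protocol contrasts clearly resolvable.

## Numerical details and edge cases

- Kabsch superposition via SVD with determinant correction (proper
  rotations only); near-collinear point sets (second singular value
  < 1e-8 of the first) are rejected as degenerate.
- RMSD is mass-unweighted over the selected beads by default; weights
  are available. Residue pairing between structures uses (chain, residue
  number, insertion code); unmatched residues are excluded.
- PDB altloc handling keeps the highest-occupancy variant; HETATM
  records are ignored.
- Best-model ties break toward the earliest frame, making outputs
  deterministic.
- exp(−Δ) underflows to exactly 0 for very large Δ; this is the correct
  limit of the acceptance rule.
- Coincident beads (pair distance < 1e-6 Å) and non-finite forces abort
  a run with a diagnostic rather than propagating NaNs.
- Hard Gaussian truncation makes CC only piecewise-smooth; finite
  difference checks therefore exclude configurations with a voxel center
  within 10 h of a truncation sphere.

## Known limitations

- No all-atom force field or implicit solvent: steps 2 and 3 run on the
  Cα Go model. Side-chain placement and hydrogen bonding are out of
  scope, as are external validation scores (MolProbity, CaBLAM,
  Ramachandran) and secondary-structure assignment itself (DSSP strings
  are consumed, not computed).
- No rigid-body docking: the initial structure must already be placed in
  the map (the pipeline superposes initial onto target when a target
  structure is supplied).
- CC is real-space over the full grid; no masking, Fourier-space
  matching or local-resolution handling.
- The Berendsen thermostat does not sample a canonical ensemble exactly;
  it matches the method's intended use (driven fitting, not equilibrium
  thermodynamics).
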