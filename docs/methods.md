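# Methods

This note documents the models, numerical choices and limitations of
`glycodock`.  It is written for users who want to know what the toolkit
actually computes, which knobs matter, and what the passing test suite
does and does not demonstrate about real protein–glycan systems.

## Ambiguous interaction restraints

Interface information enters as ambiguous interaction restraints (AIRs).
Residues are split into *active* (restrained to be at the interface;
penalized when they are not) and *passive* (allowed to satisfy a partner's
restraint but never penalized themselves).  Two scenarios are built in:

* **ti-aa** — the true interface (all residues with a heavy atom within
  3.9 Å of the partner in the reference complex) is active on both
  partners; each active residue anchors one AIR whose targets are the
  partner's active set.
* **tip-ap** — the protein interface is active, and *every* glycan residue
  is passive; AIRs are anchored on the protein only, each targeting the
  whole glycan.

The restrained quantity is an effective distance between the anchor
residue's heavy atoms and the pooled heavy atoms of all target residues,

    d_eff = ( Σ_ij d_ij^-6 )^(-1/6),

the standard r⁻⁶-sum aggregation for ambiguous restraints: d_eff is always
below the closest pair distance and approaches it when a single pair
dominates, so the restraint is satisfied by contacting *any* target.  The
restraint energy is a flat-bottom function: zero inside
[lower_bound, upper_bound] (defaults 0 and 2.0 Å), harmonic `k·v²` for
violations `v` up to a switch point (1.0 Å), then linear with matched value
and slope — bounded forces, which keeps minimization stable.  The force
constant defaults to 50 kcal/(mol·Å²).  These three numbers are
conventions, not fitted values, and are fully configurable; note that with
the default 2.0 Å upper bound a residue-level AIR is typically *not*
reducible to zero energy at vdW contact (d_eff at a real interface sits
around 2.5–3.5 Å), which is fine — the restraint still ranks closer poses
lower and its gradient points into the binding site.

Per generated model, 50% of the AIRs are randomly discarded (independently
per model, deterministically per model seed), emulating false positives in
experimental interface data.

## Energy model and scoring

Five terms are computed over heavy atoms only (hydrogens are parsed but
ignored throughout):

* **E_vdW** — 12-6 Lennard-Jones with Lorentz–Berthelot combination.
* **E_elec** — Coulomb with a constant relative permittivity ε_r = 10.
* Both nonbonded terms use an 8.5 Å cutoff with a cubic switching function
  over the last 1.5 Å (smooth value and gradient at the cutoff).
* **E_BSA** — buried surface area, SASA(A) + SASA(B) − SASA(AB), from an
  in-package Shrake–Rupley implementation (Fibonacci sphere sampling;
  960 points per atom by default, 240 inside pipelines where speed
  matters — the BSA sampling error at 240 points is well under 2%).
* **E_desolv** — empirical desolvation: Σ over atoms of an atomic
  solvation parameter times the SASA lost on complex formation.
* **E_air** — the restraint energy above.

Nonbonded parameters come from a compact built-in table keyed by a simple
atom-class typer (element level, with a carbonyl/hydroxyl oxygen split and
an element fallback).  The table is deliberately small and user-overridable:
the toolkit is self-contained rather than tied to a full force-field
distribution, and the fixtures are pseudo-chemical anyway (see below).

Stage presets for the weight vector (w_vdW, w_elec, w_desolv, w_BSA, w_air):

| stage         | w_vdW | w_elec | w_desolv | w_BSA | w_air |
|---------------|-------|--------|----------|-------|-------|
| rigid-default | 0.01  | 1.0    | 1.0      | −0.01 | 0.01  |
| rigid-vdW     | 1.0   | 1.0    | 1.0      | −0.01 | 0.01  |
| flexref       | 1.0   | 1.0    | 1.0      | 0     | 0.1   |

BSA carries a negative weight at the rigid stage so burial is rewarded
(the score is minimized).  Every coefficient is exposed in configuration;
the presets follow the established convention for this scoring family.

## Rigid-body docking

Each model starts from a uniformly random ligand orientation (quaternion
from four normal deviates) placed on a random direction from the receptor
at the sum of the two bounding radii plus 3 Å, so starts are clash-free.
Minimization is over the six rigid degrees of freedom and proceeds in two
phases: a deterministic *approach scan* (60 samples of the translation
along the line toward the receptor centre, keeping the best) followed by
three Nelder–Mead passes with shrinking initial simplexes (0.4 rad / 2 Å,
0.1 rad / 0.5 Å, 0.03 rad / 0.15 Å; 300 iterations total by default).
Direct search was chosen over analytic gradients deliberately: it is
robust to the switched potentials and trivially correct, and at desk scale
(≲ 250 heavy atoms) each energy call is a single vectorized pair sum.
The minimization objective is `w_air·E_air + w_vdW·E_vdW + w_elec·E_elec`;
the surface terms (BSA, desolvation) are noisy per-step and are computed
once on the final pose for scoring.  Model generation is embarrassingly
reproducible: every model derives its own seed (restraint discard + start
pose) from the run seed.

## Semi-flexible refinement

The refinement stage stands in for torsion-angle simulated annealing with
**two-stage restrained Cartesian minimization** — a declared protocol
approximation.  Stage 1 frees the glycan and the side chains of receptor
residues within 5 Å of the ligand; stage 2 additionally frees their
backbone.  The objective adds to the flexref energy terms stiff harmonic
restraints on bond lengths (k = 1000 kcal/(mol·Å²)) and on 1–3 distances
(k = 200), both toward their starting values; the 1–3 restraints play the
role of angle restraints (identical to second order for small
displacements) while keeping gradients trivial.  Minimization is L-BFGS
with analytic gradients, 500 function evaluations per stage by default;
a stage is accepted only if it lowers the objective.  Sugar rings stay
closed by construction (ring bonds are bonds).  If any bond stretches by
more than 0.5 Å the refinement is rejected and the input model is returned
flagged.  Non-flexible atoms are never touched.  Intra-receptor nonbonded
interactions are carried entirely by the geometry restraints (the
pseudo-residues of the fixtures are not covalently linked to each other);
intermolecular and intra-ligand pairs beyond three bonds feel the full
LJ + Coulomb terms.

## Clustering and model selection

Pairwise model distances are heavy-atom RMSDs over a scenario-matched
selection — all interface residues for ti-aa, protein interface plus whole
glycan for tip-ap — after pairwise Kabsch superposition on that same
selection (superposition-free mode is available when all models share the
receptor frame).  Clustering is agglomerative with average linkage, cut
either at 2.5 Å (bound stage, post-refinement stage) or into a requested
number of flat clusters (50 after rigid docking; 150 for ensemble runs).
Clusters below 4 members are dropped from reporting but retained in an
unclustered pool.  Clusters are ranked by the mean score of their best 4
members (ties → lower cluster id), and the top 5 models of every cluster
feed the refinement stage; a "classical" mode that refines the top 200
models overall is also provided.  Tie-breaking everywhere is stable by
(score, model id), which together with per-model seeds makes entire runs
byte-identical across repeats.

## Model quality and success rates

IL-RMSD fits on the backbone heavy atoms of the reference protein
interface (3.9 Å heavy-atom rule, evaluated on the reference complex) and
measures on the glycan heavy atoms without re-fitting; it is invariant to
joint rigid motion of the model and sensitive to glycan placement, which
is the point — a protein-dominated interface RMSD would hide a misplaced
trisaccharide.  Tiers are inclusive: ≤1.0 high, ≤2.0 medium, ≤3.0
acceptable, ≤4.0 near-acceptable.  The fraction of native contacts is
deliberately not implemented: for small ligands it saturates and cannot
resolve near-native differences.  Success rates are cumulative (a high
model also counts as medium/acceptable/near); the cluster-based variant
assigns each cluster the best tier among its top 4 members (top 5 at the
rigid stage, matching the selection size there).  Note the near-acceptable
tier is generous for di/trisaccharides — a 4 Å displacement of a
disaccharide is most of its diameter — so short-glycan headline numbers
should be read from the ≤3 Å tiers.

## Conformer presampling

Unbound glycan ensembles are generated by perturbing the glycosidic
dihedrals: for each linkage, rotations about the anomeric-C→O bond (φ) and
the O→accepting-C bond (ψ) by Gaussian deviates of width 20°·√effort,
applied to the subtree distal from the reducing-end residue; rings are
rigid.  Members with internal clashes (heavy-atom pairs of non-adjacent
residues under 2.2 Å) are relaxed by a short restrained minimization
(soft repulsion + the bond/1–3 restraints) and resampled if the clash
persists.  This torsion-space sampler replaces solvated molecular-dynamics
refinement used in heavier pipelines; the `effort` multiplier (default 16
with 400 members, the heaviest preset) controls spread, and the ensemble
median pairwise RMSD grows monotonically with it.  Ensembles are reduced
to 20 cluster centers (average-linkage RMSD clustering; the center is the
member with minimal mean RMSD to its cluster), which become the starting
conformations for ensemble docking at 200 models per conformation.  The
reduction loses information one-sidedly: the best center is never closer
to the bound conformation than the best raw member.

## The synthetic fixtures, and what tests do (not) show

The fixture generator builds toy complexes from idealized chemistry:
glycans are chains of 2–7 hexagonal pseudo-pyranose rings (C1–C5 + ring O,
exocyclic O1/O2/O4) joined by C1→O4 glycosidic contacts at 1.43 Å, with an
optional O2 branch (a degree-3 unit; a graph-branched glycan needs ≥ 4
units, since any 3-residue linkage tree is a path); receptors are concave
cradles of pseudo amino acids (N/CA/C/O backbone plus CB/CG side chain)
wrapped around the glycan's lower hemisphere with side-chain tips ~3.5 Å
from its surface.  Bound poses are guaranteed to have ≥ 3 interface
residues at 3.9 Å and no contact below 2.2 Å.  Decoys apply a screw motion
amplitude-bisected to a requested IL-RMSD (±0.1 Å), optionally redrawing
the axis until a genuine steric clash is planted.

These fixtures test *mechanics* — restraint math, energy sums, pose
search, clustering, bookkeeping, reproducibility — under a smooth,
funnel-shaped landscape with an unambiguous native pose.  Passing them
does **not** demonstrate accuracy on real complexes: real glycans have
stereochemistry, intramolecular hydrogen bonds and solvent effects the
pseudo-chemistry lacks; real binding sites have competing pockets and
conformational change; and the compact parameter table is not a fitted
force field.  The toolkit can be pointed at real PDB files (the
monosaccharide catalogue covers common pyranose codes and is extensible),
but benchmark-scale accuracy claims require benchmark-scale data and
compute, which are outside this package's scope.

## Problem sizes and determinism

Default pipeline sizes (1000 rigid models, 500 refinement evaluations per
stage, 960 SASA points) suit production runs; the shipped tests and the
acceptance script use reduced sizes (200 models for recovery checks,
12–40 minimizer iterations in bookkeeping checks, 240 or 120 SASA points)
chosen so the full suite exercises every stage in minutes on one CPU.
All stochastic components — starts, discards, decoy axes, perturbations —
draw from seeds derived from a single run seed via `numpy.random.
SeedSequence`, so every table the workflows write is byte-identical across
repeated runs with the same configuration.
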