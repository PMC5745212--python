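# Methods

This note records the models implemented in `hawkrank`, the numerical
choices behind them, what the synthetic fixtures do and do not emulate, and
the known limitations.

## Scoring model

A docked pose of a binary protein-protein complex is scored as a weighted
sum of five interface energy terms,

    score = w1 ΔE_vdw_attr + w2 ΔE_vdw_repu + w3 ΔE_elec_attr
          + w4 ΔE_elec_repu + w5 ΔE_pdsol ,

with lower scores marking better poses.  Only intermolecular (receptor to
ligand) atom pairs contribute; the partners are rigid, so intramolecular
energies are constant and never computed.  The shipped default weights are
the published trained values (0.850, 0.0005, 1.887, 1.853, 0.9303).

**Van der Waals.**  A softened 6-12 form with σ_ij the sum of the two
atoms' rmin/2 values and ε_ij the geometric mean of their well depths.
For 0.89 σ_ij ≤ r_ij < 12 Å the classical well
ε_ij[(σ/r)^12 − 2(σ/r)^6] accumulates into the attractive sum; for
r_ij < 0.89 σ_ij a linear ramp 10 (1 − r/0.89σ) accumulates into the
repulsive sum.  The boundary r = 0.89 σ goes to the attractive branch
(the repulsive branch is defined by a strict inequality).  The piecewise
form leaves a small jump of ≈ 0.024 ε_ij at the switch; this is a property
of the published functional form and is asserted, not smoothed away.

**Electrostatics.**  Bare Coulomb, E = 332 q_i q_j / (ε r_ij) with ε = 1.
Pairs with E < 0 accumulate into the attractive sum, all others (including
exactly zero) into the repulsive sum, so the two sums always reconstruct
the unsplit Coulomb total.  The 12 Å cutoff is stated only for the vdW
term; by default electrostatics shares the same pairlist (a single-pass
implementation), and `--elec-no-cutoff` / `elec_cutoff=False` evaluates
every cross pair instead.  This default is a package decision; the choice
is logged at run time.

**Polar desolvation.**  A linear surface model predicts the polar
component of a structure's solvation free energy,

    psol = w0 N_res + Σ_{i=1..21} w_i SASA_i + constant   (kcal/mol),

and the desolvation of a pose is psol(complex) − psol(ligand) −
psol(receptor).  Applied literally this leaves a zero-contact pose at
−constant rather than 0 (the surface and N_res terms cancel exactly when
nothing is buried); a `cancel-intercept` option adds the constant back.
The default keeps the printed formula; the intercept is common to every
pose of a case and never changes a ranking.

## Surface model

SASA is computed with a deterministic Shrake-Rupley procedure: each atom's
expanded sphere (vdW radius + probe) is sampled with a generalized-spiral
(Fibonacci) lattice of 960 points (configurable; results move by < 0.5%
beyond 960), and a point is accessible when it clears every neighbour's
expanded sphere.  The probe radius is 0.6 Å — deliberately smaller than
the 1.4 Å water probe, matching how the solvation model was parameterized —
and hydrogens carry radii and surface like any heavy atom.  Element radii
are Bondi values: H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 Å.

Each atom's lattice is oriented by a local frame built from the principal
axes of its neighbour displacement vectors (signs fixed by third moments).
Because the frame co-rotates with the structure, areas are invariant under
rigid motion to numerical precision and exactly additive for separated
bodies; a fixed laboratory lattice would leave an orientation-dependent
sampling residue of order 0.5 Ų per atom.  For atoms with degenerate
neighbour geometry (a single neighbour, or a symmetric cage) the burial
pattern is itself symmetric about the resolved axes, so the ambiguity is
harmless.

**Atom typing.**  Every atom of the 20 standard amino acids maps to one of
21 solvation atom types.  The classification is evaluated from packaged
per-residue bond lists — sp3 vs sp2 carbons, carbons attached to exactly
one oxygen vs two, ring membership by cycle detection, hydrogens classified
by their bonded heavy atom — never from 3-D geometry, so typing is total,
single-valued, and conformation independent (asserted exhaustively over a
peptide containing all twenty residues).  Histidine is typed and charged as
the neutral ε-tautomer; terminal residues are recognized from their
protonation state (ammonium hydrogens, OXT) and use terminal parameter
variants.

**Solvation coefficients.**  The per-residue weight w0 = −10.51 and the
intercept 59.78 kcal/mol are the published fitted values.  The 21 per-type
surface coefficients shipped as defaults are package calibration values
chosen on physical grounds (charged oxygens and nitrogens strongly
negative, polar types moderately negative, apolar carbon/hydrogen near
zero); for quantitative use they are meant to be refit with `fit_weights`
against a user's polar-solvation target set (e.g. continuum-electrostatics
energies for a protein collection).  Fitting is ordinary least squares on
the 23-column design (N_res, 21 type sums, intercept) over a seeded 50/50
train/test split, with no regularization; a rank-deficient design is an
error that names the collinear columns.  On noiseless synthetic data the
fit recovers planted coefficients to better than 1e-6.

## Force-field parameters

LJ parameters use Amber-style atom classes with their standard
(rmin/2, ε) values.  Partial charges are ff14SB-style point charges; at
load time each residue's charges are renormalized exactly onto the
residue's formal charge (the residual, typically < 0.05 e, is folded into
CB, or CA where no CB exists), so per-residue sums are exact by
construction.  The hydroxyl hydrogen keeps a zero well depth; its rmin/2
is set to a small positive value purely to satisfy the positivity
contract, and contributes nothing because ε_ij = 0.

## Evaluation statistics

L_RMSD is the Cα RMSD of the ligand after least-squares (Kabsch)
superposition of the receptors; I_RMSD is the Cα RMSD over the interface
residues of the *native* complex (any atom within 10 Å, inclusive, of the
other partner) after superposing those interface Cα sets.  Cα atoms pair
by (chain, residue number, insertion code); unpaired residues are dropped
with a warning, and fewer than three pairs is an error.  A decoy is a hit
when L_RMSD < 10 Å or I_RMSD < 4 Å.

The success rate SR(N) is the fraction of cases with at least one hit in
the top N.  The modified success rate scores one case as

    F = Σ_{hits j in top N} (1 + 1/rank_j) / HIT ,

where HIT is the case's hit count over the *full* considered decoy list —
this makes F penalize functions that bury most of a case's hits below the
cut, which is the statistic's purpose — and Y averages F over cases.
Cases with no hit anywhere are excluded with a warning, mirroring how
benchmark cases without reachable hits are eliminated.  Perfect ranking
(hits at ranks 1..HIT) attains the closed form Σ(1 + 1/j)/HIT, asserted
against direct evaluation.

## Weight training

The five weights are trained by a real-coded genetic algorithm under box
bounds [0, 3] for four weights and [0, 0.001] for the vdW-repulsive weight
(kept deliberately tiny because the linear clash ramp is a blunt
instrument).  Defaults follow the published setup where stated: population
200, 1500 iterations, elitism keeping ⌈20%⌉ of the population.  The
operators are package decisions: tournament selection (size 3), BLX-0.5
blend crossover, Gaussian mutation (probability 0.2, σ = 5% of each
range) clipped to bounds.  The objective is not stated in the original
description; the default here is the Y statistic at N = 500 on the
training cases, selectable (`sr`, `mrr`).  Energy vectors are precomputed
per decoy, so a candidate weight vector only reweights cached five-term
vectors; training is seeded and bitwise reproducible, and best-so-far
fitness is non-decreasing by elitism.  On a planted benchmark (20 cases x
200 decoys whose hits are exactly the best decile under the published
weights) the GA reaches ≥ 99% of the planted weights' fitness within 200
generations — weights need only be rank-equivalent, not numerically equal.

## Synthetic fixtures

Toy proteins use real residue and atom names (so typing and parameter
tables are exercised authentically) on idealized geometry: Cα traces on an
extended strand, an α-helix (2.3 Å radius, 1.5 Å rise, 100°/residue), or a
seeded 3.8 Å random walk, with side-chain and hydrogen positions laid out
from the bond topology at bonded-scale distances.  Decoy sets apply seeded
random rigid perturbations of scheduled magnitude to the ligand and report
the reference L_RMSD analytically from the applied transform (the receptor
never moves), giving an oracle independent of the evaluation module.
Solvation datasets evaluate a planted linear surface model on diverse toys
plus Gaussian noise.

What the toys do *not* emulate: real packing density, charge
complementarity at interfaces, realistic secondary structure, or the
near-clash-free pose distributions a shape-complementarity sampler
produces.  Passing tests therefore demonstrate the arithmetic,
conservation, invariance and recovery properties of each stage — not
benchmark-level ranking performance on real complexes, which requires real
decoy sets.

Problem sizes used by the test-suite and the acceptance script — toys of
6-20 residues (150-350 atoms), decoy sets of 16-60 poses, solvation
datasets of 60-200 structures, GA runs of 200 generations — were chosen so
every stage runs in seconds to a few minutes while leaving each statistic
comfortably away from its tolerance.

## Known limitations

- With the published weights, the attractive electrostatic weight exceeds
  the repulsive one by 0.034, so any pose is rewarded by ~0.034 x its total
  Coulomb magnitude.  Poses that interpenetrate deeply (sub-Å cross-partner
  contacts) therefore *outrank* the native: the function has essentially no
  clash penalty (w_vdw_repu = 0.0005) and relies on its decoys coming from
  a sampler with excluded volume.  The pipeline test uses grossly
  misplaced decoys from the generator's heavy perturbation schedule, which
  is what such samplers actually emit when they are wrong.
- The desolvation term always favours separation within a case's terms
  (burial of surface with negative coefficients raises psol); binding
  affinity comes from the vdW/electrostatic attraction terms.  This is a
  property of the published linear form.
- Only binary complexes of the 20 standard residues are supported; no
  cofactors, modified residues, nucleic acids, or protonation assignment
  (inputs are expected protonated; a warning fires below 25% hydrogen).
- The interface-area percentage uses this package's SASA conventions
  (probe 0.6 Å, hydrogens included) and is not numerically comparable to
  web services that use a 1.4 Å probe on heavy atoms.
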