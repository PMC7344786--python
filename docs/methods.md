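# Methods

## The problem and the approach

Assigning the relative configuration of a small organic molecule with *n*
stereogenic centers from NMR data classically requires building and
evaluating all 2^(n-1) diastereomers.  This package implements the
floating-chirality restrained distance-geometry / distance-bounds-driven
dynamics approach (fc-rDG/DDD), in which configurations are *not* enumerated:
structures are generated from interatomic distance information alone, chiral
volume restraints are deliberately omitted on all unknown stereocenters and
prochiral CH2 groups, and the relative configuration emerges from the
experimental restraints in a single calculation.  The only inputs are the
molecular constitution (with an arbitrary-configuration 3D reference
geometry used solely to measure bond lengths, angles, torsion extremes and
chiral-volume magnitudes), NOE/ROE-derived interproton distance bounds, and
optionally one or more residual dipolar coupling (RDC) data sets measured in
different alignment media.

## Pseudo-energy force field

All restraints enter one dimensionless penalty function

    E_total = E_dist + E_chir + E_NOE + E_RDC + E_DBL,

with every term a harmonic sum of squared violations, E_X = 1/2 K_X
sum (Delta X)^2.  No physical force-field terms (bond, angle, van der Waals,
electrostatics) exist anywhere: a zero pseudo energy means "all restraints
satisfied", nothing more.

* **E_dist** - holonomic bound violations over all atom pairs.  Bounds come
  from the constitution: 1,2 and 1,3 distances at the reference value +-1%,
  1,4 distances spanning the syn/anti torsion extremes (computed
  analytically from reference bond lengths and angles, widened by 1%),
  pairs in aromatic rings pinned at +-1%, and all remaining pairs bounded
  below by hard-sphere radii (0.8 x sum of per-element radii; H 1.0, C 1.5,
  N 1.4, O 1.3, S/Cl 1.7, Br 1.8 A) and above by the bond-path-length sum.
  Bounds are triangle-smoothed (shortest-path uppers, inverse-triangle
  lowers) before use.  K_dist = 25 A^-2 (package default, reported in run
  metadata).
* **E_chir** - squared deviations of signed chiral volumes
  V = a.(b x c) from their targets.  Restraints exist only on (i) one
  user-chosen stereocenter, to exclude the global enantiomer, with the
  target taken from the reference geometry; (ii) every 3-coordinate sp2
  center, target 0 (planarity); (iii) every CH3 carbon (kept tetrahedral).
  All other stereocenters and all CH2 groups float.  K_chir = 25 A^-6
  (package default).
* **E_NOE** - piecewise violations (zero inside [r_lower, r_upper], linear
  outside) of back-calculated interproton distances; unassigned
  CH2/CH3/equivalent-proton groups are compared as <r^-6>^(-1/6) averages
  over all group proton pairs.  Bounds from experiment are r_mean +-10% by
  default.  K_NOE = 10 A^-2.
* **E_RDC** - squared deviations D_exp - D_calc in Hz.  Back-calculation is
  parameter-free: D = d_max(r) u^T S u with d_max from natural constants at
  the instantaneous C-H bond length, u the unit bond vector and S the
  traceless symmetric alignment tensor of the medium.  The five independent
  tensor elements per medium are refit by (SVD-based) linear least squares
  at every energy evaluation; because the fitted tensor is the minimizer,
  differentiating with the tensor held fixed gives the exact gradient of
  the tensor-minimized energy.  Methylene couplings can enter as unassigned
  sums D(Ha)+D(Hb) (one row, one restraint).  K_RDC = 1.5/M Hz^-2 for M
  media.
* **E_DBL** - conjugated-bond planarity: Delta = 1 - cos^2(phi) over every
  torsion with an sp2-sp2 central bond; K_DBL = 100.  This keeps double
  bonds and aryl rings planar while leaving the cis/trans choice free.

Gradients of every term are analytic (in 3D and 4D) and are verified against
Richardson-extrapolated central finite differences in the test suite.

## Structure generation pipeline

Per structure (one child seed per structure, spawned from the master seed):

1. **Partial metrization** - 4N randomly ordered pairs are drawn uniformly
   within their current bounds; after each draw the bounds are re-smoothed
   through the fixed pair; remaining distances are set to the midpoints.
   Sampling distances rather than coordinates makes every relative
   configuration reachable - the engine of floating chirality.
2. **4D embedding** - classical metric-matrix (Gram) embedding into the
   four largest non-negative eigendirections; negative eigenvalues truncated.
3. **4D annealing** - velocity-Verlet dynamics (unit masses) with per-step
   velocity rescaling to T(t): equilibration at 300 K, then a linear ramp to
   0 K (defaults 5000 + 5000 steps of 2 fs).  Interatomic distances use all
   four coordinates; chirality, planarity and RDC terms are evaluated on the
   leading three, so a configurational inversion is a barrier-free rotation
   through the fourth dimension.  A restoring force -f(T) k_w w with
   f(T) = exp(-(T/tau_T)^2), tau_T = 150 K, k_w = 1 A^-1 acts on the
   centered fourth coordinate, compressing the structure smoothly into the
   3D subspace the restraints live in as it cools.
4. **4D quench** - each annealing stage ends with a gradient minimization;
   the 4D one runs under the compression potential at stiffening strength
   (5x, 50x, 500x k_w) with the 3D-subspace terms ramping in alongside
   (weights 0.1, 0.5, 1.0), so the fourth dimension is empty - and the
   3D-subspace restraints fully engaged - before projection.  During both
   annealing stages the stiffest terms are temperature-ramped with the same
   f(T) factor: in 4D the chirality/planarity/RDC terms (meaningless on the
   3D projection of a hot, 4D-extended structure), in 3D the RDC term alone
   (its Hz^2 curvature otherwise traps the conformational search before the
   distance terms have folded the molecule); everything is at full strength
   from the end of cooling onward.  Per-atom force norms are clamped at 100
   during dynamics only.
5. **Projection** - removal of the coordinate along the largest-eigenvalue
   inertia-tensor eigenvector (the direction of least extent; this choice
   minimizes the summed squared-distance distortion).  A 3D slice of a 4D
   object has no intrinsic handedness until the dropped axis is oriented;
   the single fixed chiral restraint pins that gauge - if the projection
   lands on the wrong enantiomer of the fixed center, the mirror image is
   taken.
6. **3D annealing** and **final minimization** (L-BFGS-B on the analytic
   gradient; monotone by line-search construction; default gradient
   tolerance 1e-6, step cap 10,000 for the standalone operation, 1e-3/3000
   within the pipeline where the ranking only needs ~1e-2 energy
   resolution).

Structures that blow up numerically restart once with half the time step and
are otherwise flagged failed and excluded from ranking (never silently
regenerated).

## Ranking and diagnostics

Minimized structures are sorted by ascending E_total (ties broken by seed).
Each gets a configuration fingerprint: signs of the chiral volumes at every
floating stereocenter and every prochiral CH2 (substituents in fixed
index-sorted order; |V| < 0.01 A^3 is flagged degenerate and excluded from
class statistics).  Stereocenter signs define the configuration class;
prochiral signs are tracked separately, so a wrong CH2 proton assignment
("pseudo-configurational" change) is never confused with a wrong
diastereomer.  The report contains the class partition, the rank of the
first wrong-class structure, the pseudo-energy gap between the best
structures of the reference class and of any other class, and a per-center
confidence table (majority sign in the lowest-energy decile plus the energy
gap to the best opposite-sign structure; banded green >= 1.0, amber >= 0.3,
red below - heuristic thresholds, configurable).

## Internal unit conventions

The pseudo energy is dimensionless, so the dynamics needs two conventions
(package constants, logged in run metadata): the Boltzmann factor
KB = 0.1 pseudo-energy units per Kelvin (per-dof kinetic energy 15 at
300 K - an order of magnitude above single-restraint violation energies, so
equilibration crosses fold-defect barriers), and 1 fs = 0.01 internal time
units (a 2 fs step then resolves the stiffest restraint modes).  Per-atom
force norms are clamped at 100 during dynamics only: RDC terms are stiff in
Hz^2 and would otherwise destabilize the integrator on the badly violated
structures that exist early in annealing; minimization is unclamped.

## Class-floor refinement in the benchmarks

The class-gap statistics of the benchmark experiments compare *minimum*
pseudo energies per configuration class.  At benchmark problem sizes the
raw per-structure energies carry optimization scatter comparable to small
class gaps, so the benchmarks refine the ranked ensembles before measuring
gaps: the best few candidates of every class are deeply re-minimized;
the top candidates additionally get (i) re-annealing cycles under
*class-pinning* chiral restraints (temporary restraints holding the
candidate's configuration so the fold can re-explore without inverting -
floors are always evaluated on the unpinned model), (ii) basin hops
(perturb-minimize cycles), and (iii) cross-seeding: the globally
best-converged fold is lifted back into 4D and re-annealed under each other
class's pins, so all class floors descend from the same well-converged
conformation.  For the multi-medium gap curve, the refined folds are pooled
across media counts and re-minimized under every medium count's energy
model, making the per-M floors directly comparable.  The refinement is
class-symmetric throughout; it sharpens the floor estimates but never
favors the true class.

## Synthetic fixtures

The generator builds five molecules with known ground truth (RDKit ETKDG
embedding + MMFF optimization of an isomeric SMILES, aromatic rings
projected onto exact planes so the truth satisfies the planarity restraints
identically): two stereocenters on a chain (`chain2`), three on a ring
(`ring3`), four on fused rings (`fused4`), two benzylic centers 8 bonds
apart in a cyclophane-like macrocycle with two para-phenylene units
(`macrocycle2` - the rigid-but-remote topology of the curare alkaloid
class, where local NOEs cannot correlate the centers), and eight contiguous
centers on a fused polycycle (`pia8`, the pyrrole-imidazole-alkaloid
situation: 128 relative configurations with one center fixed).  NOE tables
contain every interproton contact <= 3.5 A as r_mean +-10% with CH2/CH3
groups unassigned; RDC tables are back-calculated from seeded random
alignment tensors (axial magnitude 1.2e-3, random rhombicity and
orientation - typical weak-alignment order of magnitude giving |D| up to
~30 Hz); optional multiplicative NOE noise and additive RDC noise (both off
by default: the study conditions are noise-free restraint sets, which make
recovery failures attributable to the method rather than the data).

What the fixtures deliberately do not emulate: spectral integration error
models, conformational ensemble averaging of NOEs/RDCs (restraints are
back-calculated from one rigid truth), vibrational corrections to d_max,
protons on heteroatoms (exchangeable), and the sheer size/proton-density of
real natural products.  Passing the recovery benchmarks therefore shows the
*machinery* is correct and discriminating under clean conditions, not that
any particular real data set is decidable.

## Benchmark problem sizes

The benchmark experiments (`fcdg.benchmarks`, used by the acceptance tests
and `scripts/acceptance.py`) run ensembles of 50-200 structures with
annealing schedules of 600-2000 steps per stage instead of the protocol
defaults (1000 structures, 5000+5000 steps): the fixtures are an order of
magnitude smaller than the natural products the full protocol is sized for,
and their recovery statistics are already stable at these lengths on one
CPU in minutes.  The `RunConfig`/CLI defaults remain the full published
protocol.

## Known limitations

* Partial metrization with midpoint completion can produce strongly
  non-Euclidean distance matrices for large rings; the 4D annealing stage
  absorbs this, but embedding quality (and hence the fraction of structures
  that converge to low energy) degrades with molecule size.
* The minimizer finds local minima; per-class energy minima are reliable
  only when the ensemble is large enough that several structures of each
  surviving class converge well.  The reported class gap is a sampling
  statistic, not a certified bound.
* RDC back-calculation assumes a single rigid conformer per structure and
  a per-medium tensor refit with no error model on D_exp; bootstrap error
  bars quantify restraint leverage only.
* Prochiral fingerprints use a fixed substituent-order convention; mapping
  signs onto CIP descriptors or Ha/Hb NMR labels is the user's
  responsibility.
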