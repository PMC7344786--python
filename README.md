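# fcdg — floating-chirality restrained distance geometry

`fcdg` determines the **relative configuration and conformation of small
organic molecules simultaneously** from NMR restraints — NOE/ROE-derived
interproton distances and (optionally) residual dipolar couplings (RDCs)
from one or more alignment media — in a **single calculation**, without
enumerating the 2^(n−1) diastereomers of a molecule with *n* stereogenic
centers and without any physical force field.

It is aimed at NMR spectroscopists and natural-product chemists who have a
constitution, a ROESY/NOESY-derived distance table, and possibly
CLIP/CLAP-HSQC couplings (¹T = ¹J + 2¹D) from aligned samples, and want to
know which relative configurations the data supports and how decisively.

## The method

Structures are generated by restrained distance geometry with
distance-bounds-driven dynamics (fc-rDG/DDD):

1. Holonomic distance bounds (bond lengths ±1%, angles, torsion extremes,
   hard-sphere contacts) are derived from the constitution using an input
   geometry of *arbitrary* configuration, then triangle-smoothed.
2. Trial structures are metrized (random distances inside the bounds) and
   embedded in **four dimensions**, where a configurational inversion is a
   simple rotation — so all relative configurations are sampled without
   barriers.
3. Simulated annealing (5000 equilibration + 5000 cooling steps of 2 fs,
   T = 300 K → 0) refines each structure against the dimensionless pseudo
   energy

   E_total = E_dist + E_chir + E_NOE + E_RDC + E_DBL,

   a pure sum of squared restraint violations (E_X = ½·K_X·Σ ΔX²; K_NOE =
   10 Å⁻², K_RDC = 1.5/M Hz⁻², K_DBL = 100). A temperature-dependent force
   f(T) = exp(−(T/τ_T)²), τ_T = 150 K, compresses the fourth dimension as
   the system cools; structures are projected to 3D along the
   largest-eigenvalue inertia axis, annealed again, and minimized.
4. Chiral-volume restraints V = a·(b×c) are applied **only** to one
   reference stereocenter (to exclude the global enantiomer), to sp²
   centers (V = 0) and to methyl groups. Every other stereocenter and every
   prochiral CH₂ *floats*: its configuration/assignment is decided by the
   experimental data alone.
5. Per medium, the alignment tensor is refit by SVD least squares at every
   step; RDCs are back-calculated from natural constants only.
6. The ensemble (default 1000 structures) is ranked by pseudo energy and
   partitioned into configuration classes; the report gives the rank of the
   first wrong-configuration structure, the energy gap between classes, and
   a per-center traffic-light confidence table.

## Worked example

Generate a synthetic test system with known ground truth (a trisubstituted
cyclohexane with three stereocenters and a noise-free NOE table), then run
the pipeline on it:

```sh
fcdg fixture ring3 demo --seed 1
# fixture ring3: 22 atoms, 3 stereocenters, 17 NOEs, true class +-|---
# wrote demo/config.yaml

fcdg run demo/config.yaml --seed 7
```

With `n_structures: 100` and a shortened schedule
(`schedule: {n_equil: 400, n_cool: 400}`) in `demo/config.yaml`, the run
takes under a minute and prints

```
structures: 100  failed: 0
best e_total: 0.0000  class: +-|---
first wrong structure: #19
class gap dE: 1.0157224199395296
```

meaning: the lowest-pseudo-energy structure satisfies every restraint
(E_total = 0) and carries the true relative configuration (`+-` over the two
floating stereocenters; the part after `|` tracks diastereotopic CH₂
assignments). The first structure with a *different* stereocenter
configuration appears only at rank 19, and the best wrong-class structure is
1.02 pseudo-energy units worse — with noise-free data, a decisive
assignment. The `demo/run/` directory contains the ranked CSV table
(per-structure energy breakdown, fingerprint, class), a JSON report (class
counts, first-wrong index, per-center confidence bands) and the ranked
multi-frame XYZ.

The same `run` command drives real data: an SDF of the constitution (any
configuration), an NOE table (`H7 H9 2.50` rows, bounds r_mean ± 10%), and
one RDC table per alignment medium (`C2 H8 T=148.0 J=140.0` or
`C5 H11 H12 D=7.2` for unassigned methylene sums).

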