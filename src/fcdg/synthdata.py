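"""Synthetic fixtures with known configurational ground truth.

Each fixture is a small organic molecule whose true geometry, true
configuration fingerprint and restraint tables are generated together, so the
whole pipeline can be exercised -- and its configurational recovery measured
-- without any external data.  The molecules mirror the structural classes of
interest for NMR configuration analysis:

==============  ============================================================
``chain2``      2 stereocenters on an open chain (2,3-dichlorobutane)
``ring3``       3 stereocenters on a cyclohexane ring
``fused4``      4 stereocenters on a fused bicyclic (hydrindane-like) core
``macrocycle2`` 2 allylic stereocenters 8 bonds apart (both ring paths)
                in a 16-membered macrocycle with two rigid trans-alkene
                units (the tubocurarine-like situation: locally rigid
                frames around remote centers that local NOEs cannot
                correlate, but global RDCs can)
``pia8``        8 contiguous stereocenters on a fused polycycle (the
                pyrrole-imidazole-alkaloid-like situation; 128 relative
                configurations with one center fixed)
==============  ============================================================

Geometries are idealized: built once per seed by RDKit ETKDG distance-
geometry embedding from an isomeric SMILES followed by MMFF optimization.
NOE tables list all interproton contacts up to a cutoff (default 3.5 A) as
r_mean -/+ 10% bounds, with CH2/CH3 protons kept unassigned (r^-6-averaged
groups); RDC tables are back-calculated from seeded random alignment tensors,
optionally with methylene sums only.  With zero noise the true geometry
satisfies every generated restraint exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import align
from .embed import Conformer
from .energy import ForceConstants, PseudoEnergy
from .molgraph import (
    DistanceBounds,
    MoleculeGraph,
    ReferenceGeometry,
    from_rdkit,
    holonomic_bounds,
    reference_chiral_volumes,
    smooth_bounds,
)
from .rank import ConfigFingerprint, fingerprint
from .restraints import NoeRestraint, RdcRestraint, RestraintSet

FIXTURE_SMILES = {
    "chain2": "C[C@H](Cl)[C@@H](Cl)C",
    "ring3": "C[C@H]1C[C@@H](Cl)C[C@H](O)C1",
    "fused4": "O[C@H]1CC[C@H]2CC[C@@H](C)[C@@H]12",
    "macrocycle2": "C[C@H]1/C=C/CCCCC[C@@H](C)/C=C/CCCCC1",
    "pia8": "O[C@H]1[C@H](C)[C@@H](O)[C@H](C)[C@@H]2[C@H](O)[C@@H](C)CC[C@@H]12",
}


@dataclass
class Fixture:
    name: str
    graph: MoleculeGraph
    true_geometry: ReferenceGeometry
    true_fingerprint: ConfigFingerprint
    restraints: RestraintSet
    bounds: DistanceBounds            # smoothed holonomic bounds
    fixed_center: int
    generator_params: dict = field(default_factory=dict)

    def energy_model(self, fc: ForceConstants | None = None) -> PseudoEnergy:
        model = PseudoEnergy(self.bounds, self.restraints, fc)
        model.set_torsions(self.graph.planar_groups)
        return model

    def true_conformer(self) -> Conformer:
        return Conformer(self.true_geometry.coordinates.copy(), stage="minimized")


def _planarize_sp2_units(mol: Chem.Mol) -> None:
    """Project every conjugated unit (atoms linked by sp2-sp2 bonds, plus
    their substituent attachment atoms) onto its best-fit plane, so the
    idealized geometry satisfies the sp2 planarity (V=0) and conjugated-
    torsion restraints exactly."""
    sp2 = {a.GetIdx() for a in mol.GetAtoms()
           if a.GetHybridization() == Chem.HybridizationType.SP2}
    if not sp2:
        return
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(sp2)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in sp2 and j in sp2:
            g.add_edge(i, j)
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions())
    for comp in nx.connected_components(g):
        comp = set(comp)
        if len(comp) < 2:
            continue
        members = set(comp)
        for i in comp:
            members.update(n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors())
        pts = coords[list(members)]
        centroid = pts.mean(0)
        normal = np.linalg.svd(pts - centroid)[2][2]
        for i in members:
            coords[i] -= ((coords[i] - centroid) @ normal) * normal
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))


def _embed_smiles(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1) or 1
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"ETKDG embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    _planarize_sp2_units(mol)
    return mol


def make_fixture(
    name: str,
    seed: int = 0,
    cutoff: float = 3.5,
    half_width: float = 0.10,
    noise_sd: float = 0.0,
    group_averaging: bool = True,
) -> Fixture:
    """Build a named fixture: geometry, holonomic bounds, chirals and NOEs."""
    if name not in FIXTURE_SMILES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_SMILES)}")
    smiles = FIXTURE_SMILES[name]
    mol = _embed_smiles(smiles, seed)
    graph, geom = from_rdkit(mol, provenance=f"synthetic fixture {name} seed={seed}")
    fixed_center = graph.stereocenters[0]

    chirals = reference_chiral_volumes(graph, geom, fixed_centers=[fixed_center])
    fix = Fixture(
        name=name,
        graph=graph,
        true_geometry=geom,
        true_fingerprint=fingerprint(
            Conformer(geom.coordinates.copy(), stage="minimized"),
            graph, fixed_centers=[fixed_center],
        ),
        restraints=RestraintSet(chirals=chirals),
        bounds=smooth_bounds(holonomic_bounds(graph, geom)),
        fixed_center=fixed_center,
        generator_params={
            "smiles": smiles, "seed": seed, "cutoff": cutoff,
            "half_width": half_width, "noise_sd": noise_sd,
        },
    )
    fix.restraints.noes = simulate_noes(
        fix, cutoff=cutoff, half_width=half_width, noise_sd=noise_sd,
        seed=seed, group_averaging=group_averaging,
    )
    return fix


def _proton_group(graph: MoleculeGraph, h: int, group_averaging: bool) -> tuple[int, ...]:
    carbon = graph.neighbors(h)[0]
    hs = tuple(graph.hydrogens_on(carbon))
    if group_averaging and len(hs) > 1:
        return hs  # unassigned CH2/CH3: whole proton group
    return (h,)


def simulate_noes(
    fix: Fixture,
    cutoff: float = 3.5,
    half_width: float = 0.10,
    noise_sd: float = 0.0,
    seed: int = 0,
    group_averaging: bool = True,
) -> list[NoeRestraint]:
    """All interproton contacts <= cutoff on the true geometry, as NOE bounds.

    CH2/CH3 protons are kept unassigned when ``group_averaging`` is on: the
    contact is emitted once per proton-group pair and its distance is the
    <r^-6> average over the group pairs (so the noise-free true geometry has
    zero NOE energy).  ``r_mean`` is perturbed multiplicatively by
    ``Normal(0, noise_sd)``; bounds are r_mean*(1 -/+ half_width).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    graph, coords = fix.graph, fix.true_geometry.coordinates
    rng = np.random.default_rng(seed)
    hydrogens = [i for i, (_, e) in enumerate(graph.atoms) if e == "H"]
    carbon_of = {h: graph.neighbors(h)[0] for h in hydrogens}

    group_pairs: dict[tuple, tuple] = {}
    for a_pos, ha in enumerate(hydrogens):
        for hb in hydrogens[a_pos + 1:]:
            if carbon_of[ha] == carbon_of[hb]:
                continue  # geminal: never an interpretable NOE contact
            d = float(np.linalg.norm(coords[ha] - coords[hb]))
            if d > cutoff:
                continue
            gi = _proton_group(graph, ha, group_averaging)
            gj = _proton_group(graph, hb, group_averaging)
            key = (min(gi, gj), max(gi, gj))
            group_pairs.setdefault(key, (gi, gj))

    out = []
    from .restraints import effective_noe_distance

    for gi, gj in group_pairs.values():
        probe = NoeRestraint(gi, gj, 0.5, 100.0)
        r_mean = effective_noe_distance(coords, probe)
        r_mean *= 1.0 + rng.normal(0.0, noise_sd) if noise_sd > 0 else 1.0
        out.append(
            NoeRestraint(
                gi, gj,
                r_lower=r_mean * (1.0 - half_width),
                r_upper=r_mean * (1.0 + half_width),
                averaging="r6" if (len(gi) > 1 or len(gj) > 1) else "none",
            )
        )
    return out


def simulate_rdcs(
    fix: Fixture,
    tensors: list[np.ndarray] | None = None,
    n_media: int = 1,
    noise_sd: float = 0.0,
    methylene_sum: bool = True,
    seed: int = 0,
    magnitude: float = 1.2e-3,
) -> list[RdcRestraint]:
    """Back-calculated 1D_CH data sets from the true geometry, one per medium.

    ``tensors``: explicit traceless-symmetric 3x3 order matrices (overrides
    ``n_media``); otherwise ``n_media`` seeded random tensors of the given
    axial magnitude are drawn.  Methyl C-H couplings are skipped (rotational
    averaging is not modelled); CH2 couplings are emitted as the sum of both
    proton couplings when ``methylene_sum`` is on, mirroring the unassigned-
    methylene convention.  Gaussian noise (Hz) is added per coupling.
    """
    rng = np.random.default_rng(seed)
    if tensors is None:
        tensors = [align.random_tensor(rng, magnitude=magnitude) for _ in range(n_media)]
    graph, coords = fix.graph, fix.true_geometry.coordinates
    methyls = set(fix.graph.methyl_groups)

    ch_records = []  # (carbon, tuple_of_H)
    for i, (_, e) in enumerate(graph.atoms):
        if e != "C" or i in methyls:
            continue
        hs = graph.hydrogens_on(i)
        if not hs:
            continue
        if len(hs) == 2 and methylene_sum:
            ch_records.append((i, tuple(hs)))
        else:
            ch_records.extend((i, (h,)) for h in hs)

    def d_of(S, c, h):
        v = coords[h] - coords[c]
        r = np.linalg.norm(v)
        u = v / r
        return float(align.DIPOLAR_CH / r ** 3 * (u @ S @ u))

    out = []
    for medium, S in enumerate(tensors):
        S = np.asarray(S, dtype=float)
        if abs(np.trace(S)) > 1e-8 or not np.allclose(S, S.T):
            raise ValueError("alignment tensors must be traceless symmetric")
        for c, hs in ch_records:
            d = sum(d_of(S, c, h) for h in hs)
            if noise_sd > 0:
                d += rng.normal(0.0, noise_sd)
            out.append(
                RdcRestraint(
                    medium, c, hs, float(d),
                    mode="methylene_sum" if len(hs) == 2 else "single",
                )
            )
    return out


def diastereomer_geometry(
    fix: Fixture, flip_position: int = 0, seed: int = 0
) -> tuple[ReferenceGeometry, ConfigFingerprint]:
    """Geometry of the diastereomer with one floating stereocenter inverted.

    ``flip_position`` indexes the floating stereocenters (fixture order).
    Returns the re-embedded geometry and its fingerprint; useful as a
    "wrong configuration" probe against the fixture's restraints.
    """
    smiles = fix.generator_params["smiles"]
    mol = Chem.MolFromSmiles(smiles)
    centers = [i for i, _ in Chem.FindMolChiralCenters(mol, includeUnassigned=True,
                                                       useLegacyImplementation=False)]
    floating = [c for c in sorted(centers) if c != fix.fixed_center]
    target = floating[flip_position]
    atom = mol.GetAtomWithIdx(target)
    tag = atom.GetChiralTag()
    flip = {
        Chem.ChiralType.CHI_TETRAHEDRAL_CW: Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
        Chem.ChiralType.CHI_TETRAHEDRAL_CCW: Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    }
    atom.SetChiralTag(flip[tag])
    # AddHs + embed directly on the edited mol: heavy atoms keep the SMILES
    # order and hydrogens are appended identically to the fixture build, so
    # atom indices stay aligned with the fixture graph.
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1) or 1
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise RuntimeError("ETKDG embedding failed for diastereomer")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=2000)
    graph2, geom = from_rdkit(molh, provenance=f"diastereomer of {fix.name}")
    fp = fingerprint(
        Conformer(geom.coordinates.copy(), stage="minimized"),
        graph2, fixed_centers=[fix.fixed_center],
    )
    return geom, fp
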