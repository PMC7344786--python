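"""Molecular constitution, holonomic distance bounds and chiral-volume restraints.

A molecule enters the pipeline as a constitution (atoms + bonds) together with
a 3D reference geometry of *arbitrary* configuration and conformation.  The
reference geometry is used only to measure quantities that depend on the
constitution alone -- bond lengths, bond angles, torsion extremes, ring
geometries and chiral-volume magnitudes -- from which the holonomic distance
bounds and chiral restraints are derived.  Nothing downstream ever sees the
reference coordinates themselves, so the configurational outcome of a run is
independent of the configuration of the input structure.

Indexing convention: all atom indices are 0-based internally; file interfaces
(SDF, XYZ + bond list) are 1-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


class MoleculeError(ValueError):
    """Raised for structurally invalid input (missing H, disconnected graph...)."""


class InfeasibleBoundsError(ValueError):
    """Raised when triangle smoothing proves the bounds contradictory."""

    def __init__(self, i: int, j: int, lower: float, upper: float):
        self.pair = (i, j)
        super().__init__(
            f"infeasible distance bounds for atom pair ({i}, {j}): "
            f"lower {lower:.4f} > upper {upper:.4f} after triangle smoothing"
        )


# Hard-sphere radii (Angstrom) used for non-bonded lower bounds.  The lower
# bound of a >=1,5 pair is 0.8 * (r_i + r_j): tight enough to prevent atom
# collapse during embedding/annealing, loose enough not to bias conformation.
HARD_SPHERE_RADII = {
    "H": 1.0, "C": 1.5, "N": 1.4, "O": 1.3, "S": 1.7,
    "Cl": 1.7, "Br": 1.8, "F": 1.2, "I": 2.0, "P": 1.7,
}
DEFAULT_RADIUS = 1.5
NONBONDED_SCALE = 0.8

BOND_TOL = 0.01   # +-1% on 1,2 reference distances
ANGLE_TOL = 0.01  # +-1% on 1,3 reference distances
TORSION_TOL = 0.01  # 1,4 bounds: [cis*(1-tol), trans*(1+tol)]


@dataclass(frozen=True)
class ChiralRestraint:
    """A signed-volume restraint V = a.(b x c) on an ordered atom quadruple.

    ``substituents`` is the ordered quadruple (p0, p1, p2, p3); the volume is
    the scalar triple product of p1-p0, p2-p0, p3-p0.  ``center`` is the
    restrained atomic center (-1 for a pure plane restraint).
    """

    center: int
    substituents: tuple[int, int, int, int]
    target_volume: float
    kind: str  # fixed_stereocenter | sp2_planar | methyl_tetrahedral
    force_constant: float | None = None


@dataclass
class ReferenceGeometry:
    coordinates: np.ndarray  # (N, 3) Angstrom
    provenance: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise MoleculeError("reference geometry contains non-finite coordinates")


@dataclass
class MoleculeGraph:
    """Constitution of the molecule plus perception results.

    ``mol`` keeps the underlying RDKit molecule (explicit hydrogens) so that
    writers can round-trip SDF output; all perception results are plain
    index lists so downstream modules never need RDKit.
    """

    atoms: list[tuple[int, str]]
    bonds: list[tuple[int, int, float]]
    planar_groups: list[tuple[int, int, int, int]]
    stereocenters: list[int]
    prochiral_centers: list[int]
    methyl_groups: list[int]
    sp2_centers: list[int] = field(default_factory=list)
    aromatic_rings: list[tuple[int, ...]] = field(default_factory=list)
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [e for _, e in self.atoms]

    def neighbors(self, i: int) -> list[int]:
        nbr = []
        for a, b, _ in self.bonds:
            if a == i:
                nbr.append(b)
            elif b == i:
                nbr.append(a)
        return sorted(nbr)

    def hydrogens_on(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.atoms[j][1] == "H"]


@dataclass
class DistanceBounds:
    lower: np.ndarray
    upper: np.ndarray

    def copy(self) -> "DistanceBounds":
        return DistanceBounds(self.lower.copy(), self.upper.copy())

    @property
    def n_atoms(self) -> int:
        return self.lower.shape[0]


# ---------------------------------------------------------------------------
# Structure loading and perception
# ---------------------------------------------------------------------------

def _perceive(mol: Chem.Mol) -> MoleculeGraph:
    """Derive stereocenters, prochiral CH2, methyls and planar torsions from
    connectivity and bond orders alone."""
    n = mol.GetNumAtoms()
    atoms = [(a.GetIdx(), a.GetSymbol()) for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]

    if any(a.GetNumImplicitHs() > 0 for a in mol.GetAtoms()):
        raise MoleculeError(
            "structure has implicit hydrogens; all hydrogens must be explicit "
            "so that interproton restraints can be expressed"
        )
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MoleculeError(f"bond graph is disconnected ({len(frags)} fragments)")

    # Potential tetrahedral stereocenters from the constitution (assignment of
    # the input configuration is deliberately ignored).
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    stereocenters = sorted(idx for idx, _ in centers)

    # Graph symmetry classes: two atoms share a rank iff an automorphism of the
    # constitution maps one onto the other.
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))

    prochiral, methyls = [], []
    for a in mol.GetAtoms():
        if a.GetSymbol() != "C":
            continue
        nbrs = list(a.GetNeighbors())
        hs = [x for x in nbrs if x.GetSymbol() == "H"]
        heavies = [x for x in nbrs if x.GetSymbol() != "H"]
        if len(hs) == 3 and len(heavies) == 1:
            methyls.append(a.GetIdx())
        elif len(hs) == 2 and len(heavies) == 2:
            # CH2 with constitutionally distinct heavy branches: the two
            # protons are diastereotopic candidates ("prochiral center").
            if ranks[heavies[0].GetIdx()] != ranks[heavies[1].GetIdx()]:
                prochiral.append(a.GetIdx())

    sp2 = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetHybridization() == Chem.HybridizationType.SP2 and a.GetDegree() == 3
    ]
    sp2_set = set(
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetHybridization() == Chem.HybridizationType.SP2
    )

    # Torsion quadruples (i, j, k, l) across every sp2-sp2 central bond.
    planar_groups = []
    for b in mol.GetBonds():
        j, k = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if j not in sp2_set or k not in sp2_set:
            continue
        for i_at in mol.GetAtomWithIdx(j).GetNeighbors():
            if i_at.GetIdx() == k:
                continue
            for l_at in mol.GetAtomWithIdx(k).GetNeighbors():
                if l_at.GetIdx() == j:
                    continue
                planar_groups.append((i_at.GetIdx(), j, k, l_at.GetIdx()))

    # Rings whose atoms are all sp2: rigid planar units (aromatic rings).
    aromatic_rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(i in sp2_set for i in ring):
            aromatic_rings.append(tuple(ring))

    return MoleculeGraph(
        atoms=atoms,
        bonds=bonds,
        planar_groups=planar_groups,
        stereocenters=stereocenters,
        prochiral_centers=sorted(prochiral),
        methyl_groups=sorted(methyls),
        sp2_centers=sorted(sp2),
        aromatic_rings=aromatic_rings,
        mol=mol,
    )


def from_rdkit(mol: Chem.Mol, provenance: str = "rdkit") -> tuple[MoleculeGraph, ReferenceGeometry]:
    """Build a MoleculeGraph + ReferenceGeometry from an RDKit mol with a conformer."""
    if mol.GetNumConformers() == 0:
        raise MoleculeError("molecule has no 3D conformer")
    graph = _perceive(mol)
    coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    return graph, ReferenceGeometry(coords, provenance=provenance)


def _load_xyz_bonds(xyz_path: str, bonds_path: str) -> Chem.Mol:
    lines = Path(xyz_path).read_text().splitlines()
    n = int(lines[0].split()[0])
    rows = [ln.split() for ln in lines[2 : 2 + n]]
    rw = Chem.RWMol()
    coords = []
    for sym, x, y, z, *_ in rows:
        rw.AddAtom(Chem.Atom(sym))
        coords.append((float(x), float(y), float(z)))
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for ln in Path(bonds_path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        i, j, order = ln.split()[:3]
        rw.AddBond(int(i) - 1, int(j) - 1, order_map[float(order)])
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for idx, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(idx, (x, y, z))
    mol.AddConformer(conf)
    for a in mol.GetAtoms():
        a.SetNoImplicit(True)
    Chem.SanitizeMol(mol)
    return mol


def load_structure(path: str, fmt: str | None = None, bonds_path: str | None = None):
    """Load an SDF/MOL V2000 file, or an XYZ file paired with a bond list.

    The bond list is a plain-text file with one ``i j order`` triple per line,
    1-based atom indices.  Returns ``(MoleculeGraph, ReferenceGeometry)``.
    """
    path = str(path)
    if fmt is None:
        fmt = "xyz+bonds" if path.endswith(".xyz") else "sdf"
    if fmt == "sdf":
        mol = Chem.MolFromMolFile(path, removeHs=False, sanitize=True)
        if mol is None:
            raise MoleculeError(f"could not parse SDF/MOL file {path!r}")
    elif fmt == "xyz+bonds":
        if bonds_path is None:
            raise MoleculeError("xyz input requires an explicit bond list file")
        mol = _load_xyz_bonds(path, bonds_path)
    else:
        raise MoleculeError(f"unknown structure format {fmt!r}")
    return from_rdkit(mol, provenance=path)


# ---------------------------------------------------------------------------
# Holonomic bounds
# ---------------------------------------------------------------------------

def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def _torsion_extremes(r1, r2, r3, th1, th2):
    """Distance between atoms i and l of a chain i-j-k-l at torsion 0 (cis)
    and 180 deg (trans), from reference bond lengths and angles."""
    i = np.array([r1 * np.cos(th1), r1 * np.sin(th1)])
    base = np.array([r2 - r3 * np.cos(th2), r3 * np.sin(th2)])
    d_cis = float(np.linalg.norm(i - base))
    d_trans = float(np.linalg.norm(i - base * np.array([1.0, -1.0])))
    return min(d_cis, d_trans), max(d_cis, d_trans)


def holonomic_bounds(graph: MoleculeGraph, ref: ReferenceGeometry) -> DistanceBounds:
    """Distance bounds implied by the constitution alone.

    1,2 and 1,3 pairs are pinned at the reference value +-1%; 1,4 pairs span
    the syn/anti torsion extremes; >=1,5 pairs get hard-sphere lower bounds
    and a bond-path-sum upper cap.  Pairs inside all-sp2 rings are pinned at
    reference +-1% (rigid planar units).
    """
    n = graph.n_atoms
    coords = ref.coordinates
    if coords.shape[0] != n:
        raise MoleculeError("reference geometry does not cover the molecular graph")
    dref = _pair_distances(coords)

    rows = [b[0] for b in graph.bonds] + [b[1] for b in graph.bonds]
    cols = [b[1] for b in graph.bonds] + [b[0] for b in graph.bonds]
    blen = []
    for i, j, _ in graph.bonds:
        d = dref[i, j]
        if d <= 1e-6:
            raise MoleculeError(f"zero-length bond {i}-{j} in reference geometry")
        blen.append(d)
    wdata = blen + blen
    adj_hop = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj_len = csr_matrix((wdata, (rows, cols)), shape=(n, n))

    hops = dijkstra(adj_hop, unweighted=True, directed=False)
    path_len = dijkstra(adj_len, directed=False)

    radii = np.array(
        [HARD_SPHERE_RADII.get(e, DEFAULT_RADIUS) for e in graph.elements]
    )
    lower = NONBONDED_SCALE * (radii[:, None] + radii[None, :])
    upper = path_len.copy()

    # 1,2 and 1,3: reference +-1%
    for mask_hops, tol in ((1, BOND_TOL), (2, ANGLE_TOL)):
        sel = hops == mask_hops
        lower[sel] = dref[sel] * (1.0 - tol)
        upper[sel] = dref[sel] * (1.0 + tol)

    # 1,4: torsion extremes, intersected over all i-j-k-l paths of the pair
    nbrs = {i: graph.neighbors(i) for i in range(n)}
    quad_lower = {}
    quad_upper = {}
    for (j, k, _) in graph.bonds:
        for jj, kk in ((j, k), (k, j)):
            for i in nbrs[jj]:
                if i == kk:
                    continue
                for l in nbrs[kk]:
                    if l == jj or l == i:
                        continue
                    if hops[i, l] != 3:
                        continue
                    r1, r2, r3 = dref[i, jj], dref[jj, kk], dref[kk, l]
                    v1 = coords[i] - coords[jj]
                    v2 = coords[kk] - coords[jj]
                    th1 = np.arccos(np.clip(v1 @ v2 / (r1 * r2), -1, 1))
                    v3 = coords[jj] - coords[kk]
                    v4 = coords[l] - coords[kk]
                    th2 = np.arccos(np.clip(v3 @ v4 / (r2 * r3), -1, 1))
                    d_cis, d_trans = _torsion_extremes(r1, r2, r3, th1, th2)
                    key = (min(i, l), max(i, l))
                    lo = d_cis * (1.0 - TORSION_TOL)
                    hi = d_trans * (1.0 + TORSION_TOL)
                    quad_lower[key] = max(quad_lower.get(key, -np.inf), lo)
                    quad_upper[key] = min(quad_upper.get(key, np.inf), hi)
    for (i, l), lo in quad_lower.items():
        lower[i, l] = lower[l, i] = lo
        upper[i, l] = upper[l, i] = quad_upper[(i, l)]

    # rigid planar rings: pin every intra-ring pair
    for ring in graph.aromatic_rings:
        for a in ring:
            for b in ring:
                if a < b:
                    lower[a, b] = lower[b, a] = dref[a, b] * (1.0 - BOND_TOL)
                    upper[a, b] = upper[b, a] = dref[a, b] * (1.0 + BOND_TOL)

    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    lower = np.minimum(lower, upper)  # hard-sphere floor never overrides pins
    return DistanceBounds(lower, upper)


def smooth_bounds(bounds: DistanceBounds) -> DistanceBounds:
    """Tighten bounds to triangle consistency.

    Uppers become all-pairs shortest paths; lowers are raised by the inverse
    triangle inequality l(i,j) >= l(i,k) - u(k,j).  Idempotent; never widens
    a bound.  Raises :class:`InfeasibleBoundsError` if a lower bound ends up
    above the corresponding upper bound.
    """
    l = bounds.lower.copy()
    u = bounds.upper.copy()
    n = u.shape[0]
    for k in range(n):
        u = np.minimum(u, u[:, k, None] + u[None, k, :])
    # check input lowers against smoothed uppers first: reports the offending
    # restraint pair itself rather than a pair the contradiction spread to
    bad = (l > u + 1e-9) & ~np.eye(n, dtype=bool)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise InfeasibleBoundsError(int(i), int(j), float(l[i, j]), float(u[i, j]))
    for k in range(n):
        l = np.maximum(l, l[:, k, None] - u[None, k, :])
        l = np.maximum(l, l[None, k, :] - u[:, k, None])
    np.fill_diagonal(l, 0.0)
    np.fill_diagonal(u, 0.0)
    if np.any(l > u + 1e-9):
        i, j = np.argwhere(l > u + 1e-9)[0]
        raise InfeasibleBoundsError(int(i), int(j), float(l[i, j]), float(u[i, j]))
    return DistanceBounds(l, u)


# ---------------------------------------------------------------------------
# Chiral volume restraints
# ---------------------------------------------------------------------------

def signed_volume(coords: np.ndarray, quad: tuple[int, int, int, int]) -> float:
    p0, p1, p2, p3 = (coords[q] for q in quad)
    return float(np.dot(p1 - p0, np.cross(p2 - p0, p3 - p0)))


def _center_quad(graph: MoleculeGraph, center: int) -> tuple[int, ...]:
    """Canonical substituent ordering: sorted neighbor indices (p0..p3)."""
    nbr = graph.neighbors(center)
    if len(nbr) != 4:
        raise MoleculeError(
            f"atom {center} has {len(nbr)} neighbors; a tetrahedral chiral "
            "restraint requires exactly 4"
        )
    return tuple(nbr)


def reference_chiral_volumes(
    graph: MoleculeGraph,
    ref: ReferenceGeometry,
    fixed_centers: list[int] | None = None,
    allow_multiple_fixed: bool = False,
) -> list[ChiralRestraint]:
    """Chiral restraints for a floating-chirality run.

    One ``fixed_stereocenter`` restraint per requested center (normally a
    single one, to exclude the global enantiomer), ``sp2_planar`` (target 0)
    on every 3-coordinate sp2 center, and ``methyl_tetrahedral`` on every CH3
    carbon.  Floating stereocenters and prochiral CH2 get no restraint.
    """
    fixed_centers = list(fixed_centers or [])
    for c in fixed_centers:
        if c not in graph.stereocenters:
            raise MoleculeError(f"fixed center {c} is not a stereocenter")
    if len(fixed_centers) > 1 and not allow_multiple_fixed:
        raise MoleculeError(
            "more than one fixed stereocenter defeats floating chirality; "
            "pass allow_multiple_fixed=True to opt in"
        )
    out: list[ChiralRestraint] = []
    coords = ref.coordinates
    for c in fixed_centers:
        quad = _center_quad(graph, c)
        out.append(
            ChiralRestraint(
                center=c,
                substituents=quad,
                target_volume=signed_volume(coords, quad),
                kind="fixed_stereocenter",
            )
        )
    for c in graph.sp2_centers:
        nbr = graph.neighbors(c)
        if len(nbr) != 3:
            continue
        quad = (c, nbr[0], nbr[1], nbr[2])
        out.append(
            ChiralRestraint(
                center=c, substituents=quad, target_volume=0.0, kind="sp2_planar"
            )
        )
    for c in graph.methyl_groups:
        quad = _center_quad(graph, c)
        out.append(
            ChiralRestraint(
                center=c,
                substituents=quad,
                target_volume=signed_volume(coords, quad),
                kind="methyl_tetrahedral",
            )
        )
    return out
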