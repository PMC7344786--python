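"""The dimensionless pseudo-energy force field and its analytic gradient.

    E_total = E_dist + E_chir + E_NOE + E_RDC + E_DBL

Every term is a harmonic sum of squared restraint violations,
``E_X = 1/2 K_X sum (Delta X)^2``.  There are no physical force-field terms of
any kind: the only "forces" are gradients of restraint violations, which is
what makes the final pseudo energy a pure measure of agreement with the
holonomic and experimental restraints.

Terms:

* ``E_dist`` -- violations of the (smoothed) holonomic distance bounds over
  all atom pairs, piecewise: Delta = r - lower below, 0 inside, r - upper
  above the interval.
* ``E_chir`` -- squared deviations of signed chiral volumes
  ``V = a.(b x c)`` from their targets (fixed stereocenter, sp2 plane with
  target 0, methyl tetrahedron).
* ``E_NOE`` -- the same piecewise form applied to <r^-6>-averaged interproton
  distances against the experimental bounds; K_NOE = 10 A^-2.
* ``E_RDC`` -- squared deviations of back-calculated RDCs, with the alignment
  tensor of each medium refit by SVD at every evaluation; K_RDC = 1.5/M Hz^-2
  for M media.  Because the tensor is the least-squares optimum, holding it
  fixed while differentiating yields the exact gradient of the
  tensor-minimized energy (envelope theorem).
* ``E_DBL`` -- torsional planarity of conjugated bonds,
  Delta = 1 - cos^2(phi) on every sp2-sp2 central torsion; K_DBL = 100.

In 4D, interatomic distances use all four coordinates while chiral volumes,
planarity torsions and RDC bond vectors are evaluated on the first three
coordinates; a configurational inversion then remains a barrier-free rotation
through the fourth dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align
from .molgraph import DistanceBounds
from .restraints import RestraintSet

_EPS_R = 1e-8  # distance floor guarding r->0 singularities in gradients


@dataclass
class ForceConstants:
    """Force constants of the pseudo-energy terms.

    ``k_noe``, ``k_rdc_base`` and ``k_dbl`` follow the published protocol
    (10 A^-2, 1.5/M Hz^-2, 100); ``k_dist`` and ``k_chir`` are package
    defaults reported in all run metadata.  ``tau_t`` is the temperature
    coupling factor of the 4D->3D compression schedule.
    """

    k_dist: float = 25.0      # A^-2, holonomic bound violations
    k_chir: float = 25.0      # A^-6, chiral volume violations
    k_noe: float = 10.0       # A^-2
    k_rdc_base: float = 1.5   # Hz^-2; effective K = k_rdc_base / n_media
    k_dbl: float = 100.0      # dimensionless
    tau_t: float = 150.0      # K

    def __post_init__(self):
        for name in ("k_dist", "k_chir", "k_noe", "k_rdc_base", "k_dbl", "tau_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def k_rdc(self, n_media: int) -> float:
        return self.k_rdc_base / max(n_media, 1)


@dataclass
class EnergyBreakdown:
    e_dist: float = 0.0
    e_chir: float = 0.0
    e_noe: float = 0.0
    e_rdc: float = 0.0
    e_dbl: float = 0.0
    violations: dict = field(default_factory=dict)

    @property
    def e_total(self) -> float:
        return self.e_dist + self.e_chir + self.e_noe + self.e_rdc + self.e_dbl

    def as_dict(self) -> dict:
        return {
            "e_dist": self.e_dist, "e_chir": self.e_chir, "e_noe": self.e_noe,
            "e_rdc": self.e_rdc, "e_dbl": self.e_dbl, "e_total": self.e_total,
        }


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def chiral_volume(p0, p1, p2, p3) -> float:
    """Signed volume a.(b x c) with a,b,c the substituent vectors from p0."""
    p0 = np.asarray(p0, float)
    a, b, c = (np.asarray(p, float) - p0 for p in (p1, p2, p3))
    return float(a @ np.cross(b, c))


def noe_violation(r_eff: float, r_lower: float, r_upper: float) -> float:
    """Piecewise bound violation: negative below, zero inside, positive above."""
    if r_eff < r_lower:
        return r_eff - r_lower
    if r_eff > r_upper:
        return r_eff - r_upper
    return 0.0


def penalty(violations, k: float) -> float:
    """Harmonic penalty 1/2 K sum(Delta^2)."""
    if k <= 0:
        raise ValueError("force constant must be positive")
    v = np.asarray(list(violations), dtype=float)
    return float(0.5 * k * np.sum(v ** 2))


def dbl_violation(phi_degrees: float) -> float:
    """Planarity violation 1 - cos^2(phi); vanishes at 0 and 180 degrees."""
    c = np.cos(np.deg2rad(phi_degrees))
    return float(1.0 - c * c)


# ---------------------------------------------------------------------------
# Compiled energy model
# ---------------------------------------------------------------------------

class PseudoEnergy:
    """Pre-compiled pseudo-energy model for one molecule + restraint set.

    ``evaluate(coords, with_grad=...)`` works on (N, 3) or (N, 4) coordinate
    arrays and returns an :class:`EnergyBreakdown` (and the analytic gradient).
    """

    def __init__(
        self,
        bounds: DistanceBounds,
        restraints: RestraintSet,
        fc: ForceConstants | None = None,
    ):
        self.fc = fc or ForceConstants()
        self.restraints = restraints
        self.n_atoms = bounds.n_atoms
        n = self.n_atoms

        iu = np.triu_indices(n, 1)
        self._pi, self._pj = iu
        self._lower = bounds.lower[iu]
        self._upper = bounds.upper[iu]
        # full-matrix copies for the vectorized bound term (diagonal neutral)
        self._L = bounds.lower.copy()
        self._U = bounds.upper.copy()
        np.fill_diagonal(self._L, 0.0)
        np.fill_diagonal(self._U, 1.0)

        # NOE pair expansion
        pi, pj, rid = [], [], []
        self._noe_lo = np.array([r.r_lower for r in restraints.noes])
        self._noe_up = np.array([r.r_upper for r in restraints.noes])
        npairs = []
        for k, noe in enumerate(restraints.noes):
            cnt = 0
            for a in noe.group_i:
                for b in noe.group_j:
                    pi.append(a); pj.append(b); rid.append(k); cnt += 1
            npairs.append(cnt)
        self._noe_i = np.array(pi, dtype=int)
        self._noe_j = np.array(pj, dtype=int)
        self._noe_rid = np.array(rid, dtype=int)
        self._noe_npairs = np.array(npairs, dtype=float)

        # chiral quadruples
        ch = restraints.chirals
        self._ch_quads = np.array([c.substituents for c in ch], dtype=int).reshape(-1, 4)
        self._ch_targets = np.array([c.target_volume for c in ch])
        self._ch_k = np.array(
            [c.force_constant if c.force_constant else self.fc.k_chir for c in ch]
        )

        # planarity torsions
        self._torsions = np.zeros((0, 4), dtype=int)

        # per-medium RDC tables
        self._media = []
        for m in range(restraints.n_media):
            recs = [r for r in restraints.rdcs if r.medium == m]
            if not recs:
                continue
            c_idx = np.array([r.atom_c for r in recs], dtype=int)
            h1 = np.array([r.atom_h[0] for r in recs], dtype=int)
            h2 = np.array(
                [r.atom_h[1] if len(r.atom_h) > 1 else -1 for r in recs], dtype=int
            )
            d_exp = np.array([r.d_exp for r in recs])
            is_sum = h2 >= 0
            self._media.append(
                (c_idx, h1, h2, d_exp, is_sum, h2[is_sum], c_idx[is_sum])
            )
        self._n_media = restraints.n_media
        # concatenated index arrays: design rows for all media in one pass
        self._rdc_slices, self._rdc_slices2 = [], []
        off = off2 = 0
        for c_idx, h1, _h2, _d, _is, h2s, _c2 in self._media:
            self._rdc_slices.append((off, off + h1.size)); off += h1.size
            self._rdc_slices2.append((off2, off2 + h2s.size)); off2 += h2s.size
        cat = lambda xs: (np.concatenate(xs) if xs else np.zeros(0, dtype=int))
        self._rdc_c_all = cat([m[0] for m in self._media])
        self._rdc_h1_all = cat([m[1] for m in self._media])
        self._rdc_h2_all = cat([m[5] for m in self._media])
        self._rdc_c2_all = cat([m[6] for m in self._media])

    def set_torsions(self, quadruples) -> None:
        self._torsions = np.array(quadruples, dtype=int).reshape(-1, 4)

    # -- individual terms ---------------------------------------------------

    def _dist_term(self, X, grad):
        # Gram-matrix form avoids materializing the (N, N, D) difference
        # tensor: r^2 = |xi|^2 + |xj|^2 - 2 xi.xj, and the pair forces reduce
        # to row sums / one matmul.
        G = X @ X.T
        sq = np.einsum("ii->i", G)
        r2 = sq[:, None] + sq[None, :] - 2.0 * G
        np.fill_diagonal(r2, 1.0)
        r = np.sqrt(np.maximum(r2, _EPS_R ** 2))
        delta_m = np.where(r < self._L, r - self._L,
                           np.where(r > self._U, r - self._U, 0.0))
        e = 0.25 * self.fc.k_dist * float(np.sum(delta_m * delta_m))
        if grad is not None:
            coef = self.fc.k_dist * (delta_m / r)  # symmetric
            grad += coef.sum(1)[:, None] * X - coef @ X
        return e, delta_m[self._pi, self._pj]

    def _noe_term(self, X, grad):
        if self._noe_rid.size == 0:
            return 0.0, np.zeros(0)
        vec = X[self._noe_i] - X[self._noe_j]
        r = np.maximum(np.sqrt((vec ** 2).sum(1)), _EPS_R)
        m6 = r ** -6.0
        mean6 = np.bincount(self._noe_rid, weights=m6,
                            minlength=self._noe_lo.size) / self._noe_npairs
        r_eff = mean6 ** (-1.0 / 6.0)
        delta = np.where(r_eff < self._noe_lo, r_eff - self._noe_lo,
                         np.where(r_eff > self._noe_up, r_eff - self._noe_up, 0.0))
        e = 0.5 * self.fc.k_noe * float(delta @ delta)
        if grad is not None:
            # dE/dr_eff = K * delta ; dr_eff/dr_ab = (r_eff^7 / n_pairs) r_ab^-7
            dEdreff = self.fc.k_noe * delta
            coef = (dEdreff[self._noe_rid]
                    * (r_eff[self._noe_rid] ** 7.0 / self._noe_npairs[self._noe_rid])
                    * r ** -7.0)
            f = (coef / r)[:, None] * vec
            np.add.at(grad, self._noe_i, f)
            np.add.at(grad, self._noe_j, -f)
        return e, delta

    @staticmethod
    def _cross(a, b):
        out = np.empty_like(a)
        out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
        out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
        out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        return out

    def _chir_term(self, X3, grad):
        if self._ch_quads.shape[0] == 0:
            return 0.0, np.zeros(0)
        q = self._ch_quads
        p0 = X3[q[:, 0]]
        a = X3[q[:, 1]] - p0
        b = X3[q[:, 2]] - p0
        c = X3[q[:, 3]] - p0
        bxc = self._cross(b, c)
        v = (a * bxc).sum(1)
        delta = v - self._ch_targets
        e = float(0.5 * np.sum(self._ch_k * delta ** 2))
        if grad is not None:
            coef = (self._ch_k * delta)[:, None]
            g1 = coef * bxc
            g2 = coef * self._cross(c, a)
            g3 = coef * self._cross(a, b)
            g0 = -(g1 + g2 + g3)
            gr3 = grad[:, :3]
            for col, g in zip(range(4), (g0, g1, g2, g3)):
                np.add.at(gr3, q[:, col], g)
        return e, delta

    def _dbl_term(self, X3, grad):
        if self._torsions.shape[0] == 0:
            return 0.0, np.zeros(0)
        t = self._torsions
        b1 = X3[t[:, 1]] - X3[t[:, 0]]
        b2 = X3[t[:, 2]] - X3[t[:, 1]]
        b3 = X3[t[:, 3]] - X3[t[:, 2]]
        n1 = self._cross(b1, b2)
        n2 = self._cross(b2, b3)
        n1n = np.linalg.norm(n1, axis=1)
        n2n = np.linalg.norm(n2, axis=1)
        ok = (n1n > 1e-10) & (n2n > 1e-10)  # collinear torsions contribute 0
        cphi = np.zeros(t.shape[0])
        u = np.zeros_like(n1)
        w = np.zeros_like(n2)
        u[ok] = n1[ok] / n1n[ok, None]
        w[ok] = n2[ok] / n2n[ok, None]
        cphi[ok] = np.clip((u[ok] * w[ok]).sum(1), -1.0, 1.0)
        delta = np.where(ok, 1.0 - cphi ** 2, 0.0)
        e = 0.5 * self.fc.k_dbl * float(delta @ delta)
        if grad is not None and np.any(ok):
            dEdc = -2.0 * self.fc.k_dbl * delta * cphi  # dE/d(cos phi)
            g1 = np.zeros_like(n1)
            g2 = np.zeros_like(n2)
            g1[ok] = (w[ok] - cphi[ok, None] * u[ok]) / n1n[ok, None]
            g2[ok] = (u[ok] - cphi[ok, None] * w[ok]) / n2n[ok, None]
            db1 = self._cross(b2, g1)
            db2 = self._cross(g1, b1) + self._cross(b3, g2)
            db3 = self._cross(g2, b2)
            coef = dEdc[:, None]
            gr3 = grad[:, :3]
            np.add.at(gr3, t[:, 0], -coef * db1)
            np.add.at(gr3, t[:, 1], coef * (db1 - db2))
            np.add.at(gr3, t[:, 2], coef * (db2 - db3))
            np.add.at(gr3, t[:, 3], coef * db3)
        return e, delta

    def _rdc_term(self, X3, grad):
        if not self._media:
            return 0.0, [], []
        k = self.fc.k_rdc(self._n_media)
        C = align.DIPOLAR_CH
        e = 0.0
        deltas, fits = [], []
        vb1 = X3[self._rdc_h1_all] - X3[self._rdc_c_all]
        Ab, r2b, r5b = self._rows(vb1)
        if self._rdc_h2_all.size:
            vb2 = X3[self._rdc_h2_all] - X3[self._rdc_c2_all]
            Ab2, r2b2, r5b2 = self._rows(vb2)
        for (c_idx, h1, h2, d_exp, is_sum, h2s, c2s), (lo, hi), (lo2, hi2) in zip(
            self._media, self._rdc_slices, self._rdc_slices2
        ):
            v1, A, r2_1, r5_1 = vb1[lo:hi], Ab[lo:hi].copy(), r2b[lo:hi], r5b[lo:hi]
            v2 = r2_2 = r5_2 = None
            if h2s.size:
                v2, r2_2, r5_2 = vb2[lo2:hi2], r2b2[lo2:hi2], r5b2[lo2:hi2]
                A[is_sum] += Ab2[lo2:hi2]
            AtA = A.T @ A
            try:
                s5 = np.linalg.solve(AtA, A.T @ d_exp)
            except np.linalg.LinAlgError:
                s5, *_ = np.linalg.lstsq(A, d_exp, rcond=None)
            d_calc = A @ s5
            delta = d_exp - d_calc
            e += 0.5 * k * float(delta @ delta)
            deltas.append(delta)
            fits.append((s5, d_calc))
            if grad is not None:
                S = np.array([[s5[0], s5[2], s5[3]],
                              [s5[2], s5[1], s5[4]],
                              [s5[3], s5[4], -s5[0] - s5[1]]])
                coef = -k * delta  # dE/dD_calc
                gr3 = grad[:, :3]
                gv = self._dD_dv(v1, r2_1, r5_1, S) * coef[:, None]
                np.add.at(gr3, h1, gv)
                np.add.at(gr3, c_idx, -gv)
                if h2s.size:
                    gv2 = self._dD_dv(v2, r2_2, r5_2, S) * coef[is_sum, None]
                    np.add.at(gr3, h2s, gv2)
                    np.add.at(gr3, c2s, -gv2)
        return e, deltas, fits

    @staticmethod
    def _rows(v):
        """Design rows: D = C q / r^5 with q = v^T S v, expanded on the
        5-element tensor basis."""
        C = align.DIPOLAR_CH
        x, y, z = v[:, 0], v[:, 1], v[:, 2]
        x2, y2, z2 = x * x, y * y, z * z
        r2 = x2 + y2 + z2
        r5 = r2 * r2 * np.sqrt(r2)
        A = np.empty((v.shape[0], 5))
        cr = C / r5
        A[:, 0] = cr * (x2 - z2)
        A[:, 1] = cr * (y2 - z2)
        A[:, 2] = cr * (2 * x * y)
        A[:, 3] = cr * (2 * x * z)
        A[:, 4] = cr * (2 * y * z)
        return A, r2, r5

    @staticmethod
    def _dD_dv(v, r2, r5, S):
        C = align.DIPOLAR_CH
        Sv = v @ S.T
        q = (v * Sv).sum(1)
        return C * (2.0 * Sv / r5[:, None] - (5.0 * q / (r5 * r2))[:, None] * v)

    # -- full evaluation ----------------------------------------------------

    def evaluate(self, coords: np.ndarray, with_grad: bool = False,
                 w3: float = 1.0, w_rdc: float | None = None):
        """Energy (and gradient) at ``coords``.

        ``w3`` scales the 3D-subspace terms (chirality, planarity, RDC):
        during 4D annealing these only become meaningful as the structure
        compresses into the 3D subspace, so the annealer ramps them in with
        the compression factor f(T).  ``w_rdc`` (default ``w3``) scales the
        RDC term separately: the 3D annealer ramps the stiff RDC forces in
        with f(T) while keeping the geometric terms at full strength, so the
        conformational search is distance-driven while hot and the RDC terms
        engage as the structure cools (they are always at full strength in
        the final minimization)."""
        X = np.asarray(coords, dtype=float)
        if X.ndim != 2 or X.shape[0] != self.n_atoms or X.shape[1] not in (3, 4):
            raise ValueError(
                f"coords must be ({self.n_atoms}, 3|4), got {X.shape}"
            )
        grad = np.zeros_like(X) if with_grad else None
        X3 = X[:, :3]

        if w_rdc is None:
            w_rdc = w3
        e_dist, d_dist = self._dist_term(X, grad)
        e_noe, d_noe = self._noe_term(X, grad)
        if w3 == 1.0:
            e_chir, d_chir = self._chir_term(X3, grad)
            e_dbl, d_dbl = self._dbl_term(X3, grad)
        else:
            g3 = np.zeros_like(X) if with_grad else None
            e_chir, d_chir = self._chir_term(X3, g3)
            e_dbl, d_dbl = self._dbl_term(X3, g3)
            e_chir, e_dbl = w3 * e_chir, w3 * e_dbl
            if with_grad:
                grad += w3 * g3
        if w_rdc == 1.0:
            e_rdc, d_rdc, fits = self._rdc_term(X3, grad)
        else:
            gr = np.zeros_like(X) if with_grad else None
            e_rdc, d_rdc, fits = self._rdc_term(X3, gr)
            e_rdc = w_rdc * e_rdc
            if with_grad:
                grad += w_rdc * gr

        bd = EnergyBreakdown(
            e_dist=e_dist, e_chir=e_chir, e_noe=e_noe, e_rdc=e_rdc, e_dbl=e_dbl,
            violations={
                "dist": d_dist, "noe": d_noe, "chir": d_chir,
                "dbl": d_dbl, "rdc": d_rdc, "rdc_fits": fits,
            },
        )
        return (bd, grad) if with_grad else bd


def total_energy(
    coords: np.ndarray,
    bounds: DistanceBounds,
    restraints: RestraintSet,
    fc: ForceConstants | None = None,
    torsions=None,
) -> EnergyBreakdown:
    model = PseudoEnergy(bounds, restraints, fc)
    if torsions is not None:
        model.set_torsions(torsions)
    return model.evaluate(coords)


def gradient(
    coords: np.ndarray,
    bounds: DistanceBounds,
    restraints: RestraintSet,
    fc: ForceConstants | None = None,
    torsions=None,
) -> np.ndarray:
    model = PseudoEnergy(bounds, restraints, fc)
    if torsions is not None:
        model.set_torsions(torsions)
    _, g = model.evaluate(coords, with_grad=True)
    return g
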