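"""Alignment (Saupe) tensor fits for residual dipolar couplings.

A one-bond C-H RDC back-calculates from a structure as

    D_calc = d_max(r) * u^T S u,

where ``u`` is the unit C->H bond vector, ``S`` the traceless symmetric 3x3
order matrix of the medium, and ``d_max(r) = -mu0 gammaC gammaH hbar /
(8 pi^2 r^3)`` the dipolar interaction constant at the instantaneous bond
length ``r`` -- natural constants only, no adjustable parameters.  The five
independent elements of ``S`` are obtained per medium as the minimal-norm
least-squares solution of the linear design system via SVD.

Tensor basis convention (internal, used consistently everywhere):
``s = (S_xx, S_yy, S_xy, S_xz, S_yz)`` with ``S_zz = -S_xx - S_yy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Natural constants (SI): mu0, hbar, gyromagnetic ratios of 1H and 13C.
_MU0 = 1.25663706212e-6
_HBAR = 1.054571817e-34
_GAMMA_H = 2.6752218744e8
_GAMMA_C = 6.728284e7

#: d_max prefactor in Hz*Angstrom^3: D = DCC / r^3 * u^T S u  (r in Angstrom)
DIPOLAR_CH = -_MU0 * _GAMMA_H * _GAMMA_C * _HBAR / (8.0 * np.pi ** 2) * 1e30

#: standard C-H bond length used when no geometry is available
R_CH_DEFAULT = 1.09


class AlignError(ValueError):
    pass


@dataclass
class AlignmentTensor:
    s5: np.ndarray          # the 5 independent elements
    residual: float         # ||A s - d||
    condition: float        # condition number of the design matrix

    @property
    def matrix(self) -> np.ndarray:
        s0, s1, s2, s3, s4 = self.s5
        return np.array([[s0, s2, s3], [s2, s1, s4], [s3, s4, -s0 - s1]])


@dataclass
class RdcFitResult:
    d_calc: np.ndarray
    delta: np.ndarray       # d_exp - d_calc
    q: float
    tensor: AlignmentTensor
    design: np.ndarray      # (n_restraints, 5) design matrix
    d_exp: np.ndarray


def d_max(r_ch: float | np.ndarray = R_CH_DEFAULT) -> float | np.ndarray:
    """Dipolar interaction constant (Hz) for a C-H pair at distance r (Angstrom)."""
    return DIPOLAR_CH / np.asarray(r_ch, dtype=float) ** 3


def design_row(unit_vector: np.ndarray, dmax: float) -> np.ndarray:
    """Row mapping the 5 tensor elements onto D_calc for one C-H vector."""
    u = np.asarray(unit_vector, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm < 1e-12:
        raise AlignError("zero-length bond vector")
    ux, uy, uz = u / nrm
    return dmax * np.array(
        [ux * ux - uz * uz, uy * uy - uz * uz, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz]
    )


def back_calculate(s5: np.ndarray, unit_vector: np.ndarray, dmax: float) -> float:
    return float(design_row(unit_vector, dmax) @ s5)


def _build_design(vectors, modes, dmaxes) -> np.ndarray:
    rows = []
    for k, v in enumerate(vectors):
        dm = dmaxes[k]
        if modes is not None and modes[k] == "methylene_sum":
            va, vb = v
            dma, dmb = dm if np.ndim(dm) else (dm, dm)
            rows.append(design_row(va, dma) + design_row(vb, dmb))
        else:
            rows.append(design_row(v, dm))
    return np.array(rows)


def fit_alignment_tensor(
    vectors,
    d_exp,
    modes: list[str] | None = None,
    dmaxes=None,
) -> RdcFitResult:
    """Minimal-norm least-squares Saupe tensor via SVD.

    ``vectors``: unit 3-vectors, or (for ``methylene_sum`` entries of
    ``modes``) pairs of two vectors whose design rows are summed.
    ``dmaxes``: per-entry dipolar constants (default: 1.09 Angstrom C-H).
    """
    d_exp = np.asarray(d_exp, dtype=float)
    if d_exp.size == 0:
        raise AlignError("need at least one RDC restraint")
    if dmaxes is None:
        dmaxes = [d_max()] * len(d_exp)
    A = _build_design(vectors, modes, dmaxes)
    if np.allclose(A, 0.0):
        raise AlignError("no orientational information (all-zero design matrix)")
    s5, _, rank, sv = np.linalg.lstsq(A, d_exp, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    d_calc = A @ s5
    delta = d_exp - d_calc
    tensor = AlignmentTensor(s5=s5, residual=float(np.linalg.norm(delta)), condition=cond)
    return RdcFitResult(
        d_calc=d_calc,
        delta=delta,
        q=q_factor(d_exp, d_calc) if np.any(d_exp) else 0.0,
        tensor=tensor,
        design=A,
        d_exp=d_exp,
    )


def q_factor(d_exp, d_calc) -> float:
    """Quality factor sqrt(sum (Dexp-Dcalc)^2 / sum Dexp^2)."""
    d_exp = np.asarray(d_exp, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_exp.size == 0 or d_exp.size != d_calc.size:
        raise AlignError("q_factor needs equal-length, non-empty inputs")
    denom = float(np.sum(d_exp ** 2))
    if denom == 0.0:
        raise AlignError("q_factor undefined for all-zero experimental RDCs")
    return float(np.sqrt(np.sum((d_exp - d_calc) ** 2) / denom))


def bootstrap_tensor_errors(
    fit: RdcFitResult, n_draws: int = 200, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo bootstrap error bars on back-calculated RDCs.

    Restraints are resampled with replacement ``n_draws`` times, the tensor is
    refit for each draw, and the standard deviation of the back-calculated
    RDCs (over draws, on the full original design) is returned.
    """
    if n_draws < 2:
        raise AlignError("bootstrap requires n_draws >= 2")
    n = fit.d_exp.size
    if n < 2:
        raise AlignError("bootstrap requires >= 2 restraints")
    rng = np.random.default_rng(seed)
    samples = np.empty((n_draws, n))
    for t in range(n_draws):
        idx = rng.integers(0, n, size=n)
        s5, *_ = np.linalg.lstsq(fit.design[idx], fit.d_exp[idx], rcond=None)
        samples[t] = fit.design @ s5
    return samples.std(axis=0, ddof=1)


def random_tensor(rng: np.random.Generator, magnitude: float = 1e-3,
                  rhombicity: float | None = None) -> np.ndarray:
    """A random physically valid (traceless symmetric) order matrix.

    Principal values have axial component ``magnitude`` and rhombicity drawn
    uniformly in [0, 2/3] unless given; the principal axis frame is a random
    rotation.  Returned as a full 3x3 matrix.
    """
    from scipy.spatial.transform import Rotation

    eta = rng.uniform(0.0, 2.0 / 3.0) if rhombicity is None else rhombicity
    azz = magnitude
    axx = -azz / 2.0 * (1.0 - 1.5 * eta)
    ayy = -azz / 2.0 * (1.0 + 1.5 * eta)
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2 ** 31))).as_matrix()
    return R @ np.diag([axx, ayy, azz]) @ R.T


def tensor_to_s5(S: np.ndarray) -> np.ndarray:
    return np.array([S[0, 0], S[1, 1], S[0, 1], S[0, 2], S[1, 2]])
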