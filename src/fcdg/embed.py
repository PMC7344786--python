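"""Metrization of the distance bounds and metric-matrix embedding into 4D.

Trial structures are generated by (i) *partial metrization* -- randomly
sampling a subset of pairwise distances uniformly within their current
bounds, re-smoothing the bounds through each sampled pair so later picks stay
consistent with earlier ones, and fixing the remaining distances at the
midpoint of their bounds -- and (ii) classical metric-matrix embedding of the
resulting distance matrix into four dimensions.  Sampling distances (rather
than coordinates) is what makes every relative configuration reachable: the
chirality of each center is implicit in the distance matrix and is drawn at
random, which is the engine of the floating-chirality approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyBreakdown
from .molgraph import DistanceBounds, InfeasibleBoundsError

STAGES = ("embedded4d", "annealed4d", "projected3d", "annealed3d", "minimized")


@dataclass
class Conformer:
    coords: np.ndarray                     # (N, D), D in {3, 4}
    velocities: np.ndarray | None = None
    energy: EnergyBreakdown | None = None
    seed: int = 0
    stage: str = "embedded4d"
    failed: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def advanced(self, coords, stage, **kw) -> "Conformer":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage may not move backwards: {self.stage} -> {stage}")
        return Conformer(coords=coords, seed=self.seed, stage=stage,
                         failed=self.failed, meta=dict(self.meta), **kw)


def metrize(
    bounds: DistanceBounds, seed: int, n_sample: int | None = None
) -> np.ndarray:
    """Sample a full distance matrix inside the (smoothed) bounds.

    ``n_sample`` pairs (default 4N) are drawn in random order, each fixed
    uniformly within its current interval, and the bounds are re-smoothed
    through the fixed pair; all remaining entries are set to the midpoint of
    their surviving bounds.  Deterministic per seed.
    """
    l = bounds.lower.copy()
    u = bounds.upper.copy()
    n = l.shape[0]
    if np.any(l > u + 1e-9):
        i, j = np.argwhere(l > u + 1e-9)[0]
        raise InfeasibleBoundsError(int(i), int(j), float(l[i, j]), float(u[i, j]))
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    order = rng.permutation(iu[0].size)
    if n_sample is None:
        n_sample = min(4 * n, order.size)
    for p in order[:n_sample]:
        i, j = int(iu[0][p]), int(iu[1][p])
        lo, hi = l[i, j], u[i, j]
        d = rng.uniform(lo, hi) if hi > lo else lo
        l[i, j] = l[j, i] = u[i, j] = u[j, i] = d
        # re-smooth through the fixed pair only (partial metrization)
        for k in (i, j):
            u = np.minimum(u, u[:, k, None] + u[None, k, :])
            l = np.maximum(l, l[:, k, None] - u[None, k, :])
            l = np.maximum(l, l[None, k, :] - u[:, k, None])
        l = np.minimum(l, u)
    d = 0.5 * (l + u)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def embed_4d(dmatrix: np.ndarray) -> Conformer:
    """Classical metric-matrix (Gram) embedding into 4 dimensions.

    The squared-distance matrix is double-centered to a Gram matrix whose top
    four non-negative eigenvalues give the coordinates; negative eigenvalues
    (non-Euclidean input) are truncated to zero.  Exact when the input is
    4D-Euclidean.
    """
    d2 = np.asarray(dmatrix, dtype=float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ d2 @ J
    w, V = np.linalg.eigh(G)
    idx = np.argsort(w)[::-1][: min(4, n)]
    w4 = np.clip(w[idx], 0.0, None)
    coords = np.zeros((n, 4))
    coords[:, : idx.size] = V[:, idx] * np.sqrt(w4)[None, :]
    return Conformer(coords=coords, stage="embedded4d")


def pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))
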