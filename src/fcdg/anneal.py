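"""Distance-bounds-driven dynamics: simulated annealing and minimization.

The pseudo-energy gradients are interpreted as forces on unit-mass atoms and
integrated with velocity Verlet under a per-step velocity-rescaling
thermostat.  A 4D annealing stage samples configurations (inversions are
rotations through the fourth dimension), while a temperature-dependent
restoring force

    F_w = -f(T) * k_w * w,     f(T) = exp(-(T / tau_T)^2)

acting on the (centered) fourth coordinate gradually compresses the fourth
dimension to zero extent as the system cools; the chirality, planarity and
RDC terms are evaluated in the leading three coordinates, so the structure
anneals onto its own eventual 3D projection while inversions remain simple
rotations through the fourth dimension while hot.  The 4D stage concludes
with a gradient minimization under the full-strength compression potential;
after projection to 3D (along the least-extent inertia eigenvector, which by
then coincides with the compressed coordinate), annealing is repeated in 3D
and each structure is finished by a gradient minimization of the total
pseudo energy.

Internal unit conventions (the pseudo energy is dimensionless, so these only
fix time and temperature scales; they are package constants reported in run
metadata): unit atomic masses; Boltzmann constant ``KB = 0.1`` pseudo-energy
units per Kelvin, so the per-degree-of-freedom kinetic energy at 300 K is 15
-- an order of magnitude above typical single-restraint violation energies,
hot enough to cross fold-defect barriers during equilibration; one
femtosecond of schedule time equals 0.01 internal time units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .embed import Conformer

KB = 0.1           # pseudo-energy units per K
TIME_PER_FS = 0.01  # internal time units per femtosecond
DEFAULT_KW = 1.0   # 4th-dimension compression force constant (per Angstrom)
FORCE_CLAMP = 100.0  # per-atom force-norm cap during dynamics


@dataclass
class AnnealSchedule:
    """Equilibration + linear-cooling schedule (published protocol defaults)."""

    n_equil: int = 5000
    n_cool: int = 5000
    dt: float = 2.0        # fs
    t_start: float = 300.0  # K
    tau_t: float = 150.0    # K

    def __post_init__(self):
        if min(self.n_equil, self.n_cool) < 0 or self.dt <= 0 or self.t_start <= 0:
            raise ValueError("schedule parameters must be positive")

    def temperature(self, step: int) -> float:
        if step < self.n_equil:
            return self.t_start
        frac = (step - self.n_equil + 1) / max(self.n_cool, 1)
        return self.t_start * max(0.0, 1.0 - frac)


def compression_factor(t: float, tau_t: float = 150.0) -> float:
    """Scaling f = exp(-(T/tau_T)^2) of the 4D compression force: ~0 while
    hot (structures evolve freely), -> 1 as T -> 0 (full compression)."""
    return float(np.exp(-((t / tau_t) ** 2)))


def compression_axis(coords: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the inertia tensor (unit masses, centered
    coordinates) with the largest eigenvalue: the direction of least spatial
    extent, whose removal best preserves interatomic distances."""
    X = coords - coords.mean(axis=0)
    if np.allclose(X, 0.0):
        raise ValueError("all atoms coincident; inertia tensor degenerate")
    dim = X.shape[1]
    I = np.trace(X.T @ X) * np.eye(dim) - X.T @ X
    w, V = np.linalg.eigh(I)
    axis = V[:, -1]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis


def _kinetic(v: np.ndarray) -> float:
    return 0.5 * float((v ** 2).sum())


class Compressed4D:
    """Energy model wrapper adding the full-strength (f=1) 4D compression
    potential 1/2 k_w sum w_k^2 on the centered 4th coordinate.  Used to
    quench the fourth dimension at the end of 4D annealing, so that the
    annealed structure converges onto its own 3D projection.  ``w3`` scales
    the 3D-subspace restraint terms, so a staged quench can keep them soft
    while the structure still extends into the fourth dimension."""

    def __init__(self, model, k_w: float = DEFAULT_KW, w3: float = 1.0):
        self.model = model
        self.k_w = k_w
        self.w3 = w3

    def evaluate(self, coords, with_grad: bool = False):
        out = self.model.evaluate(coords, with_grad=with_grad, w3=self.w3)
        bd, grad = out if with_grad else (out, None)
        w = coords[:, 3] - coords[:, 3].mean()
        bd = replace(bd, e_dist=bd.e_dist + 0.5 * self.k_w * float(w @ w))
        if with_grad:
            grad = grad.copy()
            grad[:, 3] += self.k_w * w
            return bd, grad
        return bd


def run_annealing(
    conf: Conformer,
    stage: str,
    schedule: AnnealSchedule,
    model,
    seed: int,
    k_w: float = DEFAULT_KW,
    thermostat: bool = True,
    _dt_scale: float = 1.0,
) -> Conformer:
    """Simulated annealing of one conformer in 4D or 3D.

    ``stage`` is ``"4d"`` or ``"3d"`` and must match the conformer dimension.
    In 4D the compression force along the (per-step recomputed) inertia axis
    is added.  On integration blow-up the run restarts once with half the
    time step; a second blow-up marks the structure failed.
    """
    if stage not in ("4d", "3d"):
        raise ValueError("stage must be '4d' or '3d'")
    if (stage == "4d") != (conf.dim == 4):
        raise ValueError(f"conformer dimension {conf.dim} does not match stage {stage}")

    rng = np.random.default_rng(seed)
    x = conf.coords - conf.coords.mean(axis=0)
    v = rng.normal(0.0, np.sqrt(KB * schedule.t_start), size=x.shape)
    dt = schedule.dt * TIME_PER_FS * _dt_scale
    n_steps = schedule.n_equil + schedule.n_cool
    ndof = x.size

    def force(xx, t):
        fT = compression_factor(t, schedule.tau_t)
        if stage == "4d":
            # 3D-subspace terms (chirality, planarity, RDC) ramp in with the
            # compression factor: while hot and 4D-extended they are
            # meaningless on the 3D projection and only frustrate the
            # distance-driven evolution ("structures evolve freely" at high T)
            _, g = model.evaluate(xx, with_grad=True, w3=fT)
        else:
            # in 3D the geometric terms stay at full strength but the stiff
            # RDC forces ramp in with f(T): the conformational search is
            # distance-driven while hot, and the alignment terms engage as
            # the structure cools (full strength in the final minimization)
            _, g = model.evaluate(xx, with_grad=True, w_rdc=fT)
        f = -g
        if stage == "4d":
            # restrain the 4th coordinate directly: the model's restraint
            # terms live in the leading-3-coordinate subspace, so compressing
            # w makes the structure converge onto its own 3D projection
            w_comp = xx[:, 3] - xx[:, 3].mean()
            f[:, 3] -= fT * k_w * w_comp
        # clamp per-atom force norms: stiff terms (RDCs in Hz^2) otherwise
        # destabilize the integrator on badly violated structures; the final
        # minimization handles the stiff regime exactly
        fn = np.sqrt((f ** 2).sum(1))
        over = fn > FORCE_CLAMP
        if np.any(over):
            f[over] *= (FORCE_CLAMP / fn[over])[:, None]
        return f

    f = force(x, schedule.temperature(0))
    for step in range(n_steps):
        t_now = schedule.temperature(step)
        v_half = v + 0.5 * dt * f
        x = x + dt * v_half
        if not np.all(np.isfinite(x)) or np.abs(x).max() > 1e4:
            if _dt_scale == 1.0:
                return run_annealing(conf, stage, schedule, model, seed,
                                     k_w=k_w, thermostat=thermostat, _dt_scale=0.5)
            out = conf.advanced(conf.coords, "annealed4d" if stage == "4d" else "annealed3d")
            out.failed = True
            return out
        f = force(x, t_now)
        v = v_half + 0.5 * dt * f
        if thermostat:
            ke_target = 0.5 * ndof * KB * t_now
            ke = _kinetic(v)
            if ke > 1e-12:
                v *= np.sqrt(max(ke_target, 0.0) / ke)
            elif ke_target > 0:
                v = rng.normal(0.0, np.sqrt(KB * t_now), size=x.shape)

    new_stage = "annealed4d" if stage == "4d" else "annealed3d"
    energy = model.evaluate(x)
    return conf.advanced(x, new_stage, velocities=v, energy=energy)


def project_to_3d(conf: Conformer, fix_restraint=None) -> Conformer:
    """Project a 4D conformer to 3D along the largest-eigenvalue inertia axis.

    The retained axes are the three remaining inertia eigenvectors (a proper
    4D rotation followed by dropping the compressed coordinate), which
    preserves interatomic distances at least as well as removal of any other
    eigenvector.  If ``fix_restraint`` (a fixed-stereocenter chiral restraint)
    is given and the projected structure lands on the wrong side of that
    single restrained center, the mirror image is taken instead -- the 3D
    enantiomer choice is a free gauge that the fixed center pins down.
    """
    if conf.dim != 4:
        raise ValueError("project_to_3d expects a 4D conformer")
    X = conf.coords - conf.coords.mean(axis=0)
    I = np.trace(X.T @ X) * np.eye(4) - X.T @ X
    w, V = np.linalg.eigh(I)
    basis = V[:, :3]
    if np.linalg.det(V) < 0:
        basis = basis.copy()
        basis[:, 2] = -basis[:, 2]
    coords3 = X @ basis
    if fix_restraint is not None:
        q = fix_restraint.substituents
        p = coords3[list(q)]
        vol = float((p[1] - p[0]) @ np.cross(p[2] - p[0], p[3] - p[0]))
        if vol * fix_restraint.target_volume < 0:
            coords3 = coords3.copy()
            coords3[:, 2] = -coords3[:, 2]
    return conf.advanced(coords3, "projected3d")


def minimize(
    conf: Conformer,
    model,
    tol: float = 1e-6,
    max_steps: int = 10_000,
    stage_out: str | None = "minimized",
) -> Conformer:
    """Gradient-based descent of the total pseudo energy (L-BFGS-B with the
    analytic gradient; line searches only ever accept energy decreases, so the
    reported energy is monotone non-increasing relative to the start).

    Stops when the largest gradient component drops below ``tol`` or after
    ``max_steps`` iterations (then flagged ``unconverged`` in ``meta``).
    """
    from scipy.optimize import minimize as _sp_minimize

    shape = conf.coords.shape
    e0 = model.evaluate(conf.coords).e_total

    def fun(flat):
        bd, g = model.evaluate(flat.reshape(shape), with_grad=True)
        return bd.e_total, g.ravel()

    res = _sp_minimize(
        fun, conf.coords.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": tol, "ftol": 1e-14,
                 "maxcor": 20},
    )
    x = res.x.reshape(shape)
    bd = model.evaluate(x)
    if bd.e_total > e0:  # line-search pathologies never get to raise the energy
        x = conf.coords.copy()
        bd = model.evaluate(x)
    out = conf.advanced(x, stage_out or conf.stage, energy=bd)
    g_final = np.abs(model.evaluate(x, with_grad=True)[1]).max()
    out.meta["unconverged"] = bool(g_final >= tol and res.nit >= max_steps)
    return out
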