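"""Annealing schedule, 4D compression, projection and minimization."""

import numpy as np
import pytest

from fcdg.anneal import (
    AnnealSchedule,
    Compressed4D,
    compression_axis,
    compression_factor,
    minimize,
    project_to_3d,
    run_annealing,
)
from fcdg.embed import Conformer, embed_4d, metrize, pair_distances


def test_compression_factor_values():
    assert compression_factor(0.0) == pytest.approx(1.0)
    assert compression_factor(150.0, 150.0) == pytest.approx(np.exp(-1.0))
    assert compression_factor(300.0, 150.0) == pytest.approx(np.exp(-4.0))
    for t in (0.0, 75.0, 600.0):
        assert 0.0 < compression_factor(t) <= 1.0


def test_schedule_defaults_and_temperature_ramp():
    s = AnnealSchedule()
    assert (s.n_equil, s.n_cool, s.dt, s.t_start, s.tau_t) == (5000, 5000, 2.0, 300.0, 150.0)
    assert s.temperature(0) == 300.0
    assert s.temperature(4999) == 300.0
    assert s.temperature(9999) == pytest.approx(0.0)
    mid = s.temperature(7499)
    assert 140.0 < mid < 160.0  # linear cooling ramp
    with pytest.raises(ValueError):
        AnnealSchedule(dt=-1.0)


def test_compression_axis_flat_cloud():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (50, 4))
    X[:, 3] *= 0.01  # tiny extent along w
    axis = compression_axis(X)
    assert abs(axis[3]) > 0.999


def test_compression_axis_oracle_largest_inertia_eigenvalue():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (20, 4)) * np.array([2.0, 1.0, 0.5, 0.1])
    Xc = X - X.mean(0)
    I = np.trace(Xc.T @ Xc) * np.eye(4) - Xc.T @ Xc
    w, V = np.linalg.eigh(I)
    axis = compression_axis(X)
    assert abs(axis @ V[:, -1]) == pytest.approx(1.0, abs=1e-10)


def test_compression_axis_two_point_system():
    X = np.array([[0.0, 0, 0, 0], [1.0, 0, 0, 0]])
    axis = compression_axis(X)
    # least extent: any direction orthogonal to the interatomic vector
    assert abs(axis[0]) < 1e-10
    with pytest.raises(ValueError):
        compression_axis(np.zeros((3, 4)))


def test_zero_temperature_annealing_leaves_minimum_alone(chain2):
    model = chain2.energy_model()
    X4 = np.hstack([chain2.true_geometry.coordinates, np.zeros((chain2.graph.n_atoms, 1))])
    conf = Conformer(X4.copy(), stage="embedded4d", seed=1)
    sched = AnnealSchedule(n_equil=50, n_cool=50, t_start=1e-15)
    out = run_annealing(conf, "4d", sched, model, seed=2)
    # centered comparison: dynamics never translates a zero-force structure
    a = out.coords - out.coords.mean(0)
    b = X4 - X4.mean(0)
    assert np.abs(a - b).max() < 1e-6


def test_annealing_dimension_mismatch_rejected(chain2):
    model = chain2.energy_model()
    conf = Conformer(chain2.true_geometry.coordinates.copy(), stage="projected3d")
    with pytest.raises(ValueError, match="dimension"):
        run_annealing(conf, "4d", AnnealSchedule(n_equil=1, n_cool=1), model, 0)


def test_annealing_deterministic_per_seed(chain2):
    model = chain2.energy_model()
    sched = AnnealSchedule(n_equil=60, n_cool=60)
    conf = embed_4d(metrize(chain2.bounds, 3))
    a = run_annealing(conf, "4d", sched, model, seed=11)
    b = run_annealing(conf, "4d", sched, model, seed=11)
    c = run_annealing(conf, "4d", sched, model, seed=12)
    np.testing.assert_array_equal(a.coords, b.coords)
    assert not np.allclose(a.coords, c.coords)


def test_w_extent_compressed_by_end_of_cooling(chain2):
    model = chain2.energy_model()
    conf = embed_4d(metrize(chain2.bounds, 7))
    sched = AnnealSchedule(n_equil=500, n_cool=1500)
    out = run_annealing(conf, "4d", sched, model, seed=8)
    for kw in (5.0, 50.0, 500.0):  # stiffening quench, as in the pipeline
        out = minimize(out, Compressed4D(model, k_w=kw), tol=1e-4,
                       max_steps=400, stage_out=None)
    w = out.coords[:, 3] - out.coords[:, 3].mean()
    assert np.sqrt(np.mean(w ** 2)) < 0.05


def test_energy_conservation_without_thermostat(chain2):
    """Velocity Verlet sanity: with the thermostat off, total (kinetic +
    pseudo) energy drifts < 1% per 1000 steps at dt = 2 fs."""
    from fcdg.anneal import KB, _kinetic

    model = chain2.energy_model()
    rng = np.random.default_rng(0)
    X = chain2.true_geometry.coordinates + rng.normal(0, 0.05, (chain2.graph.n_atoms, 3))
    conf = Conformer(X, stage="projected3d", seed=0)
    sched = AnnealSchedule(n_equil=1000, n_cool=0, t_start=30.0)
    out = run_annealing(conf, "3d", sched, model, seed=5, thermostat=False)
    e_end = out.energy.e_total + _kinetic(out.velocities)
    # reconstruct the initial total energy with the same velocity draw
    v0 = np.random.default_rng(5).normal(0, np.sqrt(KB * 30.0), X.shape)
    e_start = model.evaluate(X).e_total + _kinetic(v0)
    assert abs(e_end - e_start) / e_start < 0.01


def test_projection_preserves_zero_w_extent():
    rng = np.random.default_rng(2)
    X = rng.normal(0, 2, (15, 4))
    X[:, 3] = 0.42  # constant w: zero extent after centering
    conf = Conformer(X, stage="annealed4d")
    out = project_to_3d(conf)
    d4 = pair_distances(X)
    d3 = pair_distances(out.coords)
    np.testing.assert_allclose(d3, d4, atol=1e-10)


def test_projection_axis_beats_alternatives():
    # anisotropic clouds with a clearly smallest extent (the post-annealing
    # situation); the largest-eigenvalue inertia axis minimizes the summed
    # squared-distance distortion exactly, and on such clouds it also wins
    # in plain distance RMSD against the other three eigenvectors
    rng = np.random.default_rng(3)
    for _ in range(100):
        scales = np.array([rng.uniform(1.5, 2.5), rng.uniform(0.8, 1.2),
                           rng.uniform(0.4, 0.6), rng.uniform(0.05, 0.15)])
        X = rng.normal(0, 1, (12, 4)) * rng.permutation(scales)
        conf = Conformer(X, stage="annealed4d")
        out = project_to_3d(conf)
        d4 = pair_distances(X)
        rms_chosen = np.sqrt(np.mean((pair_distances(out.coords) - d4) ** 2))
        Xc = X - X.mean(0)
        I = np.trace(Xc.T @ Xc) * np.eye(4) - Xc.T @ Xc
        w, V = np.linalg.eigh(I)
        for k in range(3):  # the three non-chosen eigenvectors
            keep = [c for c in range(4) if c != k]
            alt = Xc @ V[:, keep]
            rms_alt = np.sqrt(np.mean((pair_distances(alt) - d4) ** 2))
            assert rms_chosen <= rms_alt + 1e-9


def test_projection_treats_mirror_pair_coherently(chain2):
    """A 3D slice of a 4D structure has no intrinsic handedness until the
    dropped axis is oriented: projections of a mirror pair are related by a
    *global* mirror or identity, never a partial sign change, and the fixed
    chiral restraint pins the gauge so both project to the same enantiomer."""
    from fcdg.molgraph import signed_volume

    fixr = next(c for c in chain2.restraints.chirals if c.kind == "fixed_stereocenter")
    quads = [chain2.graph.neighbors(c) for c in chain2.graph.stereocenters]
    for seed in range(5):
        conf = embed_4d(metrize(chain2.bounds, seed))
        mirror = Conformer(conf.coords * np.array([-1.0, 1, 1, 1]), stage="annealed4d")
        p = project_to_3d(Conformer(conf.coords, stage="annealed4d"))
        m = project_to_3d(mirror)
        ratios = [np.sign(signed_volume(p.coords, q) * signed_volume(m.coords, q))
                  for q in quads]
        assert len(set(ratios)) == 1  # global mirror or global identity
        pf = project_to_3d(Conformer(conf.coords, stage="annealed4d"), fix_restraint=fixr)
        mf = project_to_3d(mirror, fix_restraint=fixr)
        for q in quads:
            assert signed_volume(pf.coords, q) * signed_volume(mf.coords, q) > 0


def test_projection_mirror_fix_pins_fixed_center(chain2):
    from fcdg.molgraph import signed_volume

    fixr = next(c for c in chain2.restraints.chirals if c.kind == "fixed_stereocenter")
    for seed in range(6):
        conf = embed_4d(metrize(chain2.bounds, seed))
        conf.stage = "annealed4d"
        out = project_to_3d(conf, fix_restraint=fixr)
        v = signed_volume(out.coords, fixr.substituents)
        assert v * fixr.target_volume > 0


def test_minimize_zero_energy_structure_returns_immediately(chain2):
    model = chain2.energy_model()
    conf = Conformer(chain2.true_geometry.coordinates.copy(), stage="annealed3d")
    out = minimize(conf, model)
    assert out.energy.e_total == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(out.coords, conf.coords, atol=1e-9)


def test_minimize_restores_stretched_bond(chain2):
    model = chain2.energy_model()
    X = chain2.true_geometry.coordinates.copy()
    i, j, _ = chain2.graph.bonds[0]
    X[j] += 0.8 * (X[j] - X[i])  # stretch one bond far out of bounds
    conf = Conformer(X, stage="annealed3d")
    out = minimize(conf, model, tol=1e-8)
    assert out.energy.e_dist < 1e-10


def test_minimize_monotone_on_random_starts(chain2):
    model = chain2.energy_model()
    rng = np.random.default_rng(4)
    for _ in range(20):
        X = chain2.true_geometry.coordinates + rng.normal(0, 0.4, (chain2.graph.n_atoms, 3))
        e0 = model.evaluate(X).e_total
        out = minimize(Conformer(X, stage="annealed3d"), model, max_steps=300)
        assert out.energy.e_total <= e0 + 1e-12


def test_inversion_accessible_in_4d_annealing(chain2):
    """With no chiral restraint on a center, 4D annealing produces both
    volume signs across seeds (inversion = rotation through dimension 4)."""
    from fcdg.molgraph import signed_volume

    model = chain2.energy_model()
    quad = chain2.graph.neighbors(chain2.graph.stereocenters[1])
    sched = AnnealSchedule(n_equil=150, n_cool=150)
    signs = set()
    for seed in range(12):
        conf = embed_4d(metrize(chain2.bounds, seed))
        out = run_annealing(conf, "4d", sched, model, seed=seed + 100)
        v = signed_volume(out.coords[:, :3], quad)
        if abs(v) > 0.01:
            signs.add(np.sign(v))
        if len(signs) == 2:
            break
    assert signs == {1.0, -1.0}
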