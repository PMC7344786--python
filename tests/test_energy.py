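"""Pseudo-energy terms, composition and analytic gradients."""

import numpy as np
import pytest

from fcdg.energy import (
    ForceConstants,
    PseudoEnergy,
    chiral_volume,
    dbl_violation,
    noe_violation,
    penalty,
    total_energy,
)
from fcdg.molgraph import ReferenceGeometry, reference_chiral_volumes
from fcdg.restraints import NoeRestraint, RestraintSet

from conftest import random_feasible_coords


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def test_chiral_volume_unit_cases():
    o = np.zeros(3)
    ex, ey, ez = np.eye(3)
    assert chiral_volume(o, ex, ey, ez) == pytest.approx(1.0)
    assert chiral_volume(o, ex, ey, -ez) == pytest.approx(-1.0)
    assert chiral_volume(o, ex, ey, ex + ey) == pytest.approx(0.0)  # coplanar


def test_chiral_volume_symmetries():
    rng = np.random.default_rng(2)
    p = rng.normal(0, 1, (4, 3))
    v = chiral_volume(*p)
    # rotation + translation invariance
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
    q = p @ R.T + np.array([3.0, -1.0, 0.5])
    assert chiral_volume(*q) == pytest.approx(v)
    # reflection flips
    m = p * np.array([1, -1, 1])
    assert chiral_volume(*m) == pytest.approx(-v)
    # odd permutation flips
    assert chiral_volume(p[0], p[2], p[1], p[3]) == pytest.approx(-v)


@pytest.mark.parametrize(
    "r,lo,up,expected",
    [(2.6, 2.5, 3.0, 0.0), (2.0, 2.5, 3.0, -0.5), (3.2, 2.5, 3.0, 0.2)],
)
def test_noe_violation_piecewise(r, lo, up, expected):
    assert noe_violation(r, lo, up) == pytest.approx(expected)


def test_noe_violation_continuous_at_bounds():
    eps = 1e-9
    assert abs(noe_violation(2.5 - eps, 2.5, 3.0)) < 1e-8
    assert abs(noe_violation(3.0 + eps, 2.5, 3.0)) < 1e-8


def test_penalty_values_and_scaling():
    assert penalty([], 10.0) == 0.0
    assert penalty([-0.5], 10.0) == pytest.approx(1.25)
    assert penalty([1.0, 1.0, 1.0], 1.5 / 3) == pytest.approx(0.75)
    rng = np.random.default_rng(0)
    v = rng.normal(0, 1, 7)
    assert penalty(2 * v, 3.0) == pytest.approx(4 * penalty(v, 3.0))
    with pytest.raises(ValueError):
        penalty([1.0], -1.0)


def test_dbl_violation_values():
    assert dbl_violation(180.0) == pytest.approx(0.0)
    assert dbl_violation(0.0) == pytest.approx(0.0)
    assert dbl_violation(90.0) == pytest.approx(1.0)
    assert 0.5 * 100.0 * dbl_violation(90.0) ** 2 == pytest.approx(50.0)


def test_k_rdc_scales_with_media():
    fc = ForceConstants()
    assert fc.k_rdc(1) == pytest.approx(1.5)
    assert fc.k_rdc(3) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_feasible_reference_geometry_has_zero_energy(chain2):
    bd = chain2.energy_model().evaluate(chain2.true_geometry.coordinates)
    assert bd.e_total == pytest.approx(0.0, abs=1e-10)


def test_breakdown_sums_to_total(chain2):
    rng = np.random.default_rng(5)
    model = chain2.energy_model()
    bd = model.evaluate(random_feasible_coords(chain2, rng, 0.3))
    total = bd.e_dist + bd.e_chir + bd.e_noe + bd.e_rdc + bd.e_dbl
    assert bd.e_total == pytest.approx(total, rel=1e-12)
    assert all(v >= 0 for v in (bd.e_dist, bd.e_chir, bd.e_noe, bd.e_rdc, bd.e_dbl))


def test_single_noe_violation_energy(chain2):
    # geometry violating exactly one NOE by a known amount
    bounds = chain2.bounds
    X = chain2.true_geometry.coordinates
    noe = chain2.restraints.noes[0]
    rs = RestraintSet(noes=[noe])
    model = PseudoEnergy(bounds, rs)
    bd = model.evaluate(X)
    assert bd.e_noe == pytest.approx(0.0)
    # shrink the bounds so r_eff sits 0.5 A below the lower bound
    from fcdg.restraints import effective_noe_distance

    r_eff = effective_noe_distance(X, noe)
    tight = NoeRestraint(noe.group_i, noe.group_j, r_eff + 0.5, r_eff + 1.0)
    bd = PseudoEnergy(bounds, RestraintSet(noes=[tight])).evaluate(X)
    assert bd.e_noe == pytest.approx(0.5 * 10.0 * 0.25, rel=1e-6)  # 1.25


def test_mirror_image_violates_fixed_chiral_restraint(chain2):
    model = chain2.energy_model()
    X = chain2.true_geometry.coordinates
    mirror = X * np.array([1.0, 1.0, -1.0])
    bd = model.evaluate(mirror)
    fixed = next(c for c in chain2.restraints.chirals if c.kind == "fixed_stereocenter")
    v = fixed.target_volume
    # chir term >= the fixed-center contribution 1/2 k (2V)^2
    assert bd.e_chir >= 0.5 * 25.0 * (2 * v) ** 2 - 1e-6


def test_energy_rotation_translation_invariance(ring3):
    from scipy.spatial.transform import Rotation

    model = ring3.energy_model()
    rng = np.random.default_rng(8)
    X = random_feasible_coords(ring3, rng, 0.2)
    e0 = model.evaluate(X).e_total
    R = Rotation.from_euler("xyz", [0.2, 0.9, -1.3]).as_matrix()
    e1 = model.evaluate(X @ R.T + np.array([5.0, -2.0, 1.0])).e_total
    assert e1 == pytest.approx(e0, rel=1e-9)


# ---------------------------------------------------------------------------
# gradients vs finite differences
# ---------------------------------------------------------------------------

def _fd_check(model, X, h=1e-5, stride=1):
    """Max deviation between the analytic gradient and a Richardson-
    extrapolated central difference (h and h/2; truncation error O(h^4))."""
    bd, g = model.evaluate(X, with_grad=True)

    def central(i, d, step):
        Xp = X.copy(); Xp[i, d] += step
        Xm = X.copy(); Xm[i, d] -= step
        return (model.evaluate(Xp).e_total - model.evaluate(Xm).e_total) / (2 * step)

    err = 0.0
    for i in range(0, X.shape[0], stride):
        for d in range(X.shape[1]):
            num = (4.0 * central(i, d, h / 2) - central(i, d, h)) / 3.0
            err = max(err, abs(num - g[i, d]))
    return err


def test_gradient_zero_at_feasible_geometry(chain2):
    _, g = chain2.energy_model().evaluate(
        chain2.true_geometry.coordinates, with_grad=True
    )
    assert np.abs(g).max() == pytest.approx(0.0, abs=1e-12)


def test_gradient_matches_finite_differences_3d(chain2):
    rng = np.random.default_rng(3)
    X = random_feasible_coords(chain2, rng, 0.15)
    assert _fd_check(chain2.energy_model(), X) < 1e-6


def test_gradient_matches_finite_differences_4d(chain2):
    rng = np.random.default_rng(4)
    X3 = random_feasible_coords(chain2, rng, 0.15)
    X4 = np.hstack([X3, rng.normal(0, 0.3, (X3.shape[0], 1))])
    assert _fd_check(chain2.energy_model(), X4) < 1e-6


def test_gradient_with_rdc_and_dbl_terms(tmp_path):
    # molecule with an sp2-sp2 torsion plus RDCs: exercises every term
    from fcdg.synthdata import make_fixture, simulate_rdcs
    from conftest import mol_from_smiles
    from fcdg.molgraph import from_rdkit, holonomic_bounds, smooth_bounds

    fix = make_fixture("ring3", seed=2)
    fix.restraints.rdcs = simulate_rdcs(fix, n_media=2, seed=9)
    model = fix.energy_model()
    rng = np.random.default_rng(6)
    X = fix.true_geometry.coordinates + rng.normal(0, 0.08, (fix.graph.n_atoms, 3))
    assert _fd_check(model, X, stride=3) < 1e-6

    graph, geom = from_rdkit(mol_from_smiles("C/C=C/CO"))
    bounds = smooth_bounds(holonomic_bounds(graph, geom))
    chirals = reference_chiral_volumes(graph, geom, [])
    model = PseudoEnergy(bounds, RestraintSet(chirals=chirals))
    model.set_torsions(graph.planar_groups)
    X = geom.coordinates + rng.normal(0, 0.1, geom.coordinates.shape)
    bd = model.evaluate(X)
    assert bd.e_dbl > 0  # perturbed double bond is non-planar
    assert _fd_check(model, X) < 1e-6


def test_noe_gradient_is_local(chain2):
    X = chain2.true_geometry.coordinates.copy()
    noe = chain2.restraints.noes[0]
    from fcdg.restraints import effective_noe_distance

    r_eff = effective_noe_distance(X, noe)
    tight = NoeRestraint(noe.group_i, noe.group_j, r_eff + 0.5, r_eff + 1.0)
    model = PseudoEnergy(chain2.bounds, RestraintSet(noes=[tight]))
    _, g = model.evaluate(X, with_grad=True)
    involved = set(tight.group_i) | set(tight.group_j)
    for i in range(X.shape[0]):
        if i in involved:
            assert np.abs(g[i]).max() > 1e-8
        else:
            assert np.abs(g[i]).max() < 1e-12


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

try:
    from hypothesis import given, settings, strategies as st

    coords3 = st.lists(
        st.tuples(*[st.floats(-5, 5, allow_nan=False, width=32)] * 3),
        min_size=4, max_size=4,
    )

    @given(coords3)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_chiral_volume_reflection_antisymmetry_property(pts):
        p = np.asarray(pts, dtype=float)
        v = chiral_volume(*p)
        v_m = chiral_volume(*(p * np.array([1.0, 1.0, -1.0])))
        assert v_m == pytest.approx(-v, abs=1e-6)

    @given(st.lists(st.floats(-10, 10, allow_nan=False), max_size=12),
           st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_penalty_quadratic_scaling_property(deltas, k):
        v = np.asarray(deltas, dtype=float)
        assert penalty(2.0 * v, k) == pytest.approx(4.0 * penalty(v, k), rel=1e-9)
        assert penalty(v, k) >= 0.0

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
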