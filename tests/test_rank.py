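"""Configuration fingerprints, ensemble ranking and confidence tables."""

import numpy as np
import pytest

from fcdg.embed import Conformer
from fcdg.energy import EnergyBreakdown
from fcdg.rank import (
    ConfigFingerprint,
    center_confidence,
    fingerprint,
    rank_ensemble,
)


def _conf(fix, coords, seed=0, e=0.0):
    c = Conformer(coords.copy(), stage="minimized", seed=seed)
    c.energy = EnergyBreakdown(e_noe=e)
    return c


def test_fingerprint_requires_minimized_stage(chain2):
    c = Conformer(chain2.true_geometry.coordinates.copy(), stage="projected3d")
    with pytest.raises(ValueError, match="minimized"):
        fingerprint(c, chain2.graph)


def test_fingerprint_mirror_is_elementwise_negation(ring3):
    X = ring3.true_geometry.coordinates
    fp = fingerprint(_conf(ring3, X), ring3.graph, fixed_centers=[ring3.fixed_center])
    fp_m = fingerprint(_conf(ring3, X * np.array([1, -1, 1.0])), ring3.graph,
                       fixed_centers=[ring3.fixed_center])
    assert fp_m.stereo_signs == tuple(-s for s in fp.stereo_signs)
    assert fp_m.prochiral_signs == tuple(-s for s in fp.prochiral_signs)
    assert fp_m == fp.mirror()


def test_fingerprint_rigid_motion_invariant(ring3):
    from scipy.spatial.transform import Rotation

    X = ring3.true_geometry.coordinates
    R = Rotation.from_euler("xyz", [0.5, -0.2, 1.7]).as_matrix()
    fp0 = fingerprint(_conf(ring3, X), ring3.graph, fixed_centers=[ring3.fixed_center])
    fp1 = fingerprint(_conf(ring3, X @ R.T + 3.0), ring3.graph,
                      fixed_centers=[ring3.fixed_center])
    assert fp0 == fp1


def test_fingerprint_conformers_of_one_diastereomer_agree(ring3):
    """Small conformational perturbations never change volume signs at
    well-formed tetrahedral centers."""
    rng = np.random.default_rng(1)
    X = ring3.true_geometry.coordinates
    fp0 = fingerprint(_conf(ring3, X), ring3.graph, fixed_centers=[ring3.fixed_center])
    for _ in range(10):
        fp = fingerprint(_conf(ring3, X + rng.normal(0, 0.05, X.shape)),
                         ring3.graph, fixed_centers=[ring3.fixed_center])
        assert fp.class_key == fp0.class_key


def test_fingerprint_length_covers_floating_and_prochiral():
    from fcdg.synthdata import make_fixture

    fix = make_fixture("pia8", seed=1)
    fp = fix.true_fingerprint
    # 8 stereocenters, one fixed -> 7 floating, plus prochiral CH2 centers
    assert len(fp.stereo_signs) == 7
    assert len(fp.prochiral_signs) == len(fix.graph.prochiral_centers)
    assert 0 not in fp.stereo_signs


def test_degenerate_volume_flagged(chain2):
    X = chain2.true_geometry.coordinates.copy()
    center = [c for c in chain2.graph.stereocenters if c != chain2.fixed_center][0]
    quad = chain2.graph.neighbors(center)
    # flatten the center: project its substituents onto their best-fit plane
    pts = X[quad]
    centroid = pts.mean(0)
    _, _, vt = np.linalg.svd(pts - centroid)
    X[quad] = centroid + (pts - centroid) @ vt[:2].T @ vt[:2]
    X[center] = centroid
    fp = fingerprint(_conf(chain2, X), chain2.graph, fixed_centers=[chain2.fixed_center])
    assert 0 in fp.stereo_signs and fp.degenerate


def _synthetic_ensemble(fix, energies, classes, pro=None):
    """Build minimized conformers from the true/flipped geometries with
    assigned energies; classes are 'A' (true) or 'B' (mirror)."""
    X = fix.true_geometry.coordinates
    out = []
    for i, (e, cls) in enumerate(zip(energies, classes)):
        coords = X if cls == "A" else X * np.array([1.0, 1.0, -1.0])
        c = _conf(fix, coords, seed=i, e=e)
        out.append(c)
    return out


def test_rank_ensemble_hand_trace(chain2):
    confs = _synthetic_ensemble(chain2, [1.0, 2.0, 3.0, 4.0], "AABA")
    ref = chain2.true_fingerprint
    rep = rank_ensemble(confs, chain2.graph, reference=ref,
                        fixed_centers=[chain2.fixed_center])
    assert [s.e_total for s in rep.structures] == [1.0, 2.0, 3.0, 4.0]
    assert rep.first_wrong_index == 3
    assert rep.delta_e_gap == pytest.approx(2.0)  # 3 - 1
    assert rep.class_counts[ref.class_key] == 3


def test_rank_single_class_has_no_wrong_index(chain2):
    confs = _synthetic_ensemble(chain2, [1.0, 1.5], "AA")
    rep = rank_ensemble(confs, chain2.graph, reference=chain2.true_fingerprint,
                        fixed_centers=[chain2.fixed_center])
    assert rep.first_wrong_index is None
    assert rep.delta_e_gap is None
    assert sum(rep.class_counts.values()) == 2


def test_rank_tie_break_by_seed_and_duplicate_invariance(chain2):
    confs = _synthetic_ensemble(chain2, [2.0, 2.0, 1.0], "ABA")
    rep = rank_ensemble(confs, chain2.graph, reference=chain2.true_fingerprint,
                        fixed_centers=[chain2.fixed_center])
    assert [s.seed for s in rep.structures] == [2, 0, 1]
    # duplicating a structure within a class leaves first_wrong unchanged
    confs2 = _synthetic_ensemble(chain2, [2.0, 2.0, 1.0, 1.0], "ABAA")
    rep2 = rank_ensemble(confs2, chain2.graph, reference=chain2.true_fingerprint,
                         fixed_centers=[chain2.fixed_center])
    assert rep2.structures[rep2.first_wrong_index - 1].fp.class_key == \
           rep.structures[rep.first_wrong_index - 1].fp.class_key


def test_empty_ensemble_raises(chain2):
    with pytest.raises(ValueError):
        rank_ensemble([], chain2.graph)


def test_prochiral_only_change_reported_separately(ring3):
    """A structure differing only in a CH2 proton assignment is a
    pseudo-configurational change, not the first wrong structure."""
    X = ring3.true_geometry.coordinates
    pro = ring3.graph.prochiral_centers[0]
    h1, h2 = ring3.graph.hydrogens_on(pro)
    X_swap = X.copy()
    X_swap[[h1, h2]] = X_swap[[h2, h1]]  # swap the two methylene protons
    confs = [
        _conf(ring3, X, seed=0, e=1.0),
        _conf(ring3, X_swap, seed=1, e=2.0),
        _conf(ring3, X * np.array([1.0, 1.0, -1.0]), seed=2, e=3.0),
    ]
    rep = rank_ensemble(confs, ring3.graph, reference=ring3.true_fingerprint,
                        fixed_centers=[ring3.fixed_center])
    assert rep.first_pseudo_index == 2
    assert rep.first_wrong_index == 3


def test_no_two_classes_are_global_mirrors(chain2):
    """With one fixed chiral restraint, the reported classes never include a
    global-enantiomer pair (signs include the fixed-center context)."""
    confs = _synthetic_ensemble(chain2, [1.0, 2.0, 3.0], "ABA")
    rep = rank_ensemble(confs, chain2.graph, reference=chain2.true_fingerprint,
                        fixed_centers=[chain2.fixed_center])
    # class B here is the full mirror of A, which a fixed center forbids in
    # minimized structures: its fixed-center volume violates the restraint
    fixr = next(c for c in chain2.restraints.chirals if c.kind == "fixed_stereocenter")
    from fcdg.molgraph import signed_volume

    mirror_coords = chain2.true_geometry.coordinates * np.array([1.0, 1.0, -1.0])
    assert signed_volume(mirror_coords, fixr.substituents) * fixr.target_volume < 0


def test_center_confidence_bands(chain2):
    # 18 good structures of class A, 2 of class B at high energy -> green;
    # near-degenerate opposite class -> red
    energies = list(np.linspace(0.0, 0.5, 18)) + [11.0, 12.0]
    classes = "A" * 18 + "BB"
    rep = rank_ensemble(_synthetic_ensemble(chain2, energies, classes),
                        chain2.graph, reference=chain2.true_fingerprint,
                        fixed_centers=[chain2.fixed_center])
    table = center_confidence(rep)
    stereo_rows = [r for r in table if r["kind"] == "stereo"]
    assert stereo_rows[0]["band"] == "green"
    assert stereo_rows[0]["delta_e_opposite"] == pytest.approx(11.0)

    energies = [0.0, 0.04] + list(np.linspace(1.0, 2.0, 10))
    classes = "AB" + "A" * 10
    rep = rank_ensemble(_synthetic_ensemble(chain2, energies, classes),
                        chain2.graph, reference=chain2.true_fingerprint,
                        fixed_centers=[chain2.fixed_center])
    table = center_confidence(rep)
    stereo_rows = [r for r in table if r["kind"] == "stereo"]
    assert stereo_rows[0]["band"] == "red"

    # one observed sign only -> probability 1, green
    rep = rank_ensemble(_synthetic_ensemble(chain2, list(np.linspace(0, 1, 12)),
                                            "A" * 12),
                        chain2.graph, reference=chain2.true_fingerprint,
                        fixed_centers=[chain2.fixed_center])
    table = center_confidence(rep)
    row = [r for r in table if r["kind"] == "stereo"][0]
    assert row["band"] == "green" and row["decile_fraction"] == 1.0


def test_report_json_and_csv_roundtrip(tmp_path, chain2):
    import json
    import pandas as pd

    confs = _synthetic_ensemble(chain2, [1.0, 2.0, 3.0], "ABA")
    rep = rank_ensemble(confs, chain2.graph, reference=chain2.true_fingerprint,
                        fixed_centers=[chain2.fixed_center])
    rep.to_csv(tmp_path / "r.csv")
    df = pd.read_csv(tmp_path / "r.csv")
    assert list(df["rank"]) == [1, 2, 3]
    payload = json.loads(rep.to_json(tmp_path / "r.json"))
    assert payload["first_wrong_index"] == rep.first_wrong_index
    assert payload["n_structures"] == 3
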