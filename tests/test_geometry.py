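"""Torsions, Ramachandran classification, Kabsch superposition, RMSD."""

import numpy as np
import pytest

from helpers import naive_kabsch_rmsd, quaternion_min_rmsd, random_rotation

from conformens.geometry import (DEFAULT_RAMA_REGIONS, GeometryError,
                                 SuperpositionResult, backbone_torsions,
                                 classify_rama, dihedral, kabsch,
                                 pairwise_rmsd, rama_segments)
from conformens.model import Ensemble
from conformens.synth import LINKER_SEQUENCE, build_backbone, \
    sample_ensemble, EnsembleDesign

N = len(LINKER_SEQUENCE)


# ------------------------------------------------------------- dihedrals
def test_dihedral_planar_cis_and_trans():
    p1, p2, p3 = [0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]
    assert dihedral(p1, p2, p3, [1.0, 1.0, 0.0]) == pytest.approx(0.0)
    assert dihedral(p1, p2, p3, [1.0, -1.0, 0.0]) == pytest.approx(180.0)


def test_dihedral_matches_independent_formula():
    """Random quadruples vs a separate atan2-of-plane-normals derivation."""
    rng = np.random.default_rng(42)

    def reference(p1, p2, p3, p4):
        b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        x = np.dot(n1, n2)
        y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
        return np.degrees(np.arctan2(y, x))

    for _ in range(50):
        pts = rng.normal(size=(4, 3))
        expected = reference(*pts)
        got = dihedral(*pts)
        diff = (got - expected + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-9


def test_dihedral_collinear_raises():
    with pytest.raises(GeometryError):
        dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


# -------------------------------------------------------------- torsions
def test_backbone_torsions_roundtrip_ideal_helix(helix_model):
    t = backbone_torsions(helix_model, "A")
    assert np.allclose(t.phi[1:], -57.0, atol=1e-6)
    assert np.allclose(t.psi[:-1], -47.0, atol=1e-6)
    assert np.allclose(np.cos(np.radians(t.omega[1:])), -1.0, atol=1e-12)
    assert np.isnan(t.phi[0]) and np.isnan(t.psi[-1]) and np.isnan(t.omega[0])


def test_two_residue_chain_undefined_pattern():
    m = build_backbone("AQ", np.full(2, -57.0), np.full(2, -47.0),
                       start_res=1)
    t = backbone_torsions(m, "A")
    assert np.isnan(t.phi[0]) and not np.isnan(t.psi[0])
    assert not np.isnan(t.phi[1]) and np.isnan(t.psi[1])


def test_numbering_gap_breaks_torsion_chain(helix_model):
    keep = np.nonzero(~np.isin(helix_model.res_seqs, [46, 47]))[0]
    gapped = helix_model.subset(keep)
    t = backbone_torsions(gapped, "A")
    d = t.as_dict()
    assert np.isnan(d[45][1])  # psi(45) needs N(46)
    assert np.isnan(d[48][0])  # phi(48) needs C(47)
    assert not np.isnan(d[44][1]) and not np.isnan(d[49][0])


# ---------------------------------------------------------- Ramachandran
@pytest.mark.parametrize("phi,psi,label", [
    (-57.0, -47.0, "alpha"),
    (-120.0, 130.0, "beta"),
    (-120.0, -170.0, "beta"),   # wrapped beta psi branch
    (60.0, 40.0, "other"),
    (np.nan, -47.0, "undefined"),
])
def test_rama_basin_classification(phi, psi, label):
    assert DEFAULT_RAMA_REGIONS.classify(phi, psi) == label


def test_rama_classify_depends_only_on_phi_psi_and_is_idempotent(helix_model):
    t = backbone_torsions(helix_model, "A")
    labels = classify_rama(t)
    assert labels == classify_rama(t)
    assert labels[1:-1] == ["alpha"] * (N - 2)
    assert labels[0] == "undefined" and labels[-1] == "undefined"


def test_rama_segments_run_length_rule():
    labels = ["alpha", "alpha", "beta", "alpha", "alpha", "alpha"]
    assert rama_segments(labels) == [("alpha", 0, 1), ("alpha", 3, 5)]
    assert rama_segments(["beta", "alpha", "beta"]) == []
    assert rama_segments(["other", "other", "alpha", "alpha"]) == \
        [("alpha", 2, 3)]


# ------------------------------------------------------------- Kabsch
def test_kabsch_identity_and_exact_recovery():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 3))
    res = kabsch(X, X)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    R = random_rotation(rng)
    t = rng.normal(size=3)
    Y = (X - t) @ R  # X = R Y + t  with R proper
    res = kabsch(X, Y)
    assert res.rmsd < 1e-9
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(res.apply(Y), X, atol=1e-8)


def test_kabsch_reflection_guard():
    """A mirrored point set must not be matched by an improper rotation."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(6, 3))
    Y = X * np.array([1.0, 1.0, -1.0])
    res = kabsch(X, Y)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    assert res.rmsd > 0.1


def test_kabsch_degenerate_inputs_error():
    with pytest.raises(GeometryError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.raises(GeometryError):
        kabsch(line, line)


def test_kabsch_agrees_with_quaternion_search():
    rng = np.random.default_rng(7)
    for k in range(5):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 3))
        assert kabsch(X, Y).rmsd == pytest.approx(
            quaternion_min_rmsd(X, Y, seed=k), abs=1e-6)


def test_rmsd_rigid_transform_invariance():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(9, 3))
    Y = rng.normal(size=(9, 3))
    base = kabsch(X, Y).rmsd
    for _ in range(10):
        R = random_rotation(rng)
        t = rng.normal(size=3)
        assert kabsch(X @ R.T + t, Y).rmsd == pytest.approx(base, abs=1e-9)
        assert kabsch(X, Y @ R.T + t).rmsd == pytest.approx(base, abs=1e-9)


# ------------------------------------------------------- pairwise matrix
@pytest.fixture(scope="module")
def small_ensemble():
    design = EnsembleDesign(
        basin_weights=(("alpha", 0.5), ("beta", 0.5)),
        switching_prob=1.0, n_frames=10, seed=5)
    return sample_ensemble(design)[0]


def test_pairwise_rmsd_matches_per_pair_kabsch(small_ensemble):
    sel = "resseq 40-48 and name N,CA,C"
    D = pairwise_rmsd(small_ensemble, sel)
    idx = small_ensemble.frames[0].select_indices(sel)
    coords = small_ensemble.coords(idx)
    n = len(small_ensemble)
    assert D.shape == (n, n)
    np.testing.assert_allclose(D, D.T, atol=1e-9)
    assert np.all(np.diag(D) == 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            assert D[i, j] == pytest.approx(
                naive_kabsch_rmsd(coords[i], coords[j]), abs=1e-9)


def test_pairwise_rmsd_identical_and_rotated_frames(helix_model):
    rng = np.random.default_rng(2)
    R = random_rotation(rng)
    rotated = helix_model.with_coords(helix_model.coords @ R.T + 0.5,
                                      model_id=2)
    ens = Ensemble([helix_model, rotated, helix_model.with_coords(
        helix_model.coords.copy(), model_id=3)], [5.0, 10.0, 15.0])
    D = pairwise_rmsd(ens, "name N,CA,C")
    assert np.abs(D).max() < 1e-9


def test_pairwise_rmsd_empty_selection_errors(small_ensemble):
    from conformens.model import SelectionError
    with pytest.raises(SelectionError):
        pairwise_rmsd(small_ensemble, "name XX")
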