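"""Hydrogen-bond geometry, taxonomy, populations and interface contacts."""

import numpy as np
import pytest

from conformens.hbonds import (HBondRecord, classify_helix_bond,
                               detect_hbonds, hbond_populations,
                               interface_contacts, place_amide_hydrogens)
from conformens.model import AtomRecord, Ensemble, StructureError, \
    StructureModel
from conformens.synth import LINKER_SEQUENCE, build_backbone

N = len(LINKER_SEQUENCE)


def _donor_acceptor_model(d_ha: float, angle_deg: float) -> StructureModel:
    """Minimal N-H ... O geometry with exact H-A distance and D-H-A angle."""
    n_pos = np.array([0.0, 0.0, 0.0])
    h_pos = np.array([0.1, 0.0, 0.0])
    # acceptor in the xy-plane at the requested angle from the H-D direction
    theta = np.radians(180.0 - angle_deg)
    a_pos = h_pos + d_ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    atoms = [
        AtomRecord("N", "N", 10, "ALA", "A", n_pos),
        AtomRecord("H", "H", 10, "ALA", "A", h_pos),
        AtomRecord("O", "O", 5, "GLN", "A", a_pos),
    ]
    return StructureModel.from_atoms(atoms)


@pytest.mark.parametrize("d,angle,expected", [
    (0.240, 140.0, True),    # inside both thresholds
    (0.249, 135.1, True),    # just inside both
    (0.2501, 179.0, False),  # outside the distance threshold
    (0.249, 134.9, False),   # outside the angle threshold
])
def test_hbond_criterion_inside_outside(d, angle, expected):
    bonds = detect_hbonds(_donor_acceptor_model(d, angle))
    assert (len(bonds) == 1) is expected
    if expected:
        b = bonds[0]
        assert b.d_ha == pytest.approx(d, abs=1e-9)
        assert b.angle_dha == pytest.approx(angle, abs=1e-6)
        assert b.bond_id == "10 NH-5 O"


def test_hbond_criterion_strict_at_exact_boundaries():
    """A geometry sitting exactly on either threshold is NOT a bond."""
    # exactly representable linear N-H...O with H-A distance = 0.25 nm
    exact = StructureModel.from_atoms([
        AtomRecord("N", "N", 10, "ALA", "A", np.array([-0.1, 0.0, 0.0])),
        AtomRecord("H", "H", 10, "ALA", "A", np.array([0.0, 0.0, 0.0])),
        AtomRecord("O", "O", 5, "GLN", "A", np.array([0.25, 0.0, 0.0])),
    ])
    assert detect_hbonds(exact) == []                     # d == cutoff
    assert len(detect_hbonds(exact, d_cut=0.2500001)) == 1
    # strictness probed with thresholds set to the measured geometry
    m = _donor_acceptor_model(0.23, 150.0)
    (b,) = detect_hbonds(m)
    assert detect_hbonds(m, d_cut=b.d_ha) == []           # strict <
    assert detect_hbonds(m, angle_cut=b.angle_dha) == []  # strict >
    assert len(detect_hbonds(m, d_cut=np.nextafter(b.d_ha, 1),
                             angle_cut=np.nextafter(b.angle_dha, 0))) == 1


def test_detect_requires_hydrogens(helix_model):
    no_h = helix_model.subset(np.nonzero(
        [n != "H" for n in helix_model.atom_names])[0])
    with pytest.raises(StructureError, match="place_amide_hydrogens"):
        detect_hbonds(no_h)


def test_detect_matches_bruteforce_scan(helix_model):
    """Production detection equals an exhaustive O(N^2) donor-acceptor loop."""
    got = {(b.donor_res, b.donor_h, b.acceptor_res, b.acceptor_atom)
           for b in detect_hbonds(helix_model)}
    m = helix_model
    expected = set()
    donors = []  # (heavy position, H position, res, h name)
    for i in range(m.n_atoms):
        if m.atom_names[i] == "H":
            j = m.atom_index(m.chain_ids[i], int(m.res_seqs[i]), "N")
            donors.append((j, i))
    acceptors = [i for i in range(m.n_atoms)
                 if m.atom_names[i] in ("O", "OXT")
                 or (m.res_names[i], m.atom_names[i]) in
                 {("GLN", "OE1"), ("GLU", "OE1"), ("GLU", "OE2"),
                  ("ASP", "OD1"), ("ASP", "OD2")}]
    for dh, hi in donors:
        for ai in acceptors:
            d = np.linalg.norm(m.coords[hi] - m.coords[ai])
            v1 = m.coords[dh] - m.coords[hi]
            v2 = m.coords[ai] - m.coords[hi]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if d < 0.25 and ang > 135.0:
                expected.add((int(m.res_seqs[dh]), "H",
                              int(m.res_seqs[ai]), m.atom_names[ai]))
    assert got == expected and len(got) == 9


def test_helix_bond_taxonomy():
    mk = lambda dres, ares, heavy="N", h="H", acc="O": HBondRecord(
        "A", dres, heavy, h, "A", ares, acc, 0.2, 160.0)
    assert classify_helix_bond(mk(45, 41)) == "alpha_i_i4"
    assert classify_helix_bond(mk(45, 42)) == "three10_i_i3"
    assert classify_helix_bond(mk(40, 49)) == "other"   # hairpin-type bond
    assert classify_helix_bond(
        mk(48, 41, heavy="NH1", h="HH11", acc="OD1")) == "other"


def test_sidechain_bond_id_labels():
    b = HBondRecord("A", 46, "NE2", "HE22", "A", 40, "O", 0.2, 150.0)
    assert b.bond_id == "46 NHE22-40 O"
    b = HBondRecord("A", 48, "NH1", "HH11", "A", 41, "OD1", 0.2, 150.0)
    assert b.bond_id == "48 NH11-41 OD1"


# ------------------------------------------------------------ placement
def test_place_amide_hydrogens_idempotent_and_analytic(helix_model):
    placed = place_amide_hydrogens(helix_model)
    assert placed.n_atoms == helix_model.n_atoms  # builder already adds H
    assert placed.atom_names == helix_model.atom_names

    stripped = helix_model.subset(np.nonzero(
        [n != "H" for n in helix_model.atom_names])[0])
    rebuilt = place_amide_hydrogens(stripped)
    # independent vector-algebra check of each constructed H
    for res in range(39, 51):
        h = rebuilt.get_position("A", res, "H")
        n = rebuilt.get_position("A", res, "N")
        ca = rebuilt.get_position("A", res, "CA")
        c_prev = rebuilt.get_position("A", res - 1, "C")
        assert np.linalg.norm(h - n) == pytest.approx(0.100, abs=1e-9)
        u1 = (c_prev - n) / np.linalg.norm(c_prev - n)
        u2 = (ca - n) / np.linalg.norm(ca - n)
        expected = n - 0.100 * (u1 + u2) / np.linalg.norm(u1 + u2)
        assert np.linalg.norm(h - expected) < 1e-3
        # in the C(i-1)-N-CA plane
        normal = np.cross(u1, u2)
        assert abs((h - n) @ normal / np.linalg.norm(normal)) < 1e-9


def test_proline_gets_no_amide_hydrogen():
    m = build_backbone("APA", np.full(3, -57.0), np.full(3, -47.0),
                       start_res=1)
    stripped = m.subset(np.nonzero([n != "H" for n in m.atom_names])[0])
    rebuilt = place_amide_hydrogens(stripped)
    with pytest.raises(KeyError):
        rebuilt.atom_index("A", 2, "H")   # PRO
    assert rebuilt.atom_index("A", 3, "H") >= 0


# ----------------------------------------------------------- populations
@pytest.fixture(scope="module")
def mixed_ensemble(helix_model, strand_model):
    frames = [helix_model.with_coords(helix_model.coords.copy(), model_id=i)
              for i in range(1, 10)]
    frames.append(strand_model.with_coords(strand_model.coords.copy(),
                                           model_id=10))
    return Ensemble(frames, 5.0 * np.arange(1, 11),
                    frame_labels=["helix"] * 9 + ["strand"])


def test_population_counting(mixed_ensemble):
    """A bond present in 9 of 10 frames has population 0.9."""
    pops = hbond_populations(mixed_ensemble)
    assert pops.n_frames == 10
    assert pops.fractions["45 NH-41 O"] == pytest.approx(0.9)
    all_h = hbond_populations(mixed_ensemble, frame_indices=range(9))
    assert all_h.fractions["45 NH-41 O"] == pytest.approx(1.0)


def test_population_frame_order_invariance(mixed_ensemble):
    perm = [3, 0, 9, 1, 8, 2, 7, 4, 6, 5]
    shuffled = Ensemble([mixed_ensemble.frames[i] for i in perm],
                        5.0 * np.arange(1, 11))
    assert hbond_populations(shuffled).fractions == \
        hbond_populations(mixed_ensemble).fractions


def test_cluster_weighted_populations_pool_to_global(mixed_ensemble):
    """Global population is the exact cluster-size-weighted mean."""
    groups = [list(range(9)), [9]]
    global_pops = hbond_populations(mixed_ensemble).fractions
    pooled: dict[str, float] = {}
    for g in groups:
        sub = hbond_populations(mixed_ensemble, frame_indices=g).fractions
        w = len(g) / 10
        for k, v in sub.items():
            pooled[k] = pooled.get(k, 0.0) + w * v
    assert set(pooled) == set(global_pops)
    for k in pooled:
        assert pooled[k] == pytest.approx(global_pops[k], abs=1e-12)


def test_empty_ensemble_errors(mixed_ensemble):
    with pytest.raises(StructureError):
        hbond_populations(mixed_ensemble, frame_indices=[])


# ------------------------------------------------------------ interfaces
def test_salt_bridge_contact(salt_bridge_assembly):
    cmap = interface_contacts(salt_bridge_assembly, "A", "B")
    assert cmap.entries == {(41, 120): ("saltbridge", pytest.approx(0.35))}


def test_distant_chains_empty_map(salt_bridge_assembly):
    far = salt_bridge_assembly.with_coords(
        salt_bridge_assembly.coords + np.where(
            np.array([c == "B" for c in salt_bridge_assembly.chain_ids])[:, None],
            5.0, 0.0))
    assert interface_contacts(far, "A", "B").entries == {}


def test_interface_mirror_symmetry(salt_bridge_assembly):
    ab = interface_contacts(salt_bridge_assembly, "A", "B")
    ba = interface_contacts(salt_bridge_assembly, "B", "A")
    assert ba.entries == ab.mirrored().entries


def test_unknown_chain_errors(salt_bridge_assembly):
    with pytest.raises(StructureError, match="chain"):
        interface_contacts(salt_bridge_assembly, "A", "Z")
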