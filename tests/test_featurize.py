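import logging

import numpy as np
import pytest

from nmsm.featurize import (
    GAUCHE_MINUS,
    GAUCHE_PLUS,
    TRANS,
    classify_rotamer,
    compute_chi1,
    compute_helix_distance,
    compute_ligand_distances,
    compute_sasa,
    dihedral,
    residence_time,
)
from nmsm.synthetic_data import generate_rotamer_toy
from nmsm.trajectory_io import Atom, Trajectory


def _traj(atoms, frames):
    return Trajectory(atoms, np.asarray(frames, dtype=float), 0.1)


def _rigid_transform(coords, rng):
    # random rotation (QR of a Gaussian matrix) + translation
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return coords @ q.T + rng.uniform(-5, 5, 3)


# ---------------------------------------------------------------------------
# chi1 / rotamers


def test_planar_zigzag_dihedral_is_trans():
    p = [np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]),
         np.array([[1.0, 1, 0]]), np.array([[2.0, 1, 0]])]
    assert dihedral(*p)[0] == pytest.approx(180.0)


@pytest.mark.parametrize("target", [180.0, -60.0, 60.0, 0.0, 119.999, -175.25])
def test_chi1_recovers_constructed_angle(target):
    traj = generate_rotamer_toy([target])
    chi = compute_chi1(traj, "A:1").values[0, 0]
    assert chi == pytest.approx(target, abs=1e-6)


def test_chi1_skips_glycine_with_warning(caplog):
    toy = generate_rotamer_toy([60.0])
    atoms = toy.atoms + [Atom("N", "GLY", 2, "A", "N"), Atom("CA", "GLY", 2, "A", "C")]
    coords = np.concatenate([toy.coords, np.zeros((1, 2, 3)) + 30.0], axis=1)
    traj = _traj(atoms, coords)
    with caplog.at_level(logging.WARNING):
        table = compute_chi1(traj, ["A:1-2"])
    assert table.n_features == 1
    assert any("no chi1" in r.message for r in caplog.records)


def test_rotamer_classification_follows_field_convention():
    assert classify_rotamer(180.0) == TRANS
    assert classify_rotamer(-60.0) == GAUCHE_PLUS
    assert classify_rotamer(60.0) == GAUCHE_MINUS
    # boundary convention: bins centred on -60/+60/180
    assert classify_rotamer(119.999) == GAUCHE_MINUS
    assert classify_rotamer(120.0) == TRANS
    assert classify_rotamer(-120.0) == TRANS
    assert classify_rotamer(0.0) == GAUCHE_MINUS
    with pytest.raises(ValueError):
        classify_rotamer(181.0)


def test_chi1_invariant_under_rigid_motion(rng):
    traj = generate_rotamer_toy([-60.0, 45.0, 170.0])
    moved = Trajectory(
        traj.atoms,
        np.stack([_rigid_transform(f, rng) for f in traj.coords]),
        traj.frame_interval,
    )
    np.testing.assert_allclose(
        compute_chi1(moved, "A:1").values, compute_chi1(traj, "A:1").values, atol=1e-9
    )


# ---------------------------------------------------------------------------
# distances


def test_helix_distance_single_ca_pairs():
    atoms = [Atom("CA", "ALA", 1, "A", "C"), Atom("CA", "ALA", 10, "A", "C")]
    frames = [[[0, 0, 0], [5, 0, 0]]]
    traj = _traj(atoms, frames)
    assert compute_helix_distance(traj, "A:1", "A:10").values[0, 0] == pytest.approx(5.0)
    assert compute_helix_distance(traj, "A:1", "A:1").values[0, 0] == pytest.approx(0.0)
    shifted = Trajectory(atoms, traj.coords + np.array([1.0, 2.0, 3.0]), 0.1)
    assert compute_helix_distance(shifted, "A:1", "A:10").values[0, 0] == pytest.approx(5.0)
    with pytest.raises(ValueError, match="CA"):
        compute_helix_distance(traj, "A:99", "A:10")


def test_ligand_distances_capping():
    atoms = [
        Atom("C1", "LIG", 1, "L", "C"),
        Atom("CA", "ALA", 1, "A", "C"),
        Atom("CA", "ALA", 2, "A", "C"),
    ]
    frames = [[[0, 0, 0], [15.0, 0, 0], [3.2, 0, 0]]]
    traj = _traj(atoms, frames)
    table = compute_ligand_distances(traj, "resname:LIG", "A:1-2", cap=12.0)
    assert table.values[0].tolist() == [12.0, 3.2]
    uncapped = compute_ligand_distances(traj, "resname:LIG", "A:1-2", cap=np.inf)
    assert uncapped.values[0].tolist() == [15.0, 3.2]
    with pytest.raises(ValueError, match="ligand"):
        compute_ligand_distances(traj, "resname:XXX", "A:1-2")


def test_residence_occupancy_hand_enumerated():
    # per-frame min distances [3.5, 3.9, 4.2, 3.0, 5.1] vs cutoff 4
    atoms = [Atom("C1", "LIG", 1, "L", "C"), Atom("CA", "ALA", 1, "A", "C")]
    d = [3.5, 3.9, 4.2, 3.0, 5.1]
    frames = [[[0, 0, 0], [x, 0, 0]] for x in d]
    traj = _traj(atoms, frames)
    report = residence_time(traj, "resname:LIG", "A:1", cutoff=4.0)
    assert report.occupancy == pytest.approx(0.6)
    assert report.consistent is True


def test_residence_zero_and_exact_half_are_inconsistent():
    atoms = [Atom("C1", "LIG", 1, "L", "C"), Atom("CA", "ALA", 1, "A", "C")]
    far = _traj(atoms, [[[0, 0, 0], [10.0, 0, 0]]] * 4)
    assert residence_time(far, "resname:LIG", "A:1").occupancy == 0.0
    half = _traj(atoms, [[[0, 0, 0], [3.0, 0, 0]], [[0, 0, 0], [10.0, 0, 0]]])
    report = residence_time(half, "resname:LIG", "A:1")
    assert report.occupancy == pytest.approx(0.5)
    assert report.consistent is False  # strictly above 50% required


# ---------------------------------------------------------------------------
# SASA


def test_sasa_isolated_atom_matches_sphere_area():
    atoms = [Atom("S", "XXX", 1, "A", "S")]  # r = 1.8
    traj = _traj(atoms, [[[0, 0, 0]]])
    area = compute_sasa(traj, "A:1").values[0, 0]
    assert area == pytest.approx(4 * np.pi * (1.8 + 1.4) ** 2, rel=0.01)


def test_sasa_additive_at_large_separation():
    atoms = [Atom("C1", "XXX", 1, "A", "C"), Atom("O1", "XXX", 2, "A", "O")]
    traj = _traj(atoms, [[[0, 0, 0], [100.0, 0, 0]]])
    total = compute_sasa(traj, ["A:1", "A:2"]).values[0, 0]
    expected = 4 * np.pi * ((1.7 + 1.4) ** 2 + (1.52 + 1.4) ** 2)
    assert total == pytest.approx(expected, rel=0.01)


def test_sasa_buried_atom_is_zero():
    # central atom enclosed by a tight shell of 26 large atoms
    offsets = [
        np.array([i, j, k], dtype=float)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    atoms = [Atom("C1", "XXX", 1, "A", "C")] + [
        Atom("S", "XXX", 2 + n, "A", "S") for n in range(len(offsets))
    ]
    frame = np.vstack([[0.0, 0.0, 0.0]] + [2.2 * o / np.linalg.norm(o) for o in offsets])
    traj = _traj(atoms, frame[None])
    assert compute_sasa(traj, "A:1").values[0, 0] == pytest.approx(0.0, abs=1.0)


def test_sasa_agrees_with_dense_point_oracle(rng):
    # random 10-atom cluster: production quadrature vs 10x denser points
    atoms = [Atom("C1", "XXX", i + 1, "A", "C") for i in range(10)]
    frame = rng.uniform(-3, 3, (10, 3))
    traj = _traj(atoms, frame[None])
    sel = [f"A:{i}" for i in range(1, 11)]
    fast = compute_sasa(traj, sel, n_points=960).values[0, 0]
    dense = compute_sasa(traj, sel, n_points=10000).values[0, 0]
    assert fast == pytest.approx(dense, rel=0.02)


def test_sasa_unknown_element_fallback(caplog):
    atoms = [Atom("Q1", "XXX", 1, "A", "Q")]
    traj = _traj(atoms, [[[0, 0, 0]]])
    with caplog.at_level(logging.WARNING):
        area = compute_sasa(traj, "A:1").values[0, 0]
    assert area == pytest.approx(4 * np.pi * (1.5 + 1.4) ** 2, rel=0.01)
    assert any("unknown element" in r.message for r in caplog.records)
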