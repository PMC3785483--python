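"""Kabsch superposition, best-fit RMSD and side-chain distance conventions."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gatewave.geometry import (DegenerateGeometryError, DistanceConvention,
                               bestfit_rmsd, kabsch_superpose, pair_min_distance)
from gatewave.structio import Atom, Structure


def rigid(coords, rotvec, translation):
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return coords @ R.T + translation


def brute_force_rmsd(mobile, reference):
    """Independent oracle: numerical minimization over rotation parameters."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((mc @ R.T - rc) ** 2).sum() / len(mc))

    best = np.inf
    for x0 in ([0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0],
               [0.0, 0.0, 1.5], [1.2, 1.2, 1.2], [-1.2, 0.6, 2.0]):
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def test_identity_superposition(rng):
    pts = rng.normal(size=(10, 3))
    transform, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)


def test_pure_rigid_motion_recovered(rng):
    pts = rng.normal(size=(12, 3))
    moved = rigid(pts, [0.0, 0.0, np.radians(37.0)], [5.0, -3.0, 2.0])
    transform, rmsd = kabsch_superpose(moved, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(transform.apply(moved), pts, atol=1e-6)


def test_rmsd_matches_numerical_optimizer_oracle(rng):
    worst = 0.0
    for _ in range(50):
        pts = rng.normal(size=(10, 3)) * 5
        noisy = rigid(pts + rng.normal(scale=0.5, size=pts.shape),
                      rng.normal(size=3), rng.normal(size=3) * 4)
        worst = max(worst, abs(bestfit_rmsd(noisy, pts) - brute_force_rmsd(noisy, pts)))
    assert worst < 1e-6


def test_rmsd_invariant_under_rigid_motion_of_either_argument(rng):
    a = rng.normal(size=(15, 3))
    b = a + rng.normal(scale=0.3, size=a.shape)
    base = bestfit_rmsd(a, b)
    a2 = rigid(a, rng.normal(size=3), rng.normal(size=3))
    b2 = rigid(b, rng.normal(size=3), rng.normal(size=3))
    assert bestfit_rmsd(a2, b) == pytest.approx(base, abs=1e-9)
    assert bestfit_rmsd(a, b2) == pytest.approx(base, abs=1e-9)
    assert bestfit_rmsd(b, a) == pytest.approx(base, abs=1e-9)


def test_translation_only_gives_zero(rng):
    a = rng.normal(size=(8, 3))
    assert bestfit_rmsd(a + [3.0, -1.0, 7.5], a) == pytest.approx(0.0, abs=1e-9)


def test_single_displaced_atom_matches_oracle(rng):
    a = rng.normal(size=(9, 3)) * 3
    b = a.copy()
    b[4] += [1.0, 0.0, 0.0]
    assert bestfit_rmsd(b, a) == pytest.approx(brute_force_rmsd(b, a), abs=1e-6)


def test_triangle_like_bound(rng):
    a = rng.normal(size=(12, 3))
    b = a + rng.normal(scale=0.4, size=a.shape)
    c = b + rng.normal(scale=0.4, size=a.shape)
    assert bestfit_rmsd(a, c) <= bestfit_rmsd(a, b) + bestfit_rmsd(b, c) + 1e-9


def test_rmsd_stationary_under_infinitesimal_rigid_motion(rng):
    """The optimum is invariant: rigid perturbations change RMSD only at O(eps^2)."""
    a = rng.normal(size=(10, 3))
    b = a + rng.normal(scale=0.5, size=a.shape)
    base = bestfit_rmsd(a, b)
    eps = 1e-6
    for axis in np.eye(3):
        shifted = a + eps * axis
        rotated = rigid(a, eps * axis, np.zeros(3))
        assert abs(bestfit_rmsd(shifted, b) - base) < 1e-9
        assert abs(bestfit_rmsd(rotated, b) - base) < 1e-9


def test_degenerate_subsets_rejected():
    line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(line, line + 1.0)
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(np.zeros((5, 3)), np.zeros((5, 3)))
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_reflection_excluded(rng):
    pts = rng.normal(size=(10, 3))
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    transform, rmsd = kabsch_superpose(mirrored, pts)
    assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1


def _two_residue_structure(d_functional, d_heavy):
    """ARG-ASP pair: functional beads at d_functional, CB beads at d_heavy."""
    atoms = [
        Atom(1, "CA", "ARG", "A", 1, np.array([0.0, 0.0, 0.0]), element="C"),
        Atom(2, "CB", "ARG", "A", 1, np.array([0.0, 1.0, 0.0]), element="C"),
        Atom(3, "NH1", "ARG", "A", 1, np.array([0.0, 2.0, 0.0]), element="N"),
        Atom(4, "CA", "ASP", "B", 2, np.array([10.0, 0.0, 0.0]), element="C"),
        Atom(5, "CB", "ASP", "B", 2, np.array([d_heavy, 1.0, 0.0]), element="C"),
        Atom(6, "OD1", "ASP", "B", 2, np.array([d_functional, 2.0, 0.0]), element="O"),
    ]
    return Structure(atoms)


def test_pair_distance_modes_and_symmetry():
    s = _two_residue_structure(d_functional=6.2, d_heavy=3.9)
    func = DistanceConvention(mode="functional_atoms")
    heavy = DistanceConvention(mode="all_sidechain_heavy")
    ka, kb = ("A", 1, ""), ("B", 2, "")
    assert pair_min_distance(s, ka, kb, func) == pytest.approx(6.2)
    assert pair_min_distance(s, ka, kb, heavy) == pytest.approx(3.9)
    assert pair_min_distance(s, kb, ka, func) == pytest.approx(
        pair_min_distance(s, ka, kb, func))


def test_planted_functional_distance(channel_pair):
    closed, opened = channel_pair
    conv = DistanceConvention(mode="functional_atoms")
    # planted NBD-like salt bridge is bound in the open state at 3.6 A
    assert pair_min_distance(opened, ("A", 2, ""), ("B", 2, ""), conv) == \
        pytest.approx(3.6, abs=0.01)


def test_missing_convention_atoms_error():
    s = _two_residue_structure(6.2, 3.9)
    conv = DistanceConvention(mode="functional_atoms",
                              functional_map={"ARG": ("NH1",)})
    with pytest.raises(ValueError, match="ASP"):
        pair_min_distance(s, ("A", 1, ""), ("B", 2, ""), conv)
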