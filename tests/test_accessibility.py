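"""Shrake-Rupley SASA against analytic values and a dense-lattice oracle."""

import numpy as np
import pytest

from gatewave.accessibility import (GXG_REFERENCE, SASAParams, fractional_sasa,
                                    golden_spiral, mutate_to_cys,
                                    neighbor_residues, shrake_rupley,
                                    state_compare)
from gatewave.structio import Atom, Structure, assign_radii


def cluster(coords, radii=None, resname="ALA"):
    atoms = []
    for i, c in enumerate(coords):
        atoms.append(Atom(i + 1, "CA", resname, "A", i + 1, np.asarray(c, float),
                          element="C"))
    s = Structure(atoms)
    assign_radii(s)
    if radii is not None:
        for a, r in zip(s.atoms, radii):
            a.vdw_radius = r
    return s


def test_isolated_sphere_analytic():
    s = cluster([[0.0, 0.0, 0.0]])
    res = shrake_rupley(s, SASAParams())
    expected = 4 * np.pi * (1.70 + 1.4) ** 2
    assert res.total == pytest.approx(expected, rel=0.01)


def test_distant_atoms_additive():
    s = cluster([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    res = shrake_rupley(s)
    single = 4 * np.pi * (1.70 + 1.4) ** 2
    assert res.total == pytest.approx(2 * single, rel=0.01)


def test_total_bounded_by_isolated_sum(rng):
    pts = rng.uniform(0, 6, size=(12, 3))
    s = cluster(pts)
    res = shrake_rupley(s)
    assert res.total <= 12 * 4 * np.pi * (1.70 + 1.4) ** 2 + 1e-6


def test_two_overlapping_atoms_match_dense_lattice_oracle():
    s = cluster([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    res = shrake_rupley(s, SASAParams(points_per_atom=960))
    oracle = shrake_rupley(s, SASAParams(points_per_atom=10000))
    np.testing.assert_allclose(res.atom_area, oracle.atom_area, rtol=0.02)


def test_random_clusters_match_dense_lattice_oracle(rng):
    """20 random multi-residue fixtures, per-residue agreement with a
    10x denser lattice within 2%."""
    for _ in range(20):
        n_res = int(rng.integers(2, 5))
        atoms = []
        serial = 1
        for r in range(n_res):
            center = rng.uniform(0, 10, size=3)
            for k in range(int(rng.integers(3, 6))):
                atoms.append(Atom(serial, f"C{k}", "ALA", "A", r + 1,
                                  center + rng.normal(scale=2.0, size=3),
                                  element="C"))
                serial += 1
        s = assign_radii(Structure(atoms))
        res = shrake_rupley(s, SASAParams(points_per_atom=960))
        oracle = shrake_rupley(s, SASAParams(points_per_atom=9600))
        for key in s.residue_keys():
            a, b = res.residue_area[key], oracle.residue_area[key]
            assert abs(a - b) / max(b, 1.0) < 0.02


def test_doubling_points_stable(closed_channel):
    a = shrake_rupley(closed_channel, SASAParams(points_per_atom=960))
    b = shrake_rupley(closed_channel, SASAParams(points_per_atom=1920))
    key = ("A", 1, "")
    fa = fractional_sasa(a, key, "isolated")
    fb = fractional_sasa(b, key, "isolated")
    assert abs(fa - fb) < 1.0


def test_golden_spiral_uniformity():
    pts = golden_spiral(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(pts.mean(axis=0), 0.0, atol=0.01)


def test_fractional_sasa_reference_modes():
    s = cluster([[0.0, 0.0, 0.0]], resname="ALA")
    res = shrake_rupley(s)
    iso = fractional_sasa(res, ("A", 1, ""), "isolated")
    assert iso == pytest.approx(100.0, abs=0.5)
    gxg = fractional_sasa(res, ("A", 1, ""), "gxg")
    assert gxg == pytest.approx(100.0 * res.total / GXG_REFERENCE["ALA"], rel=1e-6)
    with pytest.raises(KeyError):
        fractional_sasa(res, ("A", 1, ""), {"GLY": 104.0})


def test_fully_caged_residue_nearly_zero():
    """A dense shell of occluders buries the central atom below 5%."""
    shell = golden_spiral(40) * 3.3
    s = cluster(np.vstack([[0.0, 0.0, 0.0], shell]))
    res = shrake_rupley(s)
    frac = 100.0 * res.atom_area[0] / (4 * np.pi * (1.70 + 1.4) ** 2)
    assert frac < 5.0


def test_occlusion_monotone(rng):
    base = [[0.0, 0.0, 0.0]]
    occluders = rng.normal(scale=3.0, size=(8, 3)) + [3.0, 0, 0]
    prev = np.inf
    for k in range(len(occluders) + 1):
        s = cluster(base + occluders[:k].tolist())
        area = shrake_rupley(s).atom_area[0]
        assert area <= prev + 1e-9
        prev = area


def _arg_residue():
    atoms = [
        Atom(1, "N", "ARG", "A", 5, np.array([0.0, 1.3, 0.0]), element="N"),
        Atom(2, "CA", "ARG", "A", 5, np.array([0.0, 0.0, 0.0]), element="C"),
        Atom(3, "C", "ARG", "A", 5, np.array([1.4, -0.5, 0.0]), element="C"),
        Atom(4, "O", "ARG", "A", 5, np.array([2.4, 0.2, 0.0]), element="O"),
        Atom(5, "CB", "ARG", "A", 5, np.array([-1.0, -0.5, 1.0]), element="C"),
        Atom(6, "CG", "ARG", "A", 5, np.array([-1.5, -1.9, 1.2]), element="C"),
        Atom(7, "CD", "ARG", "A", 5, np.array([-2.6, -2.1, 2.2]), element="C"),
        Atom(8, "NE", "ARG", "A", 5, np.array([-3.0, -3.5, 2.3]), element="N"),
    ]
    return Structure(atoms)


def test_mutate_to_cys_all_atom():
    s = _arg_residue()
    m = mutate_to_cys(s, ("A", 5, ""))
    names = [a.name for a in m.atoms]
    assert sorted(names) == sorted(["N", "CA", "C", "O", "CB", "SG"])
    assert all(a.residue_name == "CYS" for a in m.atoms)
    cb = next(a for a in m.atoms if a.name == "CB")
    sg = next(a for a in m.atoms if a.name == "SG")
    assert np.linalg.norm(sg.coords - cb.coords) == pytest.approx(1.81, abs=1e-3)
    again = mutate_to_cys(m, ("A", 5, ""))
    assert [a.name for a in again.atoms] == names


def test_mutate_to_cys_coarse(closed_channel):
    m = mutate_to_cys(closed_channel, ("A", 1, ""))
    atoms = m.residue_atoms(("A", 1, ""))
    assert {a.name for a in atoms} == {"CA", "SG"}
    assert atoms[0].residue_name == "CYS"
    assert len(m) == len(closed_channel)


def test_mutate_missing_sidechain_errors():
    s = Structure([Atom(1, "CA", "GLY", "A", 1, np.zeros(3), element="C")])
    with pytest.raises(ValueError):
        mutate_to_cys(s, ("A", 1, ""))


def test_state_compare_probe_direction(channel_pair):
    closed, opened = channel_pair
    rep = state_compare(closed, opened, ("A", 1, ""))
    assert rep.frac_closed > rep.frac_open
    assert rep.call_closed == "accessible"
    assert rep.call_open == "buried"
    assert len(rep.neighbors_open) >= 4
    assert len(rep.neighbors_closed) <= 1


def test_state_compare_identical_structures(closed_channel):
    rep = state_compare(closed_channel, closed_channel, ("A", 1, ""))
    assert rep.frac_closed == pytest.approx(rep.frac_open)
    assert rep.neighbors_closed == rep.neighbors_open


def test_isolated_residue_has_no_neighbors():
    atoms = [Atom(1, "CA", "ALA", "A", 1, np.zeros(3), element="C"),
             Atom(2, "CA", "ALA", "B", 1, np.array([50.0, 0.0, 0.0]), element="C")]
    s = Structure(atoms)
    assert neighbor_residues(s, ("A", 1, ""), 5.0) == []
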