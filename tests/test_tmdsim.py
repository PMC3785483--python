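"""TMD schedule, bias forces, integrator and opening-run contracts.

The expensive fixture-scale opening runs live in the acceptance suite; the
tests here use short runs and small systems.
"""

import numpy as np
import pytest

from gatewave.structio import Atom, Structure, assign_radii
from gatewave.synthfix import ChannelSpec, make_two_state_channel
from gatewave.tmdsim import (KB, IntegrationError, Schedule, TMDParams,
                             ToyFFParams, build_topology, integrate, rms_star,
                             run_opening, tmd_bias)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def test_schedule_endpoints_exact():
    s = Schedule(rms0=7.3, total_time=10.0)
    assert rms_star(0.0, s) == 7.3
    assert rms_star(10.0, s) == 0.0
    assert rms_star(5.0, s) == pytest.approx(7.3 / 2)


def test_schedule_linearity_and_range():
    s = Schedule(rms0=4.0, total_time=2.0)
    ts = np.linspace(0, 2, 11)
    vals = [rms_star(t, s) for t in ts]
    np.testing.assert_allclose(vals, 4.0 * (1 - ts / 2.0))
    with pytest.raises(ValueError):
        rms_star(2.5, s)
    with pytest.raises(ValueError):
        rms_star(-0.1, s)


# ---------------------------------------------------------------------------
# bias
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_system(rng=None):
    r = np.random.default_rng(11)
    coords = r.normal(size=(20, 3)) * 4.0
    target = coords + r.normal(scale=1.0, size=coords.shape)
    params = TMDParams(k_tmd=5.0, target=target, bias_subset=np.arange(20))
    sched = Schedule(rms0=3.0, total_time=0.2)
    return coords, params, sched


def test_bias_zero_at_schedule_match(small_system):
    coords, params, _ = small_system
    from gatewave.geometry import bestfit_rmsd
    rms_now = bestfit_rmsd(coords, params.target)
    sched = Schedule(rms0=rms_now, total_time=1.0)
    e, f = tmd_bias(coords, params, 0.0, sched)
    assert e == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(f, 0.0, atol=1e-9)


def test_bias_net_force_and_torque_vanish(small_system):
    coords, params, sched = small_system
    e, f = tmd_bias(coords, params, 0.1, sched)
    assert e > 0
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(np.cross(coords, f).sum(axis=0), 0.0, atol=1e-8)


def test_bias_force_matches_finite_differences(small_system):
    coords, params, sched = small_system
    _, f = tmd_bias(coords, params, 0.05, sched)
    h = 1e-6
    r = np.random.default_rng(3)
    for i in r.choice(20, 6, replace=False):
        for d in range(3):
            xp, xm = coords.copy(), coords.copy()
            xp[i, d] += h
            xm[i, d] -= h
            fd = -(tmd_bias(xp, params, 0.05, sched)[0]
                   - tmd_bias(xm, params, 0.05, sched)[0]) / (2 * h)
            assert abs(fd - f[i, d]) / max(1e-6, abs(fd)) < 1e-4


def test_bias_invariant_under_global_rigid_motion(small_system):
    from scipy.spatial.transform import Rotation
    coords, params, sched = small_system
    e0, f0 = tmd_bias(coords, params, 0.1, sched)
    R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
    moved = coords @ R.T + np.array([4.0, -2.0, 1.0])
    e1, f1 = tmd_bias(moved, params, 0.1, sched)
    assert e1 == pytest.approx(e0, abs=1e-9)
    np.testing.assert_allclose(f1, f0 @ R.T, atol=1e-8)


def test_one_sided_variant_flat_below_schedule(small_system):
    coords, params, _ = small_system
    import dataclasses
    one = dataclasses.replace(params, one_sided=True)
    sched = Schedule(rms0=100.0, total_time=1.0)  # RMS* far above RMS
    e, f = tmd_bias(coords, one, 0.0, sched)
    assert e == 0.0
    np.testing.assert_allclose(f, 0.0)


def test_per_atom_normalized_prefactor(small_system):
    coords, params, sched = small_system
    import dataclasses
    norm = dataclasses.replace(params, per_atom_normalized=True)
    e_full, _ = tmd_bias(coords, params, 0.1, sched)
    e_norm, _ = tmd_bias(coords, norm, 0.1, sched)
    assert e_norm == pytest.approx(e_full / 20.0)


# ---------------------------------------------------------------------------
# integrator (small chain system)
# ---------------------------------------------------------------------------

def chain_structure(n=12, spacing=3.8):
    atoms = [Atom(i + 1, "CA", "ALA", "A", i + 1,
                  np.array([i * spacing, 0.3 * (i % 3), 0.0]), element="C")
             for i in range(n)]
    return assign_radii(Structure(atoms))


def test_nve_energy_conservation():
    s = chain_structure()
    topo = build_topology(s)
    params = TMDParams(k_tmd=0.0, duration=0.02, timestep=2.0, friction=0.0,
                       temperature=300.0, seed=4, stride=100)
    res = integrate(topo, s.coords, params)
    total = res.kinetic_trace + res.potential_trace
    assert abs(total[-1] - total[0]) < 0.01 * res.kinetic_trace[0]


def test_thermostat_equipartition():
    s = chain_structure()
    topo = build_topology(s)
    params = TMDParams(k_tmd=0.0, duration=0.05, timestep=5.0, friction=5.0,
                       temperature=300.0, seed=5, stride=20)
    res = integrate(topo, s.coords, params)
    half = len(res.kinetic_trace) // 2
    ke_per_dof = res.kinetic_trace[half:].mean() / (1.5 * topo.n)
    assert ke_per_dof == pytest.approx(KB * 300.0, rel=0.10)


def test_same_seed_identical_trace():
    s = chain_structure()
    topo = build_topology(s)
    params = TMDParams(k_tmd=1.0, duration=0.01, timestep=5.0, seed=9,
                       target=s.coords + 0.5, stride=10)
    a = integrate(topo, s.coords, params)
    b = integrate(topo, s.coords, params)
    np.testing.assert_array_equal(a.rmsd_trace, b.rmsd_trace)
    np.testing.assert_array_equal(a.trajectory.frames[-1], b.trajectory.frames[-1])


def test_blowup_aborts_with_frame_index():
    s = chain_structure()
    topo = build_topology(s)
    # absurd timestep-free blow-up: gigantic bias constant on a distant target
    params = TMDParams(k_tmd=1e9, duration=0.01, timestep=9.0, friction=0.0,
                       seed=0, target=s.coords + 500.0, stride=5)
    with pytest.raises(IntegrationError, match="frame"):
        integrate(topo, s.coords, params)


# ---------------------------------------------------------------------------
# opening runs (short, fixture-scale)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def short_opening(channel_pair_module=None):
    closed, opened = make_two_state_channel(ChannelSpec())
    params = TMDParams(seed=1, duration=0.04, stride=100)
    return closed, opened, run_opening(closed, opened, params)


def test_opening_snapshots_at_fractions(short_opening):
    closed, opened, res = short_opening
    times = [t for t, _ in res.snapshots]
    duration = res.params.duration
    np.testing.assert_allclose(times, [0.0, duration / 4, duration / 2,
                                       3 * duration / 4, duration], rtol=0.02)
    np.testing.assert_allclose(res.snapshots[0][1].coords, closed.coords, atol=1e-9)


def test_opening_rmsd_descends(short_opening):
    _, _, res = short_opening
    assert res.rmsd_trace[0] > 5.0
    assert res.final_rmsd < res.rmsd_trace[0] / 3
    # smoothed trace is non-increasing
    k = max(1, len(res.rmsd_trace) // 10)
    sm = np.convolve(res.rmsd_trace, np.ones(k) / k, mode="valid")
    assert np.all(np.diff(sm) < 0.2)


def test_already_at_target_stays_there():
    closed, opened = make_two_state_channel(ChannelSpec())
    params = TMDParams(seed=2, duration=0.02, stride=50)
    res = run_opening(opened, opened.copy(), params)
    assert np.all(res.rmsd_trace < 0.2)


def test_tracking_error_shrinks_with_k():
    """Stronger bias follows the schedule more faithfully.

    Checked on a single-basin chain dragged toward a deformed target, where
    the bias is the only driver of the transition (on the two-state channel
    fixture the crossing is downhill once started and the tracking error is
    dominated by the crossing speed, not by k)."""
    s = chain_structure(n=16)
    topo = build_topology(s)
    target = s.coords.copy()
    target[:, 1] += 2.0 * np.sin(np.linspace(0, np.pi, 16))
    sups = []
    for k in (1.0, 5.0, 25.0):
        params = TMDParams(k_tmd=k, seed=3, duration=0.05, stride=100,
                           target=target, bias_subset=np.arange(16))
        res = integrate(topo, s.coords, params)
        sups.append(np.max(np.abs(res.rmsd_trace - res.rms_star_trace)))
    assert sups[0] > sups[1] > sups[2]


def test_atom_order_mismatch_rejected():
    closed, opened = make_two_state_channel(ChannelSpec())
    atoms = list(opened.atoms)
    atoms[0], atoms[1] = atoms[1], atoms[0]
    with pytest.raises(ValueError, match="ordering"):
        run_opening(closed, Structure(atoms))
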