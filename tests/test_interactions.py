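"""Contact scanning, occupancy classification, event detection, wave report."""

import numpy as np
import pytest

from gatewave.geometry import DistanceConvention
from gatewave.interactions import (ContactScanParams, ContactSeries, Event,
                                   classify, detect_event, scan_contacts,
                                   trace_pairs, wave_report)
from gatewave.structio import Atom, Structure, Trajectory


def pair_structure(spacings):
    """One basic residue per spacing, with an acidic partner at that distance."""
    atoms = []
    serial = 1
    for i, d in enumerate(spacings):
        y = 20.0 * i
        atoms.append(Atom(serial, "CA", "ARG", "A", 2 * i + 1,
                          np.array([0.0, y, 0.0]), element="C")); serial += 1
        atoms.append(Atom(serial, "NH1", "ARG", "A", 2 * i + 1,
                          np.array([1.0, y, 0.0]), element="N")); serial += 1
        atoms.append(Atom(serial, "CA", "GLU", "B", 2 * i + 2,
                          np.array([1.0 + d + 1.0, y, 0.0]), element="C")); serial += 1
        atoms.append(Atom(serial, "OE1", "GLU", "B", 2 * i + 2,
                          np.array([1.0 + d, y, 0.0]), element="O")); serial += 1
    return Structure(atoms)


def series(distances, times=None):
    d = np.asarray(distances, dtype=float)
    t = np.asarray(times if times is not None else np.arange(len(d)), dtype=float)
    return ContactSeries(("A", 1), ("B", 2), "acidic", d, t)


def test_scan_includes_sub_cutoff_excludes_supra():
    s = pair_structure([4.5, 5.5])
    out = scan_contacts(s)
    found = {(c.basic[1], round(c.distance, 2)) for c in out}
    assert (1, 4.5) in found
    assert all(b != 3 for b, _ in found)


def test_scan_planted_counts():
    sub = [3.2, 4.0, 4.4, 4.6, 4.8, 4.9, 4.99]
    supra = [5.01, 5.5, 6.0, 8.0, 12.0]
    s = pair_structure(sub + supra)
    out = scan_contacts(s)
    assert len(out) == 7


def test_scan_monotone_in_cutoff():
    s = pair_structure([3.0, 4.5, 5.5, 7.0])
    small = {(c.basic, c.partner) for c in scan_contacts(s, ContactScanParams(cutoff=4.0))}
    large = {(c.basic, c.partner) for c in scan_contacts(s, ContactScanParams(cutoff=6.0))}
    assert small <= large


def test_scan_partner_classes(closed_channel):
    out = scan_contacts(closed_channel)
    classes = {c.partner_class for c in out}
    assert classes <= {"acidic", "hydroxyl"}
    # closed-state planted pairs: 2 ICL + 1 ECL acidic, plus 2 persistent hydroxyl
    pairs = {(c.basic[:2], c.partner[:2]) for c in out}
    assert (("B", 7, ""), ("C", 7, "")) in {(c.basic, c.partner) for c in out}


def test_trace_static_and_symmetry(closed_channel):
    frames = [closed_channel.coords] * 12
    traj = Trajectory(closed_channel, frames, np.arange(12, dtype=float))
    conv = DistanceConvention(mode="all_sidechain_heavy")
    fwd = trace_pairs(traj, [(("B", 7, ""), ("C", 7, ""))], conv)[0]
    rev = trace_pairs(traj, [(("C", 7, ""), ("B", 7, ""))], conv)[0]
    assert fwd.distances.std() < 1e-12
    np.testing.assert_allclose(fwd.distances, rev.distances)


def test_trace_missing_residue_errors(closed_channel):
    traj = Trajectory(closed_channel, [closed_channel.coords], [0.0])
    with pytest.raises(KeyError):
        trace_pairs(traj, [(("Z", 1, ""), ("A", 1, ""))])


@pytest.mark.parametrize("present_span,expected", [
    ((0, 50), "closed_state"),     # first half only (boundary case)
    ((50, 100), "open_state"),
    ((0, 100), "persistent"),
    ((40, 61), "unclassified"),    # occupancies 0.2 / 0.22
])
def test_classification_definitions(present_span, expected):
    d = np.full(100, 9.0)
    d[present_span[0]:present_span[1]] = 4.0
    assert classify(series(d)).label == expected


def test_classification_time_rescaling_invariant():
    d = np.r_[np.full(30, 4.0), np.full(70, 9.0)]
    a = classify(series(d, times=np.arange(100)))
    b = classify(series(d, times=np.arange(100) * 13.7 + 5))
    assert a.label == b.label
    assert a.occupancy_first_half == b.occupancy_first_half


def test_classification_needs_frames():
    with pytest.raises(ValueError):
        classify(series([4.0] * 9))


def test_breaking_event_at_planted_frame():
    d = np.r_[np.full(600, 4.0), np.full(400, 9.0)]
    t = np.linspace(0.0, 10.0, 1000)
    ev = detect_event(series(d, t), dwell_frames=50)
    assert ev.event_type == "breaking"
    assert ev.time == pytest.approx(t[600])


def test_formation_event_mirrored():
    d = np.r_[np.full(600, 9.0), np.full(400, 4.0)]
    ev = detect_event(series(d), dwell_frames=50)
    assert ev.event_type == "formation"
    assert ev.time == pytest.approx(600.0)


def test_constant_trace_no_event():
    ev = detect_event(series(np.full(200, 4.0)), dwell_frames=10)
    assert ev.event_type == "none" and ev.time is None


def test_short_excursion_rejected_by_dwell():
    d = np.full(200, 4.0)
    d[100:110] = 9.0  # 10-frame excursion, dwell 50
    ev = detect_event(series(d), dwell_frames=50)
    assert ev.event_type == "none"


def test_event_time_shifts_with_switch_frame():
    for shift in (0, 7, 31):
        d = np.r_[np.full(100 + shift, 4.0), np.full(200 - shift, 9.0)]
        ev = detect_event(series(d[:300]), dwell_frames=20)
        assert ev.time == pytest.approx(100 + shift)


def test_wave_report_ordering_and_ties():
    events = [
        Event(((("A")), ("x")), "formation", 5.0),
    ]
    # build properly keyed events
    e_tm = Event((("A", 13, ""), ("B", 13, "")), "formation", 7.0)
    e_nbd = Event((("A", 2, ""), ("B", 2, "")), "formation", 5.0)
    e_icl = Event((("B", 7, ""), ("C", 7, "")), "breaking", 6.0)
    e_none = Event((("F", 2, ""), ("F", 5, "")), "none", None)
    rmap = {("A", 13, ""): "TM-like", ("A", 2, ""): "NBD-like",
            ("B", 7, ""): "ICL-like", ("F", 2, ""): "NBD-like"}
    rep = wave_report([e_tm, e_nbd, e_icl, e_none], rmap)
    assert rep.region_sequence() == ["NBD-like", "ICL-like", "TM-like"]
    # simultaneous events: NBD-like listed before TM-like
    e_tm2 = Event((("A", 13, ""), ("B", 13, "")), "formation", 5.0)
    rep2 = wave_report([e_tm2, e_nbd], rmap)
    assert rep2.region_sequence() == ["NBD-like", "TM-like"]


def test_wave_report_single_event():
    e = Event((("A", 2, ""), ("B", 2, "")), "formation", 1.0)
    rep = wave_report([e], {("A", 2, ""): "NBD-like"})
    assert len(rep.events) == 1
    assert "NBD-like" in rep.to_tsv()


def test_wave_report_missing_region_errors():
    e = Event((("A", 2, ""), ("B", 2, "")), "formation", 1.0)
    with pytest.raises(KeyError):
        wave_report([e], {})
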