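"""Side-chain interaction scanning, classification and event detection.

Basic residues (Arg/Lys) are scanned for close contacts (default <= 5 A
between side chains) with acidic (Asp/Glu) and hydroxyl (Ser/Thr/Tyr)
partners.  Each surviving pair is traced across a trajectory, classified by
half-trajectory occupancy as closed-state / open-state / persistent, and
searched for a persistent formation or breaking event whose time, together
with a residue->region map, yields the "conformational wave" ordering
(nucleotide-binding domains first, then intracellular loops, then the
transmembrane region).

"Existing primarily" in one half is quantified as occupancy >= 2/3 in that
half and <= 1/3 in the other (configurable).  An event requires the distance
to cross the cutoff and stay crossed for a dwell window (default 5% of the
trajectory) so thermal recrossings are not reported as events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DistanceConvention, pair_min_distance
from .structio import Structure, Trajectory

__all__ = [
    "ContactScanParams",
    "Contact",
    "ContactSeries",
    "InteractionClass",
    "Event",
    "WaveReport",
    "scan_contacts",
    "trace_pairs",
    "classify",
    "detect_event",
    "wave_report",
    "REGION_ORDER",
]

REGION_ORDER = ("NBD-like", "ICL-like", "TM-like", "ECL-like")

PARTNER_CLASSES = {"acidic": frozenset({"ASP", "GLU"}),
                   "hydroxyl": frozenset({"SER", "THR", "TYR"})}


@dataclass
class ContactScanParams:
    cutoff: float = 5.0
    convention: DistanceConvention = field(
        default_factory=lambda: DistanceConvention(mode="all_sidechain_heavy"))
    occupancy_high: float = 2.0 / 3.0
    occupancy_low: float = 1.0 / 3.0
    dwell_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass(frozen=True)
class Contact:
    basic: tuple
    partner: tuple
    partner_class: str
    distance: float


@dataclass
class ContactSeries:
    basic: tuple
    partner: tuple
    partner_class: str
    distances: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.distances.shape != self.times.shape:
            raise ValueError("distances and times must be congruent")


@dataclass
class InteractionClass:
    label: str  # closed_state | open_state | persistent | unclassified
    occupancy_first_half: float
    occupancy_second_half: float


@dataclass
class Event:
    pair: tuple[tuple, tuple]
    event_type: str  # formation | breaking | none
    time: float | None
    region: str | None = None


def _partner_class(resname: str) -> str | None:
    for cls, members in PARTNER_CLASSES.items():
        if resname in members:
            return cls
    return None


def scan_contacts(structure: Structure,
                  params: ContactScanParams | None = None) -> list[Contact]:
    """All (basic, acidic-or-hydroxyl) residue pairs within the cutoff."""
    params = params or ContactScanParams()
    basics = structure.residues_of_class("basic")
    partners = [k for k in structure.residue_keys()
                if _partner_class(structure.residue_name(k)) is not None]
    out: list[Contact] = []
    for b in basics:
        for p in partners:
            if p == b:
                continue
            d = pair_min_distance(structure, b, p, params.convention)
            if d <= params.cutoff:
                out.append(Contact(b, p, _partner_class(structure.residue_name(p)), d))
    return out


def trace_pairs(trajectory: Trajectory, pairs: list[tuple[tuple, tuple]],
                convention: DistanceConvention | None = None) -> list[ContactSeries]:
    """Per-frame side-chain distance series for each residue pair."""
    convention = convention or DistanceConvention()
    topo = trajectory.topology
    for a, b in pairs:
        for key in (a, b):
            if key not in topo.residue_index:
                raise KeyError(f"residue {key} not in trajectory topology")
    series: list[ContactSeries] = []
    # resolve atom indices once; frames only move coordinates
    resolved = []
    for a, b in pairs:
        ia = _convention_indices(topo, a, convention)
        ib = _convention_indices(topo, b, convention)
        resolved.append((a, b, ia, ib))
    for a, b, ia, ib in resolved:
        dists = np.empty(len(trajectory))
        for f, frame in enumerate(trajectory.frames):
            d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :], axis=-1)
            dists[f] = d.min()
        pclass = _partner_class(topo.residue_name(b)) or "other"
        series.append(ContactSeries(a, b, pclass, dists, trajectory.times))
    return series


def _convention_indices(structure: Structure, key: tuple,
                        convention: DistanceConvention) -> np.ndarray:
    atoms = structure.residue_atoms(key)
    resname = atoms[0].residue_name
    idx = structure.residue_index[key]
    if convention.mode == "functional_atoms":
        wanted = convention.functional_map.get(resname, ())
        picked = [i for i, a in zip(idx, atoms) if a.name in wanted]
    else:
        from .structio import BACKBONE_NAMES
        picked = [i for i, a in zip(idx, atoms)
                  if a.name not in BACKBONE_NAMES and not a.element.upper().startswith("H")]
    if not picked:
        raise ValueError(f"residue {resname} {key} has no atoms under convention {convention.mode!r}")
    return np.array(picked, dtype=int)


def classify(series: ContactSeries,
             params: ContactScanParams | None = None) -> InteractionClass:
    """Closed-state / open-state / persistent classification by half-occupancy."""
    params = params or ContactScanParams()
    n = len(series.distances)
    if n < 10:
        raise ValueError(f"classification needs >= 10 frames, got {n}")
    present = series.distances <= params.cutoff
    half = n // 2
    occ1 = float(np.mean(present[:half]))
    occ2 = float(np.mean(present[half:]))
    hi, lo = params.occupancy_high, params.occupancy_low
    if occ1 >= hi and occ2 >= hi:
        label = "persistent"
    elif occ1 >= hi and occ2 <= lo:
        label = "closed_state"
    elif occ2 >= hi and occ1 <= lo:
        label = "open_state"
    else:
        label = "unclassified"
    return InteractionClass(label, occ1, occ2)


def detect_event(series: ContactSeries, params: ContactScanParams | None = None,
                 dwell_frames: int | None = None) -> Event:
    """First persistent crossing of the cutoff: a formation or breaking event.

    The event time is the time of the first frame of the persistent crossing.
    Excursions shorter than the dwell window are rejected.
    """
    params = params or ContactScanParams()
    n = len(series.distances)
    if dwell_frames is None:
        dwell_frames = max(1, int(round(params.dwell_fraction * n)))
    if n < 2 * dwell_frames:
        raise ValueError(f"need >= {2 * dwell_frames} frames for dwell {dwell_frames}")
    present = series.distances <= params.cutoff
    initial = bool(present[0])
    target = not initial  # the state whose persistent onset is the event
    run = 0
    onset = None
    for i in range(n):
        if present[i] == target:
            if run == 0:
                onset = i
            run += 1
            if run >= dwell_frames:
                etype = "formation" if target else "breaking"
                return Event((series.basic, series.partner), etype,
                             float(series.times[onset]))
        else:
            run = 0
            onset = None
    return Event((series.basic, series.partner), "none", None)


@dataclass
class WaveReport:
    events: list[Event]

    def to_tsv(self) -> str:
        lines = ["basic\tpartner\ttype\ttime_ns\tregion"]
        for e in self.events:
            b = f"{e.pair[0][0]}:{e.pair[0][1]}"
            p = f"{e.pair[1][0]}:{e.pair[1][1]}"
            lines.append(f"{b}\t{p}\t{e.event_type}\t{e.time:.4f}\t{e.region}")
        return "\n".join(lines) + "\n"

    def region_sequence(self) -> list[str]:
        return [e.region for e in self.events]

    def earliest_by_region(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.events:
            if e.region not in out or e.time < out[e.region]:
                out[e.region] = e.time
        return out


def wave_report(events: list[Event], region_map: dict[tuple, str]) -> WaveReport:
    """Order events in time; ties break by region order then residue number.

    The region of an event is the region of its basic residue.  Events with
    type "none" are excluded.
    """
    rows = []
    for e in events:
        if e.event_type == "none" or e.time is None:
            continue
        region = region_map.get(e.pair[0])
        if region is None:
            raise KeyError(f"residue {e.pair[0]} missing from region map")
        rows.append(Event(e.pair, e.event_type, e.time, region))
    region_rank = {r: i for i, r in enumerate(REGION_ORDER)}
    rows.sort(key=lambda e: (e.time, region_rank.get(e.region, len(REGION_ORDER)),
                             e.pair[0][1]))
    return WaveReport(rows)


def catalog_tsv(contacts: list[Contact],
                classes: dict[tuple[tuple, tuple], InteractionClass] | None = None) -> str:
    """Interaction catalog TSV (basic, partner, class, distance, occupancies)."""
    lines = ["basic_res\tpartner_res\tpartner_class\tmin_dist_A\tocc_half1\tocc_half2\tclass"]
    for c in contacts:
        key = (c.basic, c.partner)
        cls = classes.get(key) if classes else None
        occ1 = f"{cls.occupancy_first_half:.3f}" if cls else "NA"
        occ2 = f"{cls.occupancy_second_half:.3f}" if cls else "NA"
        label = cls.label if cls else "NA"
        lines.append(f"{c.basic[0]}:{c.basic[1]}\t{c.partner[0]}:{c.partner[1]}"
                     f"\t{c.partner_class}\t{c.distance:.3f}\t{occ1}\t{occ2}\t{label}")
    return "\n".join(lines) + "\n"
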