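"""Synthetic two-state channel fixtures with planted, analyzable structure.

The generator emulates the geometry the analyses assume, with every planted
feature exactly constructed and validated at build time:

* A six-helix channel around the z axis (one backbone bead per residue on an
  ideal helix, one side-chain pseudo-bead).  Residues 1-6 of each chain are
  the cytosolic "NBD-like" region, 7-9 "ICL-like" (hinge), 10-16 "TM-like"
  and 17-20 "ECL-like".
* Two conformations built from a common straight reference by rigid hinge
  motions, so bond lengths are preserved and the difference between states
  is carried by a few soft collective motions with a built-in amplitude
  hierarchy (NBD-like >> ICL-like > TM-like), the staging the transition
  analyses are designed to read out:

  - open: the cytosolic segments tilt inward and dimerize (continuous lumen
    wider than a chloride ion throughout the membrane span);
  - closed: cytosolic segments swing sideways (alternating chains) and tilt
    outward (dissociated cytosolic domains), the TM helices carry an axial
    twist, and the extracellular ends lean inward to form a sub-chloride
    constriction near the extracellular end of the membrane span.

* Planted residue pairs (basic vs acidic/hydroxyl) whose side-chain beads
  are placed to sit at an exact bound distance in their bound state and
  verifiably far (>= 8 A) in the other, so contact classification and event
  detection have ground truth.  Side-chain pseudo-beads carry the residue's
  functional-atom name (NH1 for Arg, OD1 for Asp, ...) so both distance
  conventions resolve them.
* A state-dependent probe residue at a chain terminus: buried by >= 4
  neighbouring residues in the open state (the cytosolic dimer closes
  around it) and neighboured by at most 1 residue in the closed state.

Transition trajectories interpolate closed -> open with per-region
smoothstep stage windows (NBD -> ICL -> TM order) and per-pair timing
adjusted so each planted contact crosses the 5 A cutoff at its specified
switch frame.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .interactions import ContactSeries
from .profalign import Alignment, ProfileSet, windowed_hydropathy
from .structio import Atom, Structure, Trajectory, write_pdb

__all__ = [
    "ChannelSpec",
    "PlantedPair",
    "TransitionSpec",
    "GeneratorError",
    "make_two_state_channel",
    "make_transition_trajectory",
    "make_trace_fixture",
    "make_alignment_fixture",
    "default_region_map",
    "region_map_tsv",
    "write_fixture",
    "DEFAULT_TM_SPAN",
]


class GeneratorError(ValueError):
    """A planted feature is geometrically infeasible under the spec."""


# region boundaries in residue index (inclusive), per chain
NBD_END = 6
ICL_END = 9
TM_END = 16
SWING_HINGE = 10
LEAN_START = 16
TWIST_START = 10
TWIST_FULL = 13

FUNCTIONAL_BEAD = {"ARG": "NH1", "LYS": "NZ", "ASP": "OD1", "GLU": "OE1",
                   "SER": "OG", "THR": "OG1", "TYR": "OH", "CYS": "SG", "ALA": "CB"}


@dataclass(frozen=True)
class PlantedPair:
    basic: tuple[str, int]
    basic_resname: str
    partner: tuple[str, int]
    partner_resname: str
    kind: str                  # open_state | closed_state | persistent
    region: str                # region of the basic residue
    bound_distance: float = 3.6


def _default_planted() -> list[PlantedPair]:
    return [
        PlantedPair(("A", 2), "ARG", ("B", 2), "ASP", "open_state", "NBD-like"),
        PlantedPair(("C", 2), "LYS", ("D", 2), "GLU", "open_state", "NBD-like"),
        PlantedPair(("B", 7), "ARG", ("C", 7), "GLU", "closed_state", "ICL-like"),
        PlantedPair(("D", 7), "ARG", ("E", 7), "ASP", "closed_state", "ICL-like"),
        PlantedPair(("A", 13), "ARG", ("B", 13), "ASP", "open_state", "TM-like"),
        PlantedPair(("D", 13), "LYS", ("E", 13), "GLU", "open_state", "TM-like"),
        PlantedPair(("B", 19), "ARG", ("C", 19), "GLU", "closed_state", "ECL-like"),
        PlantedPair(("E", 12), "ARG", ("E", 15), "SER", "persistent", "TM-like"),
        PlantedPair(("F", 2), "LYS", ("F", 5), "THR", "persistent", "NBD-like"),
    ]


def _default_lone() -> list[tuple[str, int, str]]:
    return [("A", 6, "LYS"), ("E", 5, "ARG"), ("C", 17, "TYR")]


@dataclass
class ChannelSpec:
    """Geometry of the synthetic two-state channel."""

    n_helices: int = 6
    residues_per_helix: int = 20
    rise: float = 1.5                  # A per residue
    helix_radius: float = 2.3          # A, backbone winding radius
    phase_per_residue: float = 100.0   # degrees
    sc_length: float = 2.5             # CA -> side-chain bead, A
    lumen_radius_open: float = 4.0     # A
    constriction_radius_closed: float = 0.5  # A
    tilt_open: float = 34.0            # NBD inward tilt, degrees
    tilt_open_probe: float = 62.0      # deeper tilt of the probe's chain, degrees
    tilt_open_per_chain: list | None = None  # explicit per-chain override
    tilt_closed: float = 42.0          # NBD outward tilt, degrees
    swing_closed: float = 50.0         # ICL sideways swing, degrees
    twist_closed: float = 60.0         # TM axial twist, degrees
    relief_closed: float = 10.0        # azimuthal relief of the first/last chains, degrees
    planted: list[PlantedPair] = field(default_factory=_default_planted)
    lone_residues: list[tuple[str, int, str]] = field(default_factory=_default_lone)
    probe: tuple[str, int] = ("A", 1)
    probe_resname: str = "ARG"
    seed: int = 0

    @property
    def axis_radius(self) -> float:
        """Radial distance of helix axes: lumen + bead vdW + winding radius."""
        return self.lumen_radius_open + 1.7 + self.helix_radius

    @property
    def z0(self) -> float:
        return -self.rise * (self.residues_per_helix - 1) / 2.0


DEFAULT_TM_SPAN = (-1.5, 10.0)  # membrane span incl. the extracellular mouth


def default_region_map(spec: ChannelSpec | None = None) -> dict[tuple, str]:
    spec = spec or ChannelSpec()
    out = {}
    for c in range(spec.n_helices):
        chain = chr(ord("A") + c)
        for i in range(1, spec.residues_per_helix + 1):
            if i <= NBD_END:
                region = "NBD-like"
            elif i <= ICL_END:
                region = "ICL-like"
            elif i <= TM_END:
                region = "TM-like"
            else:
                region = "ECL-like"
            out[(chain, i, "")] = region
    return out


def region_map_tsv(region_map: dict[tuple, str]) -> str:
    lines = ["chain\tresnum_start\tresnum_end\tregion"]
    # compress contiguous runs per chain
    by_chain: dict[str, list[tuple[int, str]]] = {}
    for (chain, num, _), region in sorted(region_map.items()):
        by_chain.setdefault(chain, []).append((num, region))
    for chain, rows in by_chain.items():
        start, cur = rows[0][0], rows[0][1]
        prev = start
        for num, region in rows[1:]:
            if region != cur:
                lines.append(f"{chain}\t{start}\t{prev}\t{cur}")
                start, cur = num, region
            prev = num
        lines.append(f"{chain}\t{start}\t{prev}\t{cur}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


class _StateBuilder:
    """Tracks per-residue affine transforms while applying hinge motions."""

    def __init__(self, ca_ref: dict, tip_ref: dict):
        self.ca = {k: v.copy() for k, v in ca_ref.items()}
        self.tip = {k: v.copy() for k, v in tip_ref.items()}
        self.A = {k: np.eye(3) for k in ca_ref}
        self.b = {k: np.zeros(3) for k in ca_ref}

    def rotate(self, keys: Sequence[tuple], point: np.ndarray, axis: np.ndarray,
               angle_deg: float) -> None:
        R = _rotation(axis, angle_deg)
        shift = point - R @ point
        for k in keys:
            self.ca[k] = R @ self.ca[k] + shift
            self.tip[k] = R @ self.tip[k] + shift
            self.A[k] = R @ self.A[k]
            self.b[k] = R @ self.b[k] + shift

    def to_reference(self, key: tuple, x: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.A[key], x - self.b[key])

    def from_reference(self, key: tuple, x: np.ndarray) -> np.ndarray:
        return self.A[key] @ x + self.b[key]


def _signed_tilt(builder: _StateBuilder, keys, hinge_key, angle_deg: float,
                 inward: bool) -> None:
    """Tilt a segment about the tangential axis at the hinge, toward/away the channel axis."""
    hinge = builder.ca[hinge_key]
    radial = np.array([hinge[0], hinge[1], 0.0])
    radial /= max(np.linalg.norm(radial), 1e-9)
    tangential = np.cross([0.0, 0.0, 1.0], radial)
    probe_key = keys[0]
    before = np.linalg.norm(builder.ca[probe_key][:2])
    R = _rotation(tangential, angle_deg)
    after = np.linalg.norm((R @ (builder.ca[probe_key] - hinge) + hinge)[:2])
    moved_in = after < before
    if moved_in != inward:
        angle_deg = -angle_deg
    builder.rotate(keys, hinge, tangential, angle_deg)


def make_two_state_channel(spec: ChannelSpec | None = None) -> tuple[Structure, Structure]:
    """Build the closed and open channel structures (identical atom ordering).

    Raises :class:`GeneratorError` when a planted feature cannot be realized
    under the requested geometry.
    """
    spec = spec or ChannelSpec()
    n_res = spec.residues_per_helix
    chains = [chr(ord("A") + c) for c in range(spec.n_helices)]

    # straight reference helices
    ca_ref: dict[tuple, np.ndarray] = {}
    tip_ref: dict[tuple, np.ndarray] = {}
    for c, chain in enumerate(chains):
        theta_c = 2 * np.pi * c / spec.n_helices
        axis_xy = spec.axis_radius * np.array([np.cos(theta_c), np.sin(theta_c)])
        for i in range(1, n_res + 1):
            phase = np.radians(spec.phase_per_residue * (i - 1) + 25.0 * c)
            u = np.array([np.cos(theta_c), np.sin(theta_c), 0.0])
            t = np.array([-np.sin(theta_c), np.cos(theta_c), 0.0])
            ca = np.array([axis_xy[0], axis_xy[1], spec.z0 + spec.rise * (i - 1)])
            ca = ca + spec.helix_radius * (np.cos(phase) * u + np.sin(phase) * t)
            key = (chain, i)
            ca_ref[key] = ca
            outward = np.array([ca[0], ca[1], 0.0])
            outward /= np.linalg.norm(outward)
            if 2 <= i <= 4:
                # near-terminal side chains tilt upward so the chain end stays clear
                outward = outward + np.array([0.0, 0.0, 1.0])
                outward /= np.linalg.norm(outward)
            tip_ref[key] = ca + spec.sc_length * outward

    open_b = _StateBuilder(ca_ref, tip_ref)
    closed_b = _StateBuilder(ca_ref, tip_ref)

    for c, chain in enumerate(chains):
        nbd = [(chain, i) for i in range(1, NBD_END + 1)]
        lower = [(chain, i) for i in range(1, ICL_END + 1)]
        lean = [(chain, i) for i in range(LEAN_START + 1, n_res + 1)]
        sign = 1.0 if c % 2 else -1.0

        # open: cytosolic dimerization
        if spec.tilt_open_per_chain is not None:
            open_tilt = spec.tilt_open_per_chain[c]
        elif chain == spec.probe[0]:
            # the probe's chain dives under the cytosolic dimer, burying its
            # terminal residue beneath the canopy formed by the other chains
            open_tilt = spec.tilt_open_probe
        else:
            # alternate canopy depths: staggered termini give every chain a
            # geometrically unique slot, so the dimer can only assemble in
            # its native register
            open_tilt = spec.tilt_open + (-4.0 if c % 2 else 4.0)
        _signed_tilt(open_b, nbd, (chain, NBD_END + 1), open_tilt, inward=True)

        # closed: TM twist (ramped), sideways swing, outward tilt, gate lean
        axis_pt = np.array([spec.axis_radius * np.cos(2 * np.pi * c / spec.n_helices),
                            spec.axis_radius * np.sin(2 * np.pi * c / spec.n_helices), 0.0])
        for i in range(TWIST_START, n_res + 1):
            ramp = min(max((i - (TWIST_START - 1)) / (TWIST_FULL - TWIST_START + 1), 0.0), 1.0)
            if ramp > 0:
                # counter-rotating helices: adjacent TM side chains genuinely exchange
                closed_b.rotate([(chain, i)], axis_pt, np.array([0.0, 0.0, 1.0]),
                                sign * spec.twist_closed * ramp)
        hinge = closed_b.ca[(chain, SWING_HINGE)]
        radial = np.array([hinge[0], hinge[1], 0.0])
        radial /= np.linalg.norm(radial)
        closed_b.rotate(lower, hinge, radial, sign * spec.swing_closed)
        # counter-swing the terminal segment so the splayed cytosolic ends stay
        # in their own azimuthal sectors (the ICL keeps the full swing): the
        # opening motion is then radial for every chain and paths do not cross
        hinge7 = closed_b.ca[(chain, NBD_END + 1)]
        radial7 = np.array([hinge7[0], hinge7[1], 0.0])
        radial7 /= np.linalg.norm(radial7)
        closed_b.rotate(nbd, hinge7, radial7, -sign * spec.swing_closed)
        # the alternating swing drives every odd chain toward its ccw neighbour;
        # relieve the unpaired first/last chains so their splayed ends cannot clash
        if c == 0 or c == spec.n_helices - 1:
            relief = spec.relief_closed if c == 0 else -spec.relief_closed
            closed_b.rotate(lower, np.zeros(3), np.array([0.0, 0.0, 1.0]), relief)
        _signed_tilt(closed_b, nbd, (chain, NBD_END + 1), spec.tilt_closed, inward=False)

        # gate: alternate deep/shallow inward lean; solve the angle so the
        # innermost gate bead reaches the target constriction radius
        # the backbone leans moderately; the inward-pointing side chains plug
        # the mouth, so the gate blocks without an extreme backbone rotation
        target_r = spec.constriction_radius_closed + 3.5 if c % 2 else \
            spec.constriction_radius_closed + 4.7
        hinge_key = (chain, LEAN_START)
        hinge = closed_b.ca[hinge_key]
        radial = np.array([hinge[0], hinge[1], 0.0])
        radial /= np.linalg.norm(radial)
        tangential = np.cross([0.0, 0.0, 1.0], radial)

        def min_gate_radius(angle: float) -> float:
            R = _rotation(tangential, angle)
            pts = [R @ (closed_b.ca[k] - hinge) + hinge for k in lean]
            return min(np.linalg.norm(p[:2]) for p in pts)

        best_angle, best_r = 0.0, min_gate_radius(0.0)
        for trial in np.arange(2.0, 120.0, 2.0):
            for signed in (trial, -trial):
                r = min_gate_radius(signed)
                if abs(r - target_r) < abs(best_r - target_r):
                    best_angle, best_r = signed, r
        closed_b.rotate(lean, hinge, tangential, best_angle)

    # ---- planted side chains -------------------------------------------
    resnames = {key: "ALA" for key in ca_ref}
    for chain, num, name in spec.lone_residues:
        resnames[(chain, num)] = name
    for p in spec.planted:
        resnames[p.basic] = p.basic_resname
        resnames[p.partner] = p.partner_resname
    resnames[spec.probe] = spec.probe_resname

    def place_pair(pair: PlantedPair) -> None:
        bound = open_b if pair.kind == "open_state" else closed_b
        other = closed_b if pair.kind == "open_state" else open_b
        ka, kb = pair.basic, pair.partner
        ca_a, ca_b = bound.ca[ka], bound.ca[kb]
        d = np.linalg.norm(ca_b - ca_a)
        u = (ca_b - ca_a) / d
        L = spec.sc_length
        cos_l = (d - pair.bound_distance) / (2 * L)
        if abs(cos_l) > 1.0:
            raise GeneratorError(
                f"pair {ka}-{kb}: bound-state CA distance {d:.2f} A incompatible "
                f"with bound distance {pair.bound_distance} A")
        sin_l = np.sqrt(1.0 - cos_l ** 2)
        perp0 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp0) < 1e-6:
            perp0 = np.cross(u, [1.0, 0.0, 0.0])
        perp0 /= np.linalg.norm(perp0)
        perp1 = np.cross(u, perp0)
        best = None
        best_score = None
        for ang in np.arange(0.0, 360.0, 30.0):
            n_hat = np.cos(np.radians(ang)) * perp0 + np.sin(np.radians(ang)) * perp1
            tip_a = ca_a + L * (cos_l * u + sin_l * n_hat)
            tip_b = ca_b + L * (-cos_l * u + sin_l * n_hat)
            ref_a = bound.to_reference(ka, tip_a)
            ref_b = bound.to_reference(kb, tip_b)
            other_d = np.linalg.norm(other.from_reference(ka, ref_a)
                                     - other.from_reference(kb, ref_b))
            # persistent pairs stay bound in the other state; others separate
            score = -other_d if pair.kind == "persistent" else other_d
            if best_score is None or score > best_score:
                best_score = score
                best = (tip_a, tip_b, ref_a, ref_b)
        tip_a, tip_b, ref_a, ref_b = best
        bound.tip[ka], bound.tip[kb] = tip_a, tip_b
        if pair.kind == "persistent":
            # co-moving pair: the rigid map keeps the contact in both states
            other.tip[ka] = other.from_reference(ka, ref_a)
            other.tip[kb] = other.from_reference(kb, ref_b)
        else:
            # unbound state: prefer side chains relaxed up-and-outward (clear of
            # the partner and the chain termini); fall back to the rigid map when
            # only the mapped orientation keeps the pair separated
            relaxed = {}
            for k in (ka, kb):
                ca_u = other.ca[k]
                up_out = np.array([ca_u[0], ca_u[1], 0.0])
                up_out /= max(np.linalg.norm(up_out), 1e-9)
                up_out = up_out + np.array([0.0, 0.0, 1.0])
                up_out /= np.linalg.norm(up_out)
                relaxed[k] = ca_u + L * up_out
            if np.linalg.norm(relaxed[ka] - relaxed[kb]) >= 8.0:
                other.tip[ka], other.tip[kb] = relaxed[ka], relaxed[kb]
            else:
                other.tip[ka] = other.from_reference(ka, ref_a)
                other.tip[kb] = other.from_reference(kb, ref_b)

    for pair in spec.planted:
        place_pair(pair)

    # probe cluster: all residue-1 side chains point into the cytosolic dimer
    # in the open state; in the closed (splayed) state they point down-outward,
    # away from the rest of the chain
    for chain in chains:
        key = (chain, 1)
        ca = open_b.ca[key]
        inward = np.array([-ca[0], -ca[1], -1.0])
        inward /= np.linalg.norm(inward)
        open_b.tip[key] = ca + spec.sc_length * inward
        ca_c = closed_b.ca[key]
        out = np.array([ca_c[0], ca_c[1], 0.0])
        out /= max(np.linalg.norm(out), 1e-9)
        down_out = 0.25 * out - np.array([0.0, 0.0, 1.0])
        down_out /= np.linalg.norm(down_out)
        closed_b.tip[key] = ca_c + spec.sc_length * down_out

    # gate plug: in the closed state the leaning extracellular side chains
    # point into the mouth, filling the gaps between chains (planted pair
    # residues keep their solved orientations)
    pair_residues = {p.basic for p in spec.planted} | {p.partner for p in spec.planted}
    for chain in chains:
        for i in range(LEAN_START + 1, n_res):
            key = (chain, i)
            if key in pair_residues:
                continue
            ca = closed_b.ca[key]
            inward = np.array([-ca[0], -ca[1], 0.0])
            nrm = np.linalg.norm(inward)
            if nrm < 1e-9:
                continue
            closed_b.tip[key] = ca + spec.sc_length * inward / nrm

    closed = _assemble(spec, chains, resnames, closed_b)
    opened = _assemble(spec, chains, resnames, open_b)
    _validate(spec, closed, opened, closed_b, open_b)
    return closed, opened


def _assemble(spec: ChannelSpec, chains, resnames, builder: _StateBuilder) -> Structure:
    atoms = []
    serial = 1
    for chain in chains:
        for i in range(1, spec.residues_per_helix + 1):
            key = (chain, i)
            rn = resnames[key]
            atoms.append(Atom(serial, "CA", rn, chain, i, builder.ca[key].copy(), element="C"))
            serial += 1
            bead = FUNCTIONAL_BEAD[rn]
            atoms.append(Atom(serial, bead, rn, chain, i, builder.tip[key].copy()))
            serial += 1
    return Structure(atoms)


def _validate(spec, closed: Structure, opened: Structure,
              closed_b: _StateBuilder, open_b: _StateBuilder) -> None:
    from .geometry import DistanceConvention, pair_min_distance

    conv = DistanceConvention(mode="all_sidechain_heavy")
    for p in spec.planted:
        ka = (p.basic[0], p.basic[1], "")
        kb = (p.partner[0], p.partner[1], "")
        dc = pair_min_distance(closed, ka, kb, conv)
        do = pair_min_distance(opened, ka, kb, conv)
        if p.kind == "closed_state" and not (dc <= 4.0 and do >= 8.0):
            raise GeneratorError(f"closed-state pair {p.basic}-{p.partner}: "
                                 f"closed {dc:.2f} A, open {do:.2f} A")
        if p.kind == "open_state" and not (do <= 4.0 and dc >= 8.0):
            raise GeneratorError(f"open-state pair {p.basic}-{p.partner}: "
                                 f"closed {dc:.2f} A, open {do:.2f} A")
        if p.kind == "persistent" and not (dc <= 4.0 and do <= 4.0):
            raise GeneratorError(f"persistent pair {p.basic}-{p.partner}: "
                                 f"closed {dc:.2f} A, open {do:.2f} A")

    from .accessibility import neighbor_residues
    probe = (spec.probe[0], spec.probe[1], "")
    n_open = len(neighbor_residues(opened, probe, 5.0))
    n_closed = len(neighbor_residues(closed, probe, 5.0))
    if not (n_open >= 4 and n_closed <= 1):
        raise GeneratorError(
            f"probe occlusion: {n_open} neighbours open, {n_closed} closed")

    # closed constriction: the gate must genuinely block the mouth — check
    # with the pore profiler itself (coarse slices over the gate region)
    from .poreprofile import PoreParams, radius_at_slice
    from .structio import assign_radii
    gated = assign_radii(closed.copy())
    params = PoreParams(search_bound=3.0)
    min_r = min(radius_at_slice(gated, z, params)[0]
                for z in np.arange(6.0, DEFAULT_TM_SPAN[1] + 0.5, 1.0))
    if min_r >= 1.8:
        raise GeneratorError(f"closed gate does not block: min radius {min_r:.2f} A")


# ---------------------------------------------------------------------------
# transition trajectory
# ---------------------------------------------------------------------------

def smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    u = np.clip(u, 0.0, 1.0)
    return 3.0 * u ** 2 - 2.0 * u ** 3


DEFAULT_STAGE_WINDOWS = {
    "NBD-like": (0.10, 0.50),
    "ICL-like": (0.45, 0.70),
    "ECL-like": (0.50, 0.75),
    "TM-like": (0.55, 0.90),
}

DEFAULT_SWITCH_FRACTIONS = {
    (("A", 2), ("B", 2)): 0.40,
    (("C", 2), ("D", 2)): 0.45,
    (("B", 7), ("C", 7)): 0.58,
    (("D", 7), ("E", 7)): 0.62,
    (("B", 19), ("C", 19)): 0.63,
    (("A", 13), ("B", 13)): 0.64,
    (("D", 13), ("E", 13)): 0.66,
}


@dataclass
class TransitionSpec:
    """Staged closed -> open interpolation with planted event timing."""

    n_frames: int = 201
    duration_ns: float = 10.0
    stage_windows: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_WINDOWS))
    switch_fractions: dict | None = field(
        default_factory=lambda: dict(DEFAULT_SWITCH_FRACTIONS))
    noise_sigma: float = 0.0
    cutoff: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        order = ["NBD-like", "ICL-like", "TM-like"]
        starts = [self.stage_windows[r][0] for r in order if r in self.stage_windows]
        if starts != sorted(starts):
            raise ValueError("stage windows must be ordered NBD -> ICL -> TM")


def _pair_window(xc_a, xo_a, xc_b, xo_b, cutoff: float, switch_frac: float,
                 width: float) -> tuple[float, float]:
    """Stage window for a planted pair so its contact crosses *cutoff* at switch_frac.

    The pair's beads interpolate linearly in the morph coordinate u; we find
    the u where the minimum inter-residue distance crosses the cutoff, then
    back out the time window so smoothstep progress hits that u at the
    switch fraction.
    """
    us = np.linspace(0.0, 1.0, 401)

    def dist(u):
        a = xc_a + u * (xo_a - xc_a)
        b = xc_b + u * (xo_b - xc_b)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return d.min()

    d = np.array([dist(u) for u in us])
    crossing = None
    for i in range(len(us) - 1):
        if (d[i] - cutoff) * (d[i + 1] - cutoff) <= 0 and d[i] != d[i + 1]:
            crossing = brentq(lambda u: dist(u) - cutoff, us[i], us[i + 1])
            break
    if crossing is None:
        raise GeneratorError("planted pair never crosses the cutoff along the morph")
    # invert the smoothstep: g(v) = crossing
    v = brentq(lambda v: smoothstep(v) - crossing, 0.0, 1.0)
    a = switch_frac - v * width
    return a, a + width


def make_transition_trajectory(closed: Structure, opened: Structure,
                               spec: TransitionSpec | None = None,
                               region_map: dict | None = None) -> Trajectory:
    """Staged interpolation from closed to open with planted event times."""
    spec = spec or TransitionSpec()
    if len(closed) != len(opened) or \
       [(a.chain_id, a.residue_key, a.name) for a in closed.atoms] != \
       [(a.chain_id, a.residue_key, a.name) for a in opened.atoms]:
        raise ValueError("closed and open structures must be congruent")
    region_map = region_map or default_region_map()
    rng = np.random.default_rng(spec.seed)

    xc, xo = closed.coords, opened.coords
    n_atoms = len(closed)
    windows = np.empty((n_atoms, 2))
    for i, atom in enumerate(closed.atoms):
        region = region_map.get(atom.residue_key, "TM-like")
        windows[i] = spec.stage_windows.get(region, (0.0, 1.0))

    if spec.switch_fractions:
        for (res_a, res_b), frac in spec.switch_fractions.items():
            ka = (res_a[0], res_a[1], "")
            kb = (res_b[0], res_b[1], "")
            ia = np.array(closed.residue_index[ka])
            ib = np.array(closed.residue_index[kb])
            # the crossing is measured on side-chain beads, matching the
            # distance convention of the contact analyses
            sa = np.array([i for i in ia if closed.atoms[i].name != "CA"])
            sb = np.array([i for i in ib if closed.atoms[i].name != "CA"])
            region = region_map.get(ka, "TM-like")
            lo, hi = spec.stage_windows.get(region, (0.0, 1.0))
            a, b = _pair_window(xc[sa], xo[sa], xc[sb], xo[sb],
                                spec.cutoff, frac, hi - lo)
            windows[ia] = (a, b)
            windows[ib] = (a, b)

    times = np.linspace(0.0, spec.duration_ns, spec.n_frames)
    frames = []
    for t in times:
        frac = t / spec.duration_ns if spec.duration_ns > 0 else 0.0
        u = smoothstep((frac - windows[:, 0]) / np.maximum(windows[:, 1] - windows[:, 0], 1e-12))
        x = xc + u[:, None] * (xo - xc)
        if spec.noise_sigma > 0:
            x = x + rng.normal(0.0, spec.noise_sigma, x.shape)
        frames.append(x)
    return Trajectory(closed.copy(), frames, times)


# ---------------------------------------------------------------------------
# simple trace and alignment fixtures
# ---------------------------------------------------------------------------

def make_trace_fixture(event_type: str, switch_frame: int, n_frames: int,
                       levels: tuple[float, float] = (4.0, 9.0),
                       noise_sigma: float = 0.0, seed: int = 0,
                       duration_ns: float = 10.0) -> ContactSeries:
    """Step-plus-noise distance trace with an exact planted switch frame."""
    bound, unbound = levels
    if not (bound < 5.0 < unbound):
        raise ValueError("levels must straddle the 5 A cutoff")
    if not (0 < switch_frame < n_frames):
        raise ValueError("switch_frame must lie inside the trajectory")
    rng = np.random.default_rng(seed)
    d = np.empty(n_frames)
    if event_type == "breaking":
        d[:switch_frame] = bound
        d[switch_frame:] = unbound
    elif event_type == "formation":
        d[:switch_frame] = unbound
        d[switch_frame:] = bound
    else:
        raise ValueError(f"unknown event type {event_type!r}")
    if noise_sigma > 0:
        d = d + rng.normal(0.0, noise_sigma, n_frames)
    times = np.linspace(0.0, duration_ns, n_frames)
    return ContactSeries(("A", 1), ("B", 1), "acidic", d, times)


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_alignment_fixture(length: int = 60, n_mutations: int = 6,
                           gap: tuple[int, int] = (30, 3), seed: int = 0,
                           window: int = 13) -> tuple[ProfileSet, ProfileSet, Alignment]:
    """Profile pair derived from one ancestor, with a planted indel and truth.

    Profile A follows the query convention (binary 0/100 pore accessibility
    inside the membrane span); profile B follows the template convention
    (percent SASA, correlated with A's calls: accessible ~ U(60, 100),
    buried ~ U(0, 15)).
    """
    rng = np.random.default_rng(seed)
    gap_pos, gap_len = gap
    if gap_len and not (0 <= gap_pos and gap_pos + gap_len <= length):
        raise ValueError("gap plan outside sequence")

    seq_a = "".join(rng.choice(list(AA20)) for _ in range(length))
    third = length // 3
    topology = "I" * third + "M" * (length - 2 * third) + "O" * third
    ss = "".join("H" if topology[i] == "M" or rng.random() < 0.3 else "C"
                 for i in range(length))
    accessible = np.array([topology[i] == "M" and i % 3 == 0 for i in range(length)])

    seq_b = list(seq_a)
    mut_sites = rng.choice(length, size=min(n_mutations, length), replace=False)
    for site in mut_sites:
        choices = [a for a in AA20 if a != seq_b[site]]
        seq_b[site] = str(rng.choice(choices))

    keep = [i for i in range(length) if not (gap_pos <= i < gap_pos + gap_len)]
    seq_b_str = "".join(seq_b[i] for i in keep)
    topo_b = "".join(topology[i] for i in keep)
    ss_b = "".join(ss[i] for i in keep)

    acc_a = np.where(np.array([t == "M" for t in topology]),
                     np.where(accessible, 100.0, 0.0), np.nan)
    acc_b_full = np.where(accessible, rng.uniform(60.0, 100.0, length),
                          rng.uniform(0.0, 15.0, length))
    acc_b = np.where(np.array([t == "M" for t in topo_b]),
                     acc_b_full[keep], np.nan)

    prof_a = ProfileSet(seq_a, windowed_hydropathy(seq_a, window), ss, topology, acc_a)
    prof_b = ProfileSet(seq_b_str, windowed_hydropathy(seq_b_str, window),
                        ss_b, topo_b, acc_b)

    columns = []
    j = 0
    for i in range(length):
        if gap_pos <= i < gap_pos + gap_len:
            columns.append((i, None))
        else:
            columns.append((i, j))
            j += 1
    truth = Alignment(columns, score=float("nan"))
    return prof_a, prof_b, truth


def write_fixture(outdir: str | Path, spec: ChannelSpec | None = None) -> dict:
    """Write closed/open PDBs, the region map TSV, and the planted-truth JSON."""
    spec = spec or ChannelSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    closed, opened = make_two_state_channel(spec)
    write_pdb(closed, outdir / "closed.pdb")
    write_pdb(opened, outdir / "open.pdb")
    rmap = default_region_map(spec)
    (outdir / "region_map.tsv").write_text(region_map_tsv(rmap))
    truth = {
        "planted_pairs": [
            {"basic": list(p.basic), "partner": list(p.partner), "kind": p.kind,
             "region": p.region, "bound_distance_A": p.bound_distance}
            for p in spec.planted
        ],
        "probe": list(spec.probe),
        "tm_span_A": list(DEFAULT_TM_SPAN),
        "seed": spec.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
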