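"""Coarse-grained Langevin engine with a targeted-MD (TMD) bias.

The TMD bias is a harmonic penalty on the deviation of the instantaneous
best-fit RMSD to a target structure from a prescribed schedule::

    U_TMD(t) = (k/2) * (RMS(t) - RMS*(t))**2

where ``RMS(t)`` is the best-fit RMSD of the biased beads to the target and
``RMS*(t)`` decays linearly from the initial RMSD to zero over the run, so the
bias steadily drags the system into the target conformation.  The force
constant default is 5 kcal/(mol A^2) and the bias acts on the backbone beads.
The bias gradient is analytic: at the optimal superposition the rotational
and translational stationarity conditions make the alignment's contribution
vanish, leaving ``dRMS/dx_i = (x_i - y_i') / (N * RMS)`` with ``y'`` the
target fitted onto the instantaneous coordinates.

The physical force field is a two-state structure-based (Go-like) model:

* bonds along each chain backbone and to side-chain beads (flat-bottomed
  between the two endpoint lengths, stiff outside),
* backbone angles: stiff harmonic where the states agree, bistable Gaussian
  wells at the two endpoint values at the hinges,
* a purely repulsive WCA-style soft core between non-bonded beads, with
  per-pair diameters capped by native (endpoint-state) separations,
* contact terms: flat-bottom tethers for pairs whose separation barely
  changes between states, Gaussian wells at the native distance for
  contacts formed in the target state (deep) and lost from the start state
  (weak).

Bonds and conserved contacts are flat-bottomed between their two endpoint
values and hinge angles carry a Gaussian well at each endpoint value, so
both endpoint structures are genuine force-field minima with no pull toward
the midpoint of the two states.  The open state is the deeper basin (it
gains the dense cytosolic-dimer contacts), so the biased opening run is a
downhill crossing that settles tightly into the target; see the methods
note for what this desk-scale model does and does not reproduce of the
full-scale kinetics.

Internal units: length A, energy kcal/mol, mass amu, time ps (inputs in
ns/fs where noted).  All stochastic terms come from a single seeded
generator; identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import kabsch_superpose
from .structio import Structure, Trajectory, write_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "KB",
    "Schedule",
    "TMDParams",
    "ToyFFParams",
    "ToyTopology",
    "TMDResult",
    "IntegrationError",
    "rms_star",
    "tmd_bias",
    "build_topology",
    "integrate",
    "run_opening",
]

KB = 0.0019872041          # kcal/(mol K)
ACC = 418.4                # (kcal/mol/A)/amu -> A/ps^2
SNAPSHOT_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)



def _scatter(F: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    """Accumulate per-pair force contributions (bincount is much faster than add.at)."""
    n = F.shape[0]
    for d in range(3):
        F[:, d] += np.bincount(idx, weights=contrib[:, d], minlength=n)


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration (message carries the frame index)."""


@dataclass
class Schedule:
    """Linear RMS* schedule: from the initial RMSD to zero over the run."""

    rms0: float
    total_time: float  # ns

    def __post_init__(self) -> None:
        if self.rms0 < 0:
            raise ValueError("rms0 must be >= 0")
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")


def rms_star(t: float, schedule: Schedule) -> float:
    """Target RMSD at time *t* (ns): rms0 * (1 - t / total_time)."""
    if not (0.0 <= t <= schedule.total_time * (1 + 1e-12)):
        raise ValueError(f"t = {t} ns outside schedule range [0, {schedule.total_time}]")
    return schedule.rms0 * (1.0 - min(t / schedule.total_time, 1.0))


@dataclass
class TMDParams:
    """Run parameters for the biased Langevin integrator.

    ``duration`` is in ns, ``timestep`` in fs, ``friction`` in 1/ps.  The
    desk-scale default duration (0.2 ns) plays the role of the full-scale
    10 ns schedule; the schedule is dimensionless in t/T so snapshot
    fractions transfer directly.
    """

    k_tmd: float = 5.0
    duration: float = 0.2
    timestep: float = 5.0
    temperature: float = 300.0
    friction: float = 0.5
    seed: int = 0
    stride: int = 40
    bias_subset: np.ndarray | None = None
    target: np.ndarray | None = None
    per_atom_normalized: bool = False
    one_sided: bool = False

    def __post_init__(self) -> None:
        if self.k_tmd < 0:
            raise ValueError("k_tmd must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not (0.5 < self.timestep < 10.0):
            raise ValueError("timestep must lie in (0.5, 10) fs")
        if self.bias_subset is not None:
            self.bias_subset = np.asarray(self.bias_subset, dtype=int)
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)


@dataclass
class ToyFFParams:
    """Force-field constants for the two-state coarse-grained model.

    Defaults were chosen once for the synthetic channel fixtures: bonds,
    structural angles and conserved-contact tethers stiff enough to keep
    local geometry essentially rigid on the run timescale; hinge angles
    bistable with depth scaled by the hinge amplitude; target-contact wells
    deep enough that end-state fluctuations stay well below the bias
    convergence scale; lost-contact wells weak; the soft core forgiving
    enough that segments can slide past each other during the collective
    rearrangement.
    """

    k_bond: float = 100.0          # kcal/(mol A^2)
    k_angle: float = 20.0          # kcal/(mol rad^2)
    hinge_depth_per_rad: float = 4.0  # kcal/mol per rad of hinge amplitude
    hinge_depth_max: float = 5.0   # kcal/mol cap on hinge well depth
    hinge_width: float = 0.12      # rad, hinge well width
    hinge_threshold: float = 0.15  # rad, |dtheta| above which an angle is a hinge
    rep_eps: float = 0.1           # kcal/mol
    rep_scale: float = 0.75        # sigma_ij = scale * (r_i + r_j)
    rep_radius: float = 1.7        # per-bead repulsion radius, A
    rep_cutoff: float = 12.0       # pairs never nearer than this carry no soft core, A
    well_cutoff: float = 8.0       # contact definition distance, A
    well_width: float = 0.5        # Gaussian well width, A
    depth_target: float = 3.0      # kcal/mol, contacts formed in the target state
    depth_source: float = 0.15     # kcal/mol, contacts lost from the start state
    conserved_tol: float = 1.5     # |dA - dB| below which a contact is conserved, A
    k_wall: float = 20.0           # kcal/(mol A^2), flat-bottom wall stiffness
    mass: float = 110.0            # amu per bead


class ToyTopology:
    """Bead topology: bonds, angles, soft-core pairs and contact wells."""

    def __init__(self, structure: Structure, bonds, angles, nb_pairs, nb_sigma,
                 wells, masses, backbone: np.ndarray, ff: ToyFFParams):
        self.structure = structure
        self.n = len(structure)
        # bonds: (i, j, r_lo, r_hi, k) — flat-bottom between the endpoint values
        self.bond_i, self.bond_j, self.bond_lo, self.bond_hi, self.bond_k = bonds
        # angles: (i, j(vertex), k, theta_a, theta_b, k_harmonic, well_depth)
        (self.ang_i, self.ang_j, self.ang_k, self.ang_t1, self.ang_t2,
         self.ang_ka, self.ang_ah) = angles
        self.nb_i, self.nb_j = nb_pairs
        self.nb_sigma = nb_sigma
        # wells: (i, j, d1, d2, depth1, depth2, width) Gaussian contact wells,
        # plus flat-bottom pairs (i, j, lo, hi) for conserved contacts
        (self.w_i, self.w_j, self.w_d1, self.w_d2,
         self.w_a1, self.w_a2, self.w_width,
         self.fb_i, self.fb_j, self.fb_lo, self.fb_hi) = wells
        self.masses = masses
        self.backbone = backbone
        self.ff = ff
        if len(self.bond_i) and not _connected(self.n, self.bond_i, self.bond_j, structure):
            raise ValueError("bond graph is not connected within each chain")

    def energy_forces(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Physical potential energy and forces at coordinates *x*."""
        F = np.zeros_like(x)
        E = 0.0

        if len(self.bond_i):
            d = x[self.bond_i] - x[self.bond_j]
            r = np.linalg.norm(d, axis=1)
            dr = np.where(r < self.bond_lo, r - self.bond_lo,
                          np.where(r > self.bond_hi, r - self.bond_hi, 0.0))
            E += float(np.sum(0.5 * self.bond_k * dr ** 2))
            f = (-self.bond_k * dr / r)[:, None] * d
            _scatter(F, self.bond_i, f)
            _scatter(F, self.bond_j, -f)

        if len(self.ang_i):
            u = x[self.ang_i] - x[self.ang_j]
            w = x[self.ang_k] - x[self.ang_j]
            nu = np.linalg.norm(u, axis=1)
            nw = np.linalg.norm(w, axis=1)
            c = np.clip(np.einsum("ij,ij->i", u, w) / (nu * nw), -1.0, 1.0)
            s = np.sqrt(np.maximum(1.0 - c ** 2, 1e-12))
            theta = np.arccos(c)
            dt = theta - self.ang_t1
            E += float(np.sum(0.5 * self.ang_ka * dt ** 2))
            dUdtheta = self.ang_ka * dt
            if np.any(self.ang_ah > 0):
                wh2 = self.ff.hinge_width ** 2
                g1 = np.exp(-((theta - self.ang_t1) ** 2) / (2 * wh2))
                g2 = np.exp(-((theta - self.ang_t2) ** 2) / (2 * wh2))
                E += float(np.sum(-self.ang_ah * (g1 + g2)))
                dUdtheta = dUdtheta + self.ang_ah * (
                    (theta - self.ang_t1) * g1 + (theta - self.ang_t2) * g2) / wh2
            coef = (dUdtheta / s)
            uhat = u / nu[:, None]
            what = w / nw[:, None]
            fi = -(coef / nu)[:, None] * (c[:, None] * uhat - what)
            fk = -(coef / nw)[:, None] * (c[:, None] * what - uhat)
            _scatter(F, self.ang_i, fi)
            _scatter(F, self.ang_k, fk)
            _scatter(F, self.ang_j, -(fi + fk))

        if len(self.nb_i):
            d = x[self.nb_i] - x[self.nb_j]
            r = np.linalg.norm(d, axis=1)
            mask = r < self.nb_sigma
            if np.any(mask):
                rr = r[mask]
                sig = self.nb_sigma[mask]
                sr6 = (sig / rr) ** 6
                E += float(np.sum(self.ff.rep_eps * (sr6 ** 2 - 2.0 * sr6 + 1.0)))
                dUdr = self.ff.rep_eps * (-12.0 * sr6 ** 2 + 12.0 * sr6) / rr
                f = (-dUdr / rr)[:, None] * d[mask]
                _scatter(F, self.nb_i[mask], f)
                _scatter(F, self.nb_j[mask], -f)

        if len(self.w_i):
            d = x[self.w_i] - x[self.w_j]
            r = np.linalg.norm(d, axis=1)
            w2 = self.w_width ** 2
            g1 = np.exp(-((r - self.w_d1) ** 2) / (2 * w2))
            g2 = np.exp(-((r - self.w_d2) ** 2) / (2 * w2))
            E += float(np.sum(-self.w_a1 * g1 - self.w_a2 * g2))
            dUdr = (self.w_a1 * (r - self.w_d1) * g1 + self.w_a2 * (r - self.w_d2) * g2) / w2
            f = (-dUdr / r)[:, None] * d
            _scatter(F, self.w_i, f)
            _scatter(F, self.w_j, -f)

        if len(self.fb_i):
            d = x[self.fb_i] - x[self.fb_j]
            r = np.linalg.norm(d, axis=1)
            dr = np.where(r < self.fb_lo, r - self.fb_lo,
                          np.where(r > self.fb_hi, r - self.fb_hi, 0.0))
            E += float(np.sum(0.5 * self.ff.k_wall * dr ** 2))
            f = (-self.ff.k_wall * dr / r)[:, None] * d
            _scatter(F, self.fb_i, f)
            _scatter(F, self.fb_j, -f)

        return E, F


def _connected(n: int, bi, bj, structure: Structure) -> bool:
    """Check every chain's beads form one bond-connected component."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(bi, bj):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    chains: dict[str, set[int]] = {}
    for i, atom in enumerate(structure.atoms):
        chains.setdefault(atom.chain_id, set()).add(find(i))
    return all(len(roots) == 1 for roots in chains.values())


def build_topology(closed: Structure, open_state: Structure | None = None,
                   ff: ToyFFParams | None = None) -> ToyTopology:
    """Build the coarse-grained topology from one or two endpoint structures.

    With two structures the bonded reference values are state means and the
    contact wells encode both states (two-state model); with one structure
    the wells stabilise that single state.
    """
    ff = ff or ToyFFParams()
    xa = closed.coords
    xb = open_state.coords if open_state is not None else xa
    if open_state is not None and len(open_state) != len(closed):
        raise ValueError("closed and open structures must be congruent")
    n = len(closed)

    # backbone beads and per-chain residue ordering
    backbone = np.array([i for i, a in enumerate(closed.atoms) if a.name == "CA"], dtype=int)

    bonds: list[tuple[int, int]] = []
    # consecutive CA along each chain (atom order defines the chain walk)
    prev_ca: dict[str, int] = {}
    res_ca: dict[tuple, int] = {}
    for key in closed.residue_keys():
        idxs = closed.residue_index[key]
        ca = next((i for i in idxs if closed.atoms[i].name == "CA"), None)
        if ca is None:
            continue
        res_ca[key] = ca
        chain = key[0]
        if chain in prev_ca:
            bonds.append((prev_ca[chain], ca))
        prev_ca[chain] = ca
        for i in idxs:
            if i != ca:
                bonds.append((ca, i))

    angle_triplets: list[tuple[int, int, int]] = []
    chain_cas: dict[str, list[int]] = {}
    for key, ca in res_ca.items():
        chain_cas.setdefault(key[0], []).append(ca)
    for cas in chain_cas.values():
        for a, b, c in zip(cas, cas[1:], cas[2:]):
            angle_triplets.append((a, b, c))

    bi = np.array([b[0] for b in bonds], dtype=int)
    bj = np.array([b[1] for b in bonds], dtype=int)
    ra = np.linalg.norm(xa[bi] - xa[bj], axis=1)
    rb = np.linalg.norm(xb[bi] - xb[bj], axis=1)
    # flat-bottom between the two endpoint lengths: rigid where the states
    # agree, free to slide between them where they differ (ramp bonds)
    bond_lo = np.minimum(ra, rb)
    bond_hi = np.maximum(ra, rb)
    bond_k = np.full(len(bonds), ff.k_bond)

    ai = np.array([t[0] for t in angle_triplets], dtype=int)
    aj = np.array([t[1] for t in angle_triplets], dtype=int)
    ak = np.array([t[2] for t in angle_triplets], dtype=int)

    def _angles(x):
        u = x[ai] - x[aj]
        w = x[ak] - x[aj]
        c = np.einsum("ij,ij->i", u, w) / (np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1))
        return np.arccos(np.clip(c, -1, 1))

    if len(ai):
        ta, tb = _angles(xa), _angles(xb)
        hinge = np.abs(ta - tb) > ff.hinge_threshold
        # structural angles: stiff harmonic at the (state-shared) value;
        # hinge angles: bistable, a Gaussian well at each endpoint value with
        # depth scaled by the hinge amplitude — larger motions latch harder,
        # but also feel proportionally larger bias force, so the staged
        # release order follows the motion hierarchy
        t1 = np.where(hinge, ta, 0.5 * (ta + tb))
        t2 = np.where(hinge, tb, 0.5 * (ta + tb))
        ang_ka = np.where(hinge, 0.0, ff.k_angle)
        ang_ah = np.where(hinge,
                          np.minimum(ff.hinge_depth_max,
                                     ff.hinge_depth_per_rad * np.abs(ta - tb)),
                          0.0)
    else:
        t1 = t2 = np.zeros(0)
        ang_ka = np.zeros(0)
        ang_ah = np.zeros(0)

    excluded = set()
    for a, b in bonds:
        excluded.add((min(a, b), max(a, b)))
    for a, _, c in angle_triplets:
        excluded.add((min(a, c), max(a, c)))

    iu, ju = np.triu_indices(n, k=1)
    keep = np.array([(a, b) not in excluded for a, b in zip(iu, ju)])
    nb_i, nb_j = iu[keep], ju[keep]

    da = np.linalg.norm(xa[nb_i] - xa[nb_j], axis=1)
    db = np.linalg.norm(xb[nb_i] - xb[nb_j], axis=1)
    # structure-based excluded volume: a pair may not come closer than 92% of
    # its smallest native (endpoint-state) separation, capped by the generic
    # bead diameter — dense native packing is respected, non-native clashes
    # are still repelled
    nb_sigma = np.minimum(np.full(len(nb_i), 2.0 * ff.rep_radius * ff.rep_scale),
                          0.92 * np.minimum(da, db))
    near = np.minimum(da, db) < ff.rep_cutoff
    nb_i, nb_j, nb_sigma = nb_i[near], nb_j[near], nb_sigma[near]
    da, db = da[near], db[near]

    # contact wells: conserved contacts get one deep well at the shared
    # distance; contacts formed only in the target state get a deep well
    # there (a Gaussian well exerts no force until approached, so these grip
    # the end state without resisting the transition); contacts lost from
    # the start state get a weak well — they define the start basin but can
    # be broken by the biased transition at modest cost
    contact = (da <= ff.well_cutoff) | (db <= ff.well_cutoff)
    ci, cj = nb_i[contact], nb_j[contact]
    cda, cdb = da[contact], db[contact]
    # a pair is "conserved" whenever its separation barely changes between
    # states, regardless of which side of the contact cutoff it sits on —
    # otherwise near-cutoff pairs would acquire a deep well right next to
    # their other-state distance and exert a spurious coherent pull
    conserved = np.abs(cda - cdb) < ff.conserved_tol
    # conserved contacts become flat-bottom tethers spanning the two endpoint
    # distances: stiff outside the interval, force-free inside — they hold
    # the local structure together in both states without pulling either
    # state toward the midpoint of the two
    fb_i, fb_j = ci[conserved], cj[conserved]
    fb_lo = np.minimum(cda, cdb)[conserved]
    fb_hi = np.maximum(cda, cdb)[conserved]
    keepw = ~conserved
    ci, cj = ci[keepw], cj[keepw]
    cda, cdb = cda[keepw], cdb[keepw]
    d1 = cda
    d2 = cdb
    a1 = np.where(cda <= ff.well_cutoff, ff.depth_source, 0.0)
    a2 = np.where(cdb <= ff.well_cutoff, ff.depth_target, 0.0)

    masses = np.full(n, ff.mass)
    return ToyTopology(
        closed.copy(),
        (bi, bj, bond_lo, bond_hi, bond_k),
        (ai, aj, ak, t1, t2, ang_ka, ang_ah),
        (nb_i, nb_j), nb_sigma,
        (ci, cj, d1, d2, a1, a2, ff.well_width, fb_i, fb_j, fb_lo, fb_hi),
        masses, backbone, ff,
    )


# ---------------------------------------------------------------------------
# TMD bias
# ---------------------------------------------------------------------------

def tmd_bias(coords: np.ndarray, params: TMDParams, t: float,
             schedule: Schedule) -> tuple[float, np.ndarray]:
    """Bias energy (kcal/mol) and per-bead forces at time *t* (ns).

    Beads outside the bias subset receive zero force.  The gradient is exact
    through the best-fit alignment (envelope theorem: the optimal rotation
    and translation are stationary).
    """
    coords = np.asarray(coords, dtype=float)
    subset = params.bias_subset if params.bias_subset is not None else np.arange(len(coords))
    target = params.target
    if target is None:
        raise ValueError("TMDParams.target is required for the bias")
    tgt = target[subset] if len(target) == len(coords) else target
    X = coords[subset]
    transform, rms = kabsch_superpose(tgt, X)
    star = rms_star(t, schedule)
    delta = rms - star
    kfac = params.k_tmd / (len(subset) if params.per_atom_normalized else 1.0)
    forces = np.zeros_like(coords)
    if params.one_sided and delta <= 0:
        return 0.0, forces
    energy = 0.5 * kfac * delta ** 2
    if rms > 1e-10:
        aligned = transform.apply(tgt)
        grad = kfac * delta * (X - aligned) / (len(subset) * rms)
        forces[subset] = -grad
    return float(energy), forces


@dataclass
class TMDResult:
    """Trajectory plus per-frame RMS(t), RMS*(t) and bias-energy traces."""

    trajectory: Trajectory
    rmsd_trace: np.ndarray
    rms_star_trace: np.ndarray
    bias_energy_trace: np.ndarray
    kinetic_trace: np.ndarray
    potential_trace: np.ndarray
    schedule: Schedule | None
    params: TMDParams
    snapshots: list[tuple[float, Structure]] = field(default_factory=list)

    @property
    def final_rmsd(self) -> float:
        return float(self.rmsd_trace[-1])

    def traces_tsv(self) -> str:
        lines = ["time_ns\trms\trms_star\tbias_energy"]
        for t, r, s, e in zip(self.trajectory.times, self.rmsd_trace,
                              self.rms_star_trace, self.bias_energy_trace):
            lines.append(f"{t:.6f}\t{r:.4f}\t{s:.4f}\t{e:.6f}")
        return "\n".join(lines) + "\n"


def integrate(topology: ToyTopology, start: np.ndarray, params: TMDParams,
              schedule: Schedule | None = None) -> TMDResult:
    """Propagate BAOAB Langevin dynamics with the TMD bias.

    With ``friction = 0`` the O-step is the identity and the scheme reduces
    to velocity Verlet (NVE apart from the time-dependent bias).  Frames and
    traces are recorded every ``params.stride`` steps, the initial and final
    configurations always included.
    """
    x = np.array(start, dtype=float)
    if x.shape != (topology.n, 3):
        raise ValueError("start coordinates not congruent with topology")
    rng = np.random.default_rng(params.seed)
    dt = params.timestep * 1e-3                       # ps
    n_steps = max(1, round(params.duration * 1000.0 / dt))
    m = topology.masses[:, None]

    biased = params.k_tmd > 0 and params.target is not None
    if biased:
        if params.bias_subset is None:
            params.bias_subset = topology.backbone
        subset = params.bias_subset
        tgt = params.target[subset] if len(params.target) == topology.n else params.target
        if schedule is None:
            _, rms0 = kabsch_superpose(tgt, x[subset])
            schedule = Schedule(rms0=rms0, total_time=params.duration)

    kT = KB * params.temperature
    v = rng.standard_normal(x.shape) * np.sqrt(kT * ACC / topology.masses)[:, None]
    if params.friction > 0:
        c1 = np.exp(-params.friction * dt)
        c2 = np.sqrt(max(1.0 - c1 ** 2, 0.0))
    else:
        c1, c2 = 1.0, 0.0
    sigma_v = np.sqrt(kT * ACC / topology.masses)[:, None]

    def total_force(xx, t_ns):
        try:
            e_phys, f = topology.energy_forces(xx)
            e_bias = 0.0
            if biased:
                e_bias, f_bias = tmd_bias(xx, params, t_ns, schedule)
                f = f + f_bias
        except (ValueError, FloatingPointError) as exc:
            raise IntegrationError(
                f"numerical blow-up near recorded frame {len(frames) - 1}: {exc}"
            ) from exc
        return e_phys, e_bias, f

    frames, times, rms_tr, star_tr, ebias_tr, ke_tr, pe_tr = [], [], [], [], [], [], []

    def record(step, e_phys, e_bias):
        t_ns = step * dt * 1e-3
        frames.append(x.copy())
        times.append(t_ns)
        ke = 0.5 * float(np.sum(topology.masses[:, None] * v ** 2)) / ACC
        ke_tr.append(ke)
        pe_tr.append(e_phys)
        ebias_tr.append(e_bias)
        if biased:
            _, r = kabsch_superpose(tgt, x[params.bias_subset])
            rms_tr.append(r)
            star_tr.append(rms_star(t_ns, schedule))
        else:
            rms_tr.append(np.nan)
            star_tr.append(np.nan)
        if not np.isfinite(e_phys) or np.abs(x).max() > 1e6:
            raise IntegrationError(
                f"numerical blow-up at recorded frame {len(frames) - 1} (step {step})")

    e_phys, e_bias, F = total_force(x, 0.0)
    record(0, e_phys, e_bias)
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * ACC * F / m
        x += 0.5 * dt * v
        if params.friction > 0:
            v = c1 * v + c2 * sigma_v * rng.standard_normal(v.shape)
        x += 0.5 * dt * v
        t_ns = step * dt * 1e-3
        e_phys, e_bias, F = total_force(x, min(t_ns, params.duration))
        v += 0.5 * dt * ACC * F / m
        if step % params.stride == 0 or step == n_steps:
            record(step, e_phys, e_bias)

    traj = Trajectory(topology.structure, frames, times)
    return TMDResult(traj, np.array(rms_tr), np.array(star_tr), np.array(ebias_tr),
                     np.array(ke_tr), np.array(pe_tr), schedule, params)


def run_opening(closed: Structure, open_target: Structure,
                params: TMDParams | None = None, ff: ToyFFParams | None = None,
                outdir: str | Path | None = None) -> TMDResult:
    """Drive the closed structure into the open target with the TMD schedule.

    Builds the two-state topology, integrates, and records snapshots at
    fractions 0, 1/4, 1/2, 3/4 and 1 of the duration (the full-scale analogue
    saved snapshots at 0/2.5/5/7.5/10 ns of a 10 ns run).  Snapshots are
    written as PDB when *outdir* is given.
    """
    if [(a.chain_id, a.residue_key, a.name) for a in closed.atoms] != \
       [(a.chain_id, a.residue_key, a.name) for a in open_target.atoms]:
        raise ValueError("closed and open structures must share atom ordering")
    params = params or TMDParams()
    topo = build_topology(closed, open_target, ff)
    if params.target is None:
        params.target = open_target.coords
    if params.bias_subset is None:
        params.bias_subset = topo.backbone
    result = integrate(topo, closed.coords, params)

    n_frames = len(result.trajectory)
    start = closed.coords
    for frac in SNAPSHOT_FRACTIONS:
        idx = round(frac * (n_frames - 1))
        frame = result.trajectory.frames[idx]
        # remove accumulated rigid-body diffusion so snapshots stay in the
        # input frame (the pore axis is defined there)
        transform, _ = kabsch_superpose(frame[topo.backbone], start[topo.backbone])
        snap = result.trajectory.topology.with_coords(transform.apply(frame))
        result.snapshots.append((float(result.trajectory.times[idx]), snap))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for frac, (t, snap) in zip(SNAPSHOT_FRACTIONS, result.snapshots):
            write_pdb(snap, outdir / f"snapshot_{frac:.2f}.pdb")
    logger.info("run_opening: final best-fit RMSD %.3f A over %d biased beads",
                result.final_rmsd, len(params.bias_subset))
    return result
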