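"""HOLE-style pore radius profiling along the membrane normal.

At each slice position z along the pore axis, the pore radius is the radius
of the largest sphere centred in the slice plane that does not overlap any
atom's van der Waals sphere:

    radius(z) = max over c in plane of  min over atoms a ( |c - a| - r_a )

A blocked slice reports the (negative or zero) maximal value rather than
clamping, preserving the shape of occluded profiles.  The optimizer is
deterministic (coarse grid then Nelder-Mead refinement) rather than HOLE's
simulated annealing, and each slice is warm-started from the previous centre
so the centre path follows the channel; a refined centre jumping more than
5 A triggers a fresh grid search.

Classification thresholds follow the conventions used for CFTR profiles:
slices are blocked below 1.8 A radius, narrow below 3.0 A, wide above, and a
channel is open when every transmembrane slice's diameter clears the 3.6 A
diameter of a dehydrated chloride ion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .structio import Structure

__all__ = [
    "PoreParams",
    "PoreSlice",
    "PoreProfile",
    "radius_at_slice",
    "profile",
    "classify_profile",
    "SegmentReport",
]


@dataclass
class PoreParams:
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    z_range: tuple[float, float] = (-15.0, 15.0)
    slice_spacing: float = 0.5
    search_bound: float = 10.0       # in-plane half-width of the centre search, A
    open_radius: float = 1.8         # below: blocked (red)
    wide_radius: float = 3.0         # above: wide (blue)
    chloride_diameter: float = 3.6   # dehydrated chloride ion, A
    grid_step: float = 0.5
    jump_tolerance: float = 5.0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be > 0")
        if not self.open_radius < self.wide_radius:
            raise ValueError("open_radius must be < wide_radius")


@dataclass
class PoreSlice:
    z: float
    radius: float
    center: np.ndarray  # (2,) in-plane coordinates


@dataclass
class PoreProfile:
    slices: list[PoreSlice]
    params: PoreParams

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.slices])

    def to_tsv(self, labels: Sequence[str] | None = None) -> str:
        lines = ["z_A\tradius_A\tcenter_x\tcenter_y" + ("\tlabel" if labels else "")]
        for i, s in enumerate(self.slices):
            row = f"{s.z:.3f}\t{s.radius:.4f}\t{s.center[0]:.4f}\t{s.center[1]:.4f}"
            if labels:
                row += f"\t{labels[i]}"
            lines.append(row)
        return "\n".join(lines) + "\n"


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose last row is *axis* (rows: in-plane e1, e2, axis)."""
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.vstack([e1, e2, axis])


def _slice_objective(coords: np.ndarray, radii: np.ndarray, z: float, bound: float):
    """Clearance of a sphere centred at (cx, cy, z), walled at the search bound."""
    def f(c):
        p = np.array([c[0], c[1], z])
        d = np.linalg.norm(coords - p, axis=1) - radii
        val = float(d.min())
        r = max(abs(float(c[0])), abs(float(c[1])))
        if r > bound:  # keep the optimizer inside the in-plane search square
            val -= 10.0 * (r - bound)
        return val
    return f


def _grid_then_refine(f, coords: np.ndarray, radii: np.ndarray, z: float,
                      bound: float, grid_step: float) -> tuple[float, np.ndarray]:
    """Vectorized grid seeding of the clearance landscape, then simplex refinement."""
    step = min(grid_step, bound / 20.0)
    g = np.arange(-bound, bound + 1e-9, step)
    X, Y = np.meshgrid(g, g)
    centers = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
    vals = (np.linalg.norm(centers[:, None, :] - coords[None, :, :], axis=-1)
            - radii).min(axis=1)
    order = np.argsort(vals)[::-1][:5]
    best_val, best_c = -np.inf, centers[order[0], :2]
    for k in order:
        res = minimize(lambda c: -f(c), centers[k, :2], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        if -res.fun > best_val:
            best_val, best_c = -res.fun, res.x
    return best_val, best_c


def radius_at_slice(structure: Structure, z: float, params: PoreParams | None = None,
                    warm_start: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Maximal unoccluded sphere radius and centre for the slice at *z*.

    *z* and the returned centre are expressed in the axis frame (for the
    default z axis they coincide with laboratory coordinates).
    """
    params = params or PoreParams()
    radii = structure.radii
    if np.any(np.isnan(radii)):
        raise ValueError("structure has unassigned vdW radii; call assign_radii first")
    frame = _axis_frame(params.axis)
    coords = structure.coords @ frame.T

    near = np.abs(coords[:, 2] - z) < (params.search_bound + radii.max() + 5.0)
    if not np.any(near):
        raise ValueError(f"empty slice at z = {z:.2f}")
    f = _slice_objective(coords[near], radii[near], z, params.search_bound)

    if warm_start is not None:
        res = minimize(lambda c: -f(c), np.asarray(warm_start, dtype=float),
                       method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-6})
        center = res.x
        if np.linalg.norm(center - warm_start) <= params.jump_tolerance:
            return float(-res.fun), center
    val, center = _grid_then_refine(f, coords[near], radii[near], z,
                                    params.search_bound, params.grid_step)
    return float(val), center


def profile(structure: Structure, params: PoreParams | None = None) -> PoreProfile:
    """Pore radius profile over the configured z range (warm-started centre path)."""
    params = params or PoreParams()
    z_min, z_max = params.z_range
    zs = np.arange(z_min, z_max + params.slice_spacing * 0.5, params.slice_spacing)
    slices: list[PoreSlice] = []
    warm = None
    for i, z in enumerate(zs):
        try:
            r, c = radius_at_slice(structure, float(z), params, warm_start=warm)
        except ValueError as exc:
            raise ValueError(f"slice {i} (z = {z:.2f}): {exc}") from exc
        slices.append(PoreSlice(float(z), r, c))
        warm = c
    return PoreProfile(slices, params)


@dataclass
class SegmentReport:
    labels: list[str]
    min_radius: float
    min_z: float
    is_open: bool
    blocked_spans: list[tuple[float, float]]

    def to_json(self) -> str:
        return json.dumps({
            "min_radius_A": self.min_radius,
            "min_z_A": self.min_z,
            "is_open": self.is_open,
            "blocked_spans_A": self.blocked_spans,
        }, indent=2)


def classify_profile(prof: PoreProfile, tm_span: tuple[float, float]) -> SegmentReport:
    """Label slices blocked/narrow/wide and apply the chloride-passage criterion.

    ``is_open`` is true iff every slice inside *tm_span* has diameter at
    least the chloride diameter.
    """
    p = prof.params
    z = prof.z
    if tm_span[0] < z.min() - 1e-9 or tm_span[1] > z.max() + 1e-9:
        raise ValueError("tm_span outside profile range")
    labels = []
    for r in prof.radii:
        if r < p.open_radius:
            labels.append("blocked")
        elif r < p.wide_radius:
            labels.append("narrow")
        else:
            labels.append("wide")
    tm_mask = (z >= tm_span[0] - 1e-9) & (z <= tm_span[1] + 1e-9)
    tm_radii = prof.radii[tm_mask]
    min_idx = int(np.argmin(tm_radii))
    min_radius = float(tm_radii[min_idx])
    min_z = float(z[tm_mask][min_idx])
    is_open = bool(np.all(2.0 * tm_radii >= p.chloride_diameter))

    blocked_spans: list[tuple[float, float]] = []
    start = None
    for zi, lab in zip(z, labels):
        if lab == "blocked" and start is None:
            start = zi
        elif lab != "blocked" and start is not None:
            blocked_spans.append((float(start), float(prev)))
            start = None
        prev = zi
    if start is not None:
        blocked_spans.append((float(start), float(z[-1])))
    return SegmentReport(labels, min_radius, min_z, is_open, blocked_spans)
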