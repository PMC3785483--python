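"""Shrake-Rupley solvent accessibility and state-dependent exposure.

Per-atom SASA is estimated by placing a deterministic golden-spiral lattice
of test points on each atom's probe-expanded sphere and counting the points
not buried inside any neighbouring expanded sphere:

    area_i = (exposed points / total points) * 4 pi (r_i + probe)^2

Fractional per-residue accessibility divides the residue's absolute area by
a reference maximum.  For real amino acids the embedded reference table is
the theoretical Gly-X-Gly maxima of Tien et al. (2013); for coarse two-bead
fixtures an "isolated" mode computes the reference as the residue's own SASA
in isolation.  A residue is called accessible above 20% fractional SASA.

``state_compare`` reproduces the closed-vs-open exposure analysis for a
probe residue (the analysis style used for the R334C outer-mouth arginine):
fractional SASA and accessible/buried calls in both states plus the residues
with any atom within 5 A.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .structio import Structure

__all__ = [
    "SASAParams",
    "SASAResult",
    "shrake_rupley",
    "fractional_sasa",
    "mutate_to_cys",
    "state_compare",
    "neighbor_residues",
    "GXG_REFERENCE",
]

#: Theoretical Gly-X-Gly maximum accessibilities (A^2), Tien et al. 2013.
GXG_REFERENCE: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

SG_CB_BOND = 1.81  # A, thiol placement distance for in-silico Cys


def golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@dataclass
class SASAParams:
    probe_radius: float = 1.4
    points_per_atom: int = 960
    accessible_threshold: float = 20.0  # percent

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.points_per_atom < 92:
            raise ValueError("points_per_atom must be >= 92")


@dataclass
class SASAResult:
    atom_area: np.ndarray                       # A^2 per atom
    residue_area: dict[tuple, float]            # A^2 per residue
    params: SASAParams
    structure: Structure

    @property
    def total(self) -> float:
        return float(self.atom_area.sum())

    def to_tsv(self, reference: str | dict = "gxg") -> str:
        lines = ["chain\tresnum\tresname\tabs_A2\tfrac_pct\tcall"]
        for key, area in self.residue_area.items():
            try:
                frac = fractional_sasa(self, key, reference)
                call = "accessible" if frac > self.params.accessible_threshold else "buried"
                frac_s = f"{frac:.1f}"
            except KeyError:
                frac_s, call = "NA", "NA"
            lines.append(f"{key[0]}\t{key[1]}\t{self.structure.residue_name(key)}"
                         f"\t{area:.1f}\t{frac_s}\t{call}")
        return "\n".join(lines) + "\n"


def shrake_rupley(structure: Structure, params: SASAParams | None = None) -> SASAResult:
    """Per-atom and per-residue solvent-accessible surface area."""
    params = params or SASAParams()
    radii = structure.radii
    if np.any(np.isnan(radii)):
        raise ValueError("structure has unassigned vdW radii; call assign_radii first")
    coords = structure.coords
    n = len(coords)
    expanded = radii + params.probe_radius
    sphere = golden_spiral(params.points_per_atom)

    areas = np.zeros(n)
    if n:
        pair_d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        neighbors = np.where((pair_d[i] < expanded[i] + expanded) & (np.arange(n) != i))[0]
        pts = coords[i] + expanded[i] * sphere
        if len(neighbors):
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = params.points_per_atom
        areas[i] = exposed / params.points_per_atom * 4.0 * np.pi * expanded[i] ** 2

    residue_area = {
        key: float(areas[idx].sum())
        for key, idx in ((k, np.array(v)) for k, v in structure.residue_index.items())
    }
    return SASAResult(areas, residue_area, params, structure)


def _isolated_reference(structure: Structure, key: tuple, params: SASAParams) -> float:
    iso = Structure([a.copy() for a in structure.residue_atoms(key)])
    return shrake_rupley(iso, params).total


def fractional_sasa(result: SASAResult, residue: tuple,
                    reference: str | dict = "gxg") -> float:
    """Percent of a residue's reference-maximum area that is solvent accessible.

    *reference* is ``"gxg"`` (embedded Gly-X-Gly maxima), ``"isolated"`` (the
    residue's own SASA computed alone — appropriate for coarse fixtures), or
    a custom ``{resname: area}`` mapping.
    """
    if residue not in result.residue_area:
        raise KeyError(f"residue {residue} not in SASA result")
    resname = result.structure.residue_name(residue)
    if reference == "isolated":
        ref = _isolated_reference(result.structure, residue, result.params)
    else:
        table = GXG_REFERENCE if reference == "gxg" else reference
        if resname not in table:
            raise KeyError(f"residue type {resname!r} not in reference table")
        ref = table[resname]
    return 100.0 * result.residue_area[residue] / ref


def mutate_to_cys(structure: Structure, residue_key: tuple) -> Structure:
    """In-silico cysteine substitution (idempotent).

    All-atom residues are truncated to N, CA, C, O, CB with SG placed 1.81 A
    from CB along the original CB->CG direction.  Coarse two-bead residues
    (CA plus one side-chain pseudo-bead) have the pseudo-bead relabelled SG.
    """
    out = structure.copy()
    atoms = out.residue_atoms(residue_key)
    if atoms[0].residue_name == "CYS" and any(a.name == "SG" for a in atoms):
        return out
    names = {a.name: a for a in atoms}
    idx = out.residue_index[residue_key]

    if "CB" in names:
        keep = {"N", "CA", "C", "O", "CB"}
        cb = names["CB"]
        if "CG" in names:
            direction = names["CG"].coords - cb.coords
        else:
            ca = names.get("CA")
            if ca is None:
                raise ValueError(f"residue {residue_key} lacks CA for SG placement")
            direction = cb.coords - ca.coords
        direction = direction / np.linalg.norm(direction)
        sg = cb.copy()
        sg.name = "SG"
        sg.element = "S"
        sg.coords = cb.coords + SG_CB_BOND * direction
        sg.vdw_radius = math.nan if math.isnan(cb.vdw_radius) else 1.80
        new_atoms = [a for a in atoms if a.name in keep] + [sg]
    else:
        pseudo = [a for a in atoms if a.name != "CA"]
        if not pseudo:
            raise ValueError(f"residue {residue_key} has no CB and no side-chain pseudo-bead")
        new_atoms = []
        for a in atoms:
            b = a.copy()
            if a.name != "CA":
                b.name = "SG"
                b.element = "S"
                if not math.isnan(b.vdw_radius):
                    b.vdw_radius = 1.80
            new_atoms.append(b)

    for a in new_atoms:
        a.residue_name = "CYS"
    rebuilt = []
    consumed = False
    for i, a in enumerate(out.atoms):
        if i in idx:
            if not consumed:
                rebuilt.extend(new_atoms)
                consumed = True
        else:
            rebuilt.append(a)
    return Structure(rebuilt)


def neighbor_residues(structure: Structure, residue_key: tuple,
                      cutoff: float = 5.0) -> list[tuple]:
    """Residues with any atom within *cutoff* of any atom of the query residue."""
    query = np.array([a.coords for a in structure.residue_atoms(residue_key)])
    out = []
    for key, idx in structure.residue_index.items():
        if key == residue_key:
            continue
        pts = np.array([structure.atoms[i].coords for i in idx])
        d = np.linalg.norm(query[:, None, :] - pts[None, :, :], axis=-1)
        if d.min() <= cutoff:
            out.append(key)
    return out


@dataclass
class StateCompareReport:
    residue: tuple
    frac_closed: float
    frac_open: float
    call_closed: str
    call_open: str
    neighbors_closed: list[tuple]
    neighbors_open: list[tuple]

    def to_json(self) -> str:
        return json.dumps({
            "residue": list(self.residue),
            "fractional_sasa_pct": {"closed": self.frac_closed, "open": self.frac_open},
            "call": {"closed": self.call_closed, "open": self.call_open},
            "neighbors_within_5A": {
                "closed": [list(k) for k in self.neighbors_closed],
                "open": [list(k) for k in self.neighbors_open],
            },
        }, indent=2)


def state_compare(struct_closed: Structure, struct_open: Structure, residue_key: tuple,
                  params: SASAParams | None = None,
                  reference: str | dict = "isolated",
                  neighbor_cutoff: float = 5.0) -> StateCompareReport:
    """Two-state exposure comparison for one residue."""
    params = params or SASAParams()
    for s, name in ((struct_closed, "closed"), (struct_open, "open")):
        if residue_key not in s.residue_index:
            raise KeyError(f"residue {residue_key} absent from {name} structure")
    fr = {}
    for label, s in (("closed", struct_closed), ("open", struct_open)):
        res = shrake_rupley(s, params)
        fr[label] = fractional_sasa(res, residue_key, reference)
    call = {k: ("accessible" if v > params.accessible_threshold else "buried")
            for k, v in fr.items()}
    return StateCompareReport(
        residue_key, fr["closed"], fr["open"], call["closed"], call["open"],
        neighbor_residues(struct_closed, residue_key, neighbor_cutoff),
        neighbor_residues(struct_open, residue_key, neighbor_cutoff),
    )
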