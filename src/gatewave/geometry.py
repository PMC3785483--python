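"""Rigid-body superposition and side-chain distance conventions.

The best-fit RMSD between two conformations is the root-mean-square
coordinate deviation minimized over all proper rigid motions (rotation +
translation, reflections excluded).  The minimizing rotation is obtained in
closed form from the SVD of the cross-covariance matrix (Kabsch); when the
determinant of the candidate rotation would be -1 the sign of the smallest
singular vector is flipped so chirality is preserved.

Residue-pair distances come in two conventions:

``functional_atoms``
    the charged/polar tip atoms that actually carry the interaction
    (guanidinium N of Arg, carboxyl O of Asp/Glu, hydroxyl O of Ser/Thr/Tyr,
    amine N of Lys, thiol S of Cys) — used for distance traces.
``all_sidechain_heavy``
    every non-backbone heavy atom — used for the broad contact scan, where
    "separation between side chains" is the operative phrase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import BACKBONE_NAMES, Structure

__all__ = [
    "RigidTransform",
    "DistanceConvention",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "bestfit_rmsd",
    "pair_min_distance",
    "FUNCTIONAL_ATOMS",
]

#: Interaction-carrying side-chain heavy atoms per residue type.
FUNCTIONAL_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}


class DegenerateGeometryError(ValueError):
    """Superposition subset is collinear or coincident."""


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class DistanceConvention:
    """How to resolve the atoms that represent a residue's side chain."""

    mode: str = "functional_atoms"
    functional_map: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(FUNCTIONAL_ATOMS))

    def __post_init__(self) -> None:
        if self.mode not in ("functional_atoms", "all_sidechain_heavy"):
            raise ValueError(f"unknown distance convention mode {self.mode!r}")

    def resolve(self, structure: Structure, key: tuple[str, int, str]) -> np.ndarray:
        """Return the (m, 3) coordinates representing the residue's side chain."""
        atoms = structure.residue_atoms(key)
        resname = atoms[0].residue_name
        if self.mode == "functional_atoms":
            wanted = self.functional_map.get(resname, ())
            picked = [a.coords for a in atoms if a.name in wanted]
        else:
            picked = [a.coords for a in atoms
                      if a.name not in BACKBONE_NAMES and not a.element.upper().startswith("H")]
        if not picked:
            raise ValueError(
                f"residue {resname} {key} has no atoms under convention {self.mode!r}")
        return np.array(picked)


def _prepare(mobile: np.ndarray, reference: np.ndarray,
             subset: Sequence[int] | None) -> tuple[np.ndarray, np.ndarray]:
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be congruent (N, 3) arrays")
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        if len(idx) < 3:
            raise DegenerateGeometryError("superposition subset must have >= 3 atoms")
        mobile, reference = mobile[idx], reference[idx]
    elif len(mobile) < 3:
        raise DegenerateGeometryError("superposition needs >= 3 atoms")
    return mobile, reference


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     subset: Sequence[int] | None = None) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of *mobile* onto *reference*.

    Returns the transform achieving the minimum RMSD over the subset and that
    RMSD in Angstrom.  Collinear or coincident subsets raise
    :class:`DegenerateGeometryError`.
    """
    X, Y = _prepare(mobile, reference, subset)
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    scale = max(np.abs(X0).max(), np.abs(Y0).max(), 1e-12)
    sv_x = np.linalg.svd(X0, compute_uv=False)
    if len(sv_x) < 2 or sv_x[1] < 1e-8 * scale * np.sqrt(len(X)):
        raise DegenerateGeometryError("superposition subset is collinear or coincident")
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    transform = RigidTransform(R, t)
    diff = transform.apply(X) - Y
    rmsd = float(np.sqrt((diff ** 2).sum() / len(X)))
    return transform, rmsd


def bestfit_rmsd(frame: np.ndarray, target: np.ndarray,
                 subset: Sequence[int] | None = None) -> float:
    """Minimum RMSD between two conformations over all proper rigid motions."""
    return kabsch_superpose(frame, target, subset)[1]


def pair_min_distance(structure: Structure, residue_a: tuple[str, int, str],
                      residue_b: tuple[str, int, str],
                      convention: DistanceConvention | None = None) -> float:
    """Minimum side-chain distance (A) between two residues under a convention."""
    convention = convention or DistanceConvention()
    A = convention.resolve(structure, residue_a)
    B = convention.resolve(structure, residue_b)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    return float(d.min())
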