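"""One-sided (semi-harmonic) distance restraints and model ranking.

A restraint is flat on its satisfied side and harmonic on the violated side:
a ``maximum_distance`` restraint with bound d0 contributes
``(k_r/2) (d - d0)^2`` only when d > d0, and a ``minimum_distance`` restraint
only when d < d0.  Restraints between residues measure the pair's minimum
functional-atom distance (the anchored interactions are salt bridges).

Candidate models are ranked the way the ten homology models were selected:
most satisfied restraints first, then most pore-lining residues meeting the
accessibility threshold, then lowest total penalty; ties preserve input
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .accessibility import SASAParams, fractional_sasa, shrake_rupley
from .geometry import DistanceConvention, pair_min_distance
from .structio import Structure

__all__ = [
    "DistanceRestraint",
    "RestraintResult",
    "RankingSpec",
    "evaluate",
    "rank_models",
    "read_restraints_tsv",
]


@dataclass
class DistanceRestraint:
    residue_a: tuple
    residue_b: tuple
    d0: float
    kind: str = "maximum_distance"  # or minimum_distance
    k_r: float = 1.0
    convention: DistanceConvention = field(default_factory=DistanceConvention)

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.k_r < 0:
            raise ValueError("k_r must be >= 0")
        if self.kind not in ("maximum_distance", "minimum_distance"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")


@dataclass
class RestraintResult:
    restraint: DistanceRestraint
    distance: float
    violated: bool
    penalty: float


def evaluate(structure: Structure,
             restraints: list[DistanceRestraint]) -> tuple[list[RestraintResult], dict]:
    """Evaluate each restraint; returns per-restraint results and totals."""
    results = []
    for r in restraints:
        try:
            d = pair_min_distance(structure, r.residue_a, r.residue_b, r.convention)
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"restraint {r.residue_a}-{r.residue_b}: unresolvable selector ({exc})"
            ) from exc
        violated = d > r.d0 if r.kind == "maximum_distance" else d < r.d0
        penalty = 0.5 * r.k_r * (d - r.d0) ** 2 if violated else 0.0
        results.append(RestraintResult(r, d, violated, penalty))
    totals = {
        "n_satisfied": sum(not x.violated for x in results),
        "n_violated": sum(x.violated for x in results),
        "total_penalty": sum(x.penalty for x in results),
    }
    return results, totals


@dataclass
class RankingSpec:
    restraints: list[DistanceRestraint]
    pore_lining: list[tuple]                      # residues expected accessible
    accessibility_threshold: float = 20.0         # percent
    sasa_params: SASAParams = field(default_factory=SASAParams)
    sasa_reference: str | dict = "isolated"

    def __post_init__(self) -> None:
        if not self.restraints or not self.pore_lining:
            raise ValueError("restraint and pore-lining lists must be non-empty")


@dataclass
class RankedModel:
    index: int
    n_satisfied: int
    n_accessible: int
    total_penalty: float
    structure: Structure

    def to_dict(self) -> dict:
        return {"index": self.index, "n_satisfied": self.n_satisfied,
                "n_accessible": self.n_accessible, "total_penalty": self.total_penalty}


def rank_models(structures: list[Structure], spec: RankingSpec) -> list[RankedModel]:
    """Rank candidate models by restraint satisfaction then pore accessibility."""
    if not structures:
        raise ValueError("need at least one structure")
    ranked = []
    for idx, s in enumerate(structures):
        _, totals = evaluate(s, spec.restraints)
        sasa = shrake_rupley(s, spec.sasa_params)
        n_acc = 0
        for key in spec.pore_lining:
            frac = fractional_sasa(sasa, key, spec.sasa_reference)
            if frac > spec.accessibility_threshold:
                n_acc += 1
        ranked.append(RankedModel(idx, totals["n_satisfied"], n_acc,
                                  totals["total_penalty"], s))
    ranked.sort(key=lambda r: (-r.n_satisfied, -r.n_accessible, r.total_penalty, r.index))
    return ranked


def read_restraints_tsv(path: str | Path) -> list[DistanceRestraint]:
    """Read a restraint list: chain_a res_a chain_b res_b kind d0 [k].

    Lines starting with '#' are comments.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        ca, ra, cb, rb, kind, d0 = parts[:6]
        k = float(parts[6]) if len(parts) > 6 else 1.0
        out.append(DistanceRestraint((ca, int(ra), ""), (cb, int(rb), ""),
                                     float(d0), kind, k))
    return out


def ranking_json(ranked: list[RankedModel]) -> str:
    return json.dumps([r.to_dict() for r in ranked], indent=2)
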