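"""Multi-channel profile alignment for low-homology membrane proteins.

When sequence identity between two membrane proteins is too low for a
reliable substitution-matrix alignment (as between ABC-transporter
membrane-spanning domains, < 20% identity), per-residue descriptors carry
the signal instead.  Each position holds up to five channels:

* amino acid (scored with BLOSUM62, scaled by 1/4 into an O(1) range),
* windowed Kyte-Doolittle hydropathy (normalized difference; the scale spans
  -4.5..+4.5, so |dh| / 9 maps into [0, 1]),
* secondary-structure state {H, E, C} (match indicator),
* membrane topology {M, I, O} (match indicator),
* accessibility in [0, 100] — for a query this is a binary pore-accessible
  (100) / buried (0) assignment, for a template a percent solvent-accessible
  surface area, so aligning them matches pore-facing residues to exposed
  template sites.

The column scores are combined with non-negative weights and optimized
globally under affine gaps (Gotoh three-state recursion), with optional
anchored residue pairs that force particular correspondences (the mechanised
form of manual topology adjustments).  Tie-breaking is deterministic:
match preferred over a gap in A over a gap in B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

try:
    from Bio.Align import substitution_matrices
    _BLOSUM62 = substitution_matrices.load("BLOSUM62")
except Exception:  # pragma: no cover
    _BLOSUM62 = None

__all__ = [
    "KYTE_DOOLITTLE",
    "ProfileSet",
    "AlignWeights",
    "Alignment",
    "windowed_hydropathy",
    "column_similarity",
    "global_align",
    "blosum62",
]

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

HYDROPATHY_RANGE = 9.0  # Kyte-Doolittle span, for |dh| normalization


def blosum62(a: str, b: str) -> float:
    if _BLOSUM62 is None:  # pragma: no cover
        raise RuntimeError("Biopython substitution matrices unavailable")
    try:
        return float(_BLOSUM62[a, b])
    except KeyError:
        return float(_BLOSUM62["X", "X"])


def windowed_hydropathy(sequence: str, window: int = 13) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    The window is odd and shrinks symmetrically at the termini.  Residues
    absent from the scale contribute 0 (with a warning).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    vals = np.empty(len(sequence))
    for i, aa in enumerate(sequence):
        if aa not in KYTE_DOOLITTLE:
            import warnings
            warnings.warn(f"non-standard residue {aa!r}; hydropathy treated as 0")
        vals[i] = KYTE_DOOLITTLE.get(aa, 0.0)
    n = len(sequence)
    out = np.empty(n)
    half = window // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = vals[i - h:i + h + 1].mean()
    return out


@dataclass
class ProfileSet:
    """Per-residue multi-channel descriptors; channels may be None (absent)."""

    sequence: str
    hydropathy: np.ndarray | None = None
    ss_state: str | None = None
    topology: str | None = None
    accessibility: np.ndarray | None = None  # [0, 100], NaN = missing

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if self.hydropathy is not None:
            self.hydropathy = np.asarray(self.hydropathy, dtype=float)
            if len(self.hydropathy) != n:
                raise ValueError("hydropathy length mismatch")
        if self.ss_state is not None:
            if len(self.ss_state) != n or set(self.ss_state) - set("HEC"):
                raise ValueError("ss_state must be an {H,E,C} string of sequence length")
        if self.topology is not None:
            if len(self.topology) != n or set(self.topology) - set("MIO"):
                raise ValueError("topology must be an {M,I,O} string of sequence length")
        if self.accessibility is not None:
            self.accessibility = np.asarray(self.accessibility, dtype=float)
            if len(self.accessibility) != n:
                raise ValueError("accessibility length mismatch")
            ok = np.isnan(self.accessibility) | (
                (self.accessibility >= 0) & (self.accessibility <= 100))
            if not np.all(ok):
                raise ValueError("accessibility values must lie in [0, 100] or be NaN")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, sequence: str, window: int = 13, **channels) -> "ProfileSet":
        """Build a profile with hydropathy computed from the sequence."""
        return cls(sequence, hydropathy=windowed_hydropathy(sequence, window), **channels)


@dataclass
class AlignWeights:
    w_sub: float = 1.0
    w_hyd: float = 1.0
    w_ss: float = 1.0
    w_top: float = 1.0
    w_acc: float = 1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    membrane_gap_multiplier: float = 1.0  # >1 penalizes opening gaps inside TM spans

    def __post_init__(self) -> None:
        ws = (self.w_sub, self.w_hyd, self.w_ss, self.w_top, self.w_acc)
        if any(w < 0 for w in ws):
            raise ValueError("channel weights must be non-negative")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one channel weight must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


def column_similarity(a: ProfileSet, i: int, b: ProfileSet, j: int,
                      weights: AlignWeights) -> float:
    """Weighted similarity of column *i* of A and column *j* of B.

    Channels missing on either side contribute nothing.
    """
    s = 0.0
    if weights.w_sub > 0:
        s += weights.w_sub * blosum62(a.sequence[i], b.sequence[j]) / 4.0
    if weights.w_hyd > 0 and a.hydropathy is not None and b.hydropathy is not None:
        s += weights.w_hyd * (1.0 - abs(a.hydropathy[i] - b.hydropathy[j]) / HYDROPATHY_RANGE)
    if weights.w_ss > 0 and a.ss_state is not None and b.ss_state is not None:
        s += weights.w_ss * (1.0 if a.ss_state[i] == b.ss_state[j] else 0.0)
    if weights.w_top > 0 and a.topology is not None and b.topology is not None:
        s += weights.w_top * (1.0 if a.topology[i] == b.topology[j] else 0.0)
    if weights.w_acc > 0 and a.accessibility is not None and b.accessibility is not None:
        ai, bj = a.accessibility[i], b.accessibility[j]
        if not (np.isnan(ai) or np.isnan(bj)):
            s += weights.w_acc * (1.0 - abs(ai - bj) / 100.0)
    return s


@dataclass
class Alignment:
    """Global alignment as a list of (i, j) columns; gaps are None entries."""

    columns: list[tuple[int | None, int | None]]
    score: float
    column_scores: list[float] = field(default_factory=list)

    def matched_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j in self.columns if i is not None and j is not None}

    def to_fasta(self, a: ProfileSet, b: ProfileSet,
                 names: tuple[str, str] = ("A", "B")) -> str:
        ra = "".join("-" if i is None else a.sequence[i] for i, _ in self.columns)
        rb = "".join("-" if j is None else b.sequence[j] for _, j in self.columns)
        return f">{names[0]}\n{ra}\n>{names[1]}\n{rb}\n"


def _similarity_matrix(a: ProfileSet, b: ProfileSet, weights: AlignWeights) -> np.ndarray:
    S = np.empty((len(a), len(b)))
    for i in range(len(a)):
        for j in range(len(b)):
            S[i, j] = column_similarity(a, i, b, j, weights)
    return S


def _gotoh(S: np.ndarray, weights: AlignWeights,
           topo_a: str | None, topo_b: str | None) -> tuple[float, list]:
    """Three-state affine-gap global DP.

    A gap of length L costs open + (L-1) * extend.  Tie-breaking prefers
    match, then gap in A (consuming B), then gap in B.
    """
    n, m = S.shape
    NEG = -1e18
    go, ge = weights.gap_open, weights.gap_extend

    def open_cost(i, j):
        # higher opening cost inside membrane spans, if configured
        mult = weights.membrane_gap_multiplier
        if mult != 1.0 and topo_a and topo_b:
            ii = min(max(i, 0), n - 1)
            jj = min(max(j, 0), m - 1)
            if topo_a[ii] == "M" and topo_b[jj] == "M":
                return go * mult
        return go

    M = np.full((n + 1, m + 1), NEG)   # last column matched i with j
    X = np.full((n + 1, m + 1), NEG)   # gap in A (B residue j aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)   # gap in B
    M[0, 0] = 0.0
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    # pointer codes: 0 = from M, 1 = from X, 2 = from Y

    for j in range(1, m + 1):
        oc = open_cost(0, j - 1)
        cand = (M[0, j - 1] - oc, X[0, j - 1] - ge, Y[0, j - 1] - oc)
        X[0, j] = max(cand)
        ptr_x[0, j] = int(np.argmax(cand))
    for i in range(1, n + 1):
        oc = open_cost(i - 1, 0)
        cand = (M[i - 1, 0] - oc, X[i - 1, 0] - oc, Y[i - 1, 0] - ge)
        Y[i, 0] = max(cand)
        ptr_y[i, 0] = int(np.argmax(cand))

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            best = int(np.argmax(cand))
            M[i, j] = cand[best] + S[i - 1, j - 1]
            ptr_m[i, j] = best
            oc = open_cost(i - 1, j - 1)
            cand = (M[i, j - 1] - oc, X[i, j - 1] - ge, Y[i, j - 1] - oc)
            best = int(np.argmax(cand))
            X[i, j] = cand[best]
            ptr_x[i, j] = best
            cand = (M[i - 1, j] - oc, X[i - 1, j] - oc, Y[i - 1, j] - ge)
            best = int(np.argmax(cand))
            Y[i, j] = cand[best]
            ptr_y[i, j] = best

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    score = float(finals[state])

    columns: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            columns.append((i - 1, j - 1))
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            columns.append((None, j - 1))
            state = int(ptr_x[i, j])
            j -= 1
        else:
            columns.append((i - 1, None))
            state = int(ptr_y[i, j])
            i -= 1
    columns.reverse()
    return score, columns


def global_align(a: ProfileSet, b: ProfileSet, weights: AlignWeights | None = None,
                 anchors: Sequence[tuple[int, int]] | None = None) -> Alignment:
    """Optimal global affine-gap alignment of two profile sets.

    *anchors* are (i, j) pairs forced into the alignment; they must be
    strictly increasing in both indices.  The DP is split at each anchor.
    """
    weights = weights or AlignWeights()
    if anchors:
        anchors = sorted(anchors)
        for (i1, j1), (i2, j2) in zip(anchors, anchors[1:]):
            if not (i1 < i2 and j1 < j2):
                raise ValueError(f"conflicting anchors ({i1},{j1}) and ({i2},{j2})")
        for i, j in anchors:
            if not (0 <= i < len(a) and 0 <= j < len(b)):
                raise ValueError(f"anchor ({i},{j}) out of range")

    S = _similarity_matrix(a, b, weights)

    def sub(ai, aj, bi, bj):
        """Align the half-open segment a[ai:aj] x b[bi:bj]."""
        block = S[ai:aj, bi:bj]
        score, cols = _gotoh(block, weights,
                             a.topology[ai:aj] if a.topology else None,
                             b.topology[bi:bj] if b.topology else None)
        shifted = [(None if i is None else i + ai, None if j is None else j + bi)
                   for i, j in cols]
        return score, shifted

    if not anchors:
        score, columns = _gotoh(S, weights, a.topology, b.topology)
    else:
        score = 0.0
        columns = []
        prev_i, prev_j = 0, 0
        for ai, bj in anchors:
            s, cols = sub(prev_i, ai, prev_j, bj)
            score += s
            columns.extend(cols)
            columns.append((ai, bj))
            score += S[ai, bj]
            prev_i, prev_j = ai + 1, bj + 1
        s, cols = sub(prev_i, len(a), prev_j, len(b))
        score += s
        columns.extend(cols)

    col_scores = [S[i, j] if i is not None and j is not None else 0.0
                  for i, j in columns]
    return Alignment(columns, score, col_scores)
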