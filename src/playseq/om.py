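"""Optimal-matching (OM) distances between state sequences.

OM distance is the minimal total cost of transforming one sequence into
another using insertions and deletions at a constant cost (here 1, the
conventional choice for equal-length sequences sampled on a common grid)
and substitutions priced by a symmetric state-pair cost matrix.  Following
standard practice when no theoretically motivated costs exist, the
substitution cost between states *i* and *j* is derived from the pooled
observed lag-1 transition rates::

    SC[i, j] = 2 - p(j | i) - p(i | j)        (i != j)

so states that frequently follow one another are cheap to interchange.
Costs lie in [0, 2] and the matrix is symmetric with zero diagonal.

The dynamic programme is vectorised: the insertion scan within a row is a
min-plus prefix scan, which for a constant indel cost reduces to a running
minimum of ``D[i, j] - j * indel``.  ``pairwise_distances`` additionally
batches the recursion across all sequence pairs, which keeps the full
60-animal distance matrix under a few seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqcore import (
    DEFAULT_ALPHABET,
    Alphabet,
    SequenceInputError,
    StateSequence,
    TransitionMatrix,
)

__all__ = [
    "SubstitutionCostMatrix",
    "DistanceMatrix",
    "substitution_costs_from_rates",
    "om_distance",
    "pairwise_distances",
]


@dataclass
class SubstitutionCostMatrix:
    """Symmetric non-negative substitution costs over an alphabet."""

    alphabet: Alphabet
    SC: np.ndarray

    def __post_init__(self) -> None:
        self.SC = np.asarray(self.SC, dtype=float)
        a = self.alphabet.size
        if self.SC.shape != (a, a):
            raise ValueError("cost matrix shape does not match alphabet")
        if not np.allclose(self.SC, self.SC.T):
            raise ValueError("substitution costs must be symmetric")
        if (self.SC < 0).any():
            raise ValueError("substitution costs must be non-negative")
        if not np.allclose(np.diag(self.SC), 0.0):
            raise ValueError("diagonal substitution costs must be zero")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.D < 0).any():
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.D[iu]


def substitution_costs_from_rates(tm: TransitionMatrix) -> SubstitutionCostMatrix:
    """Derive substitution costs ``2 - p(j|i) - p(i|j)`` from transition rates.

    Undefined rows (from-states never observed) contribute a rate of 0, so
    the affected costs fall back to the available direction; a warning is
    emitted because such costs are only partially informed by the data.
    """
    if not tm.defined_rows.all():
        missing = [
            tm.alphabet.states[i]
            for i in np.flatnonzero(~tm.defined_rows)
        ]
        warnings.warn(
            f"transition rows undefined for states {missing}; "
            "their substitution costs use the remaining rates only",
            stacklevel=2,
        )
    P = tm.P
    SC = 2.0 - P - P.T
    np.fill_diagonal(SC, 0.0)
    SC = np.clip(SC, 0.0, 2.0)
    SC = (SC + SC.T) / 2.0  # guard symmetry against float noise
    return SubstitutionCostMatrix(alphabet=tm.alphabet, SC=SC)


def _codes(seq: StateSequence, alphabet: Alphabet) -> np.ndarray:
    if seq.alphabet != alphabet:
        raise SequenceInputError("sequence alphabet does not match cost matrix")
    return seq.observed_codes()


def om_distance(
    s1: StateSequence,
    s2: StateSequence,
    sc: SubstitutionCostMatrix,
    indel: float = 1.0,
) -> float:
    """Minimal edit cost between two sequences (missing intervals dropped).

    Classic Needleman–Wunsch-style dynamic programme over the
    ``(|s1|+1) x (|s2|+1)`` grid; rows are vectorised and the
    constant-indel insertion scan is folded into a running minimum.
    """
    a = _codes(s1, sc.alphabet)
    b = _codes(s2, sc.alphabet)
    m = b.size
    j_off = indel * np.arange(m + 1)
    prev = j_off.copy()  # D[0, :]
    sub = sc.SC[:, b]  # substitution cost rows, indexed by s1 code
    cur = np.empty(m + 1)
    for i in range(1, a.size + 1):
        cur[0] = i * indel
        # candidate without insertions: diagonal substitution vs deletion
        cand = np.minimum(prev[:-1] + sub[a[i - 1]], prev[1:] + indel)
        cur[1:] = cand
        # insertion scan: D[i, j] = min_k<=j (cand'[k] + (j-k) * indel)
        np.minimum.accumulate(cur - j_off, out=cur)
        cur += j_off
        prev, cur = cur, prev
    return float(prev[m])


def pairwise_distances(
    dataset: Sequence[StateSequence],
    sc: SubstitutionCostMatrix,
    indel: float = 1.0,
) -> DistanceMatrix:
    """All pairwise OM distances, batched across pairs.

    Every pair is advanced through the DP recursion simultaneously.  The
    grid has no right-to-left or bottom-up dependencies, so sequences of
    unequal observed length (after dropping missing intervals) are padded
    to a common shape and each pair's distance is read off at its own
    ``(len_i, len_j)`` cell.
    """
    n = len(dataset)
    if n < 2:
        raise SequenceInputError("need at least two sequences")
    codes = [_codes(s, sc.alphabet) for s in dataset]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A, la = _pad([codes[i] for i, _ in pairs])
    B, lb = _pad([codes[j] for _, j in pairs])
    vals = _batched_om(A, la, B, lb, sc.SC, indel)
    D = np.zeros((n, n), dtype=float)
    for (i, j), v in zip(pairs, vals):
        D[i, j] = D[j, i] = v
    return DistanceMatrix(ids=[s.animal_id for s in dataset], D=D)


def _pad(code_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([c.size for c in code_list], dtype=np.int64)
    out = np.zeros((len(code_list), int(lens.max(initial=1))), dtype=np.int64)
    for r, c in enumerate(code_list):
        out[r, : c.size] = c
    return out, lens


def _batched_om(
    A: np.ndarray,
    la: np.ndarray,
    B: np.ndarray,
    lb: np.ndarray,
    SC: np.ndarray,
    indel: float,
) -> np.ndarray:
    nb = A.shape[0]
    max_a, max_b = A.shape[1], B.shape[1]
    rows = np.arange(nb)
    j_off = indel * np.arange(max_b + 1)
    prev = np.broadcast_to(j_off, (nb, max_b + 1)).copy()
    cur = np.empty_like(prev)
    out = np.empty(nb)
    done0 = la == 0
    out[done0] = lb[done0] * indel  # empty first sequence: pure insertions
    for i in range(1, max_a + 1):
        cur[:, 0] = i * indel
        sub_row = SC[A[:, i - 1][:, None], B]  # (B, max_b) costs for row i
        cand = np.minimum(prev[:, :-1] + sub_row, prev[:, 1:] + indel)
        cur[:, 1:] = cand
        np.minimum.accumulate(cur - j_off, axis=1, out=cur)
        cur += j_off
        hit = la == i
        if hit.any():
            out[hit] = cur[rows[hit], lb[hit]]
        prev, cur = cur, prev
    return out
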