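"""Player typing: initiator/joiner and solitary/social classification.

Each animal's object-play onsets are either *initiations* (first to touch
a free toy) or *joins* (starting on a toy a penmate already plays with),
and each object-play interval is spent either *alone* or *together*.  An
animal is typed on each axis by a one-sample proportion test against 0.5:
if the two-sided 90% confidence interval for its initiation share lies
entirely above 0.5 it is an initiator, entirely below a joiner, otherwise
a mixed type — and analogously solitary/social/mixed from the share of
object-play intervals spent alone.

The association between the two classifications is summarised by a 3x3
cross table with Kendall's tau-b (and its asymptotic standard error under
the alternative, the Goodman–Kruskal variance form) and an exact or
Monte-Carlo Fisher test for general r x c tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.special import gammaln

from statsmodels.stats.proportion import proportion_confint

from .seqcore import IntervalRecord

__all__ = [
    "PlayerTyping",
    "CrossTable",
    "IJ_ORDER",
    "SS_ORDER",
    "tally_events",
    "classify_proportion",
    "classify_players",
    "crosstab",
    "kendall_tau_b",
    "fisher_exact_rxc",
]

#: Fixed ordinal codings used throughout (rows then columns of the table).
IJ_ORDER = ("initiator", "mixed", "joiner")
SS_ORDER = ("solitary", "mixed", "social")


@dataclass
class PlayerTyping:
    """Object-play event tallies and the two classifications for one animal."""

    animal_id: str
    n_initiate: int = 0
    n_join: int = 0
    n_alone: int = 0
    n_together: int = 0
    ij_class: Optional[str] = None
    ss_class: Optional[str] = None
    no_onset_events: bool = False
    no_company_intervals: bool = False


@dataclass
class CrossTable:
    """3x3 contingency table of (initiator/mixed/joiner) x
    (solitary/mixed/social) counts."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = IJ_ORDER
    col_labels: tuple[str, ...] = SS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("table shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def tally_events(records: Iterable[IntervalRecord]) -> PlayerTyping:
    """Count onset kinds and company labels over one animal's records."""
    records = list(records)
    animal_id = records[0].animal_id if records else ""
    t = PlayerTyping(animal_id=animal_id)
    for r in records:
        if r.animal_id != animal_id:
            raise ValueError("records from more than one animal")
        if r.objp_onset_kind == "initiate":
            t.n_initiate += 1
        elif r.objp_onset_kind == "join":
            t.n_join += 1
        if r.objp_company == "alone":
            t.n_alone += 1
        elif r.objp_company == "together":
            t.n_together += 1
    return t


def classify_proportion(
    x: int, n: int, level: float = 0.90, method: str = "beta"
) -> str:
    """Classify a proportion x/n against 0.5 via a two-sided CI.

    Returns ``"high"`` when the CI lies entirely above 0.5, ``"low"`` when
    entirely below, else ``"mixed"`` (including n = 0, which callers flag
    separately as a no-events case).  ``method`` is passed to
    :func:`statsmodels.stats.proportion.proportion_confint`: ``"beta"``
    (exact Clopper–Pearson, the default), ``"wilson"`` or ``"normal"``.
    """
    if n < 0 or x < 0 or x > n:
        raise ValueError("need 0 <= x <= n")
    if n == 0:
        return "mixed"
    lo, hi = proportion_confint(x, n, alpha=1.0 - level, method=method)
    if lo > 0.5:
        return "high"
    if hi < 0.5:
        return "low"
    return "mixed"


def classify_players(
    typings: Iterable[PlayerTyping], level: float = 0.90, method: str = "beta"
) -> list[PlayerTyping]:
    """Fill in both classifications on each animal's tallies (in place).

    The initiator/joiner axis uses onset events (initiations out of all
    onsets); the solitary/social axis uses object-play interval counts
    (alone out of all object-play intervals).
    """
    out = []
    for t in typings:
        n_ij = t.n_initiate + t.n_join
        cls = classify_proportion(t.n_initiate, n_ij, level, method)
        t.ij_class = {"high": "initiator", "low": "joiner", "mixed": "mixed"}[cls]
        t.no_onset_events = n_ij == 0
        n_ss = t.n_alone + t.n_together
        cls = classify_proportion(t.n_alone, n_ss, level, method)
        t.ss_class = {"high": "solitary", "low": "social", "mixed": "mixed"}[cls]
        t.no_company_intervals = n_ss == 0
        out.append(t)
    return out


def crosstab(typings: Iterable[PlayerTyping]) -> CrossTable:
    counts = np.zeros((3, 3), dtype=np.int64)
    for t in typings:
        if t.ij_class is None or t.ss_class is None:
            raise ValueError(f"animal {t.animal_id} not classified yet")
        counts[IJ_ORDER.index(t.ij_class), SS_ORDER.index(t.ss_class)] += 1
    return CrossTable(counts=counts)


def kendall_tau_b(table: CrossTable | np.ndarray) -> tuple[float, float]:
    """Kendall's tau-b and its asymptotic SE for an ordered r x c table.

    tau-b = (P − Q)/sqrt(w_r w_c) with P/Q the numbers of concordant and
    discordant ordered pairs and w_r, w_c the tie corrections from the row
    and column marginals.  The standard error is the asymptotic form under
    the alternative hypothesis (Goodman–Kruskal variance), suitable for
    confidence intervals.
    """
    T = table.counts if isinstance(table, CrossTable) else np.asarray(table, float)
    T = np.asarray(T, dtype=float)
    n = T.sum()
    if n < 2:
        raise ValueError("need at least two classified animals")
    nr = T.sum(axis=1)
    nc = T.sum(axis=0)
    R, C = T.shape
    A = np.zeros_like(T)
    Dm = np.zeros_like(T)
    for i in range(R):
        for j in range(C):
            A[i, j] = T[:i, :j].sum() + T[i + 1:, j + 1:].sum()
            Dm[i, j] = T[:i, j + 1:].sum() + T[i + 1:, :j].sum()
    P = float((T * A).sum())
    Q = float((T * Dm).sum())
    w_r = n ** 2 - float((nr ** 2).sum())
    w_c = n ** 2 - float((nc ** 2).sum())
    if w_r <= 0 or w_c <= 0:
        raise ValueError("tau-b undefined: a margin is entirely tied")
    w = math.sqrt(w_r * w_c)
    tau = (P - Q) / w
    d = A - Dm
    v = nr[:, None] * w_c + nc[None, :] * w_r
    s = float((T * (2 * w * d + tau * v) ** 2).sum()) - n ** 3 * tau ** 2 * (
        w_r + w_c
    ) ** 2
    ase = math.sqrt(max(s, 0.0)) / w ** 2
    return tau, ase


def _log_table_prob(T: np.ndarray, log_fact_margins: float, log_fact_n: float) -> float:
    # P(T | margins) = prod(r_i!) prod(c_j!) / (n! prod(t_ij!))
    return log_fact_margins - log_fact_n - float(gammaln(T + 1).sum())


def _enumerate_tables(row_margins, col_margins):
    """Yield every non-negative integer table with the given margins."""
    R = len(row_margins)

    def rec(rows_left, cols_left):
        if rows_left == 1:
            yield (tuple(cols_left),)
            return
        r = row_margins[len(row_margins) - rows_left]
        for combo in _row_fills(r, cols_left):
            rest = [c - v for c, v in zip(cols_left, combo)]
            for tail in rec(rows_left - 1, rest):
                yield (combo,) + tail

    yield from rec(R, list(col_margins))


def _row_fills(total, caps):
    """All ways to write `total` as a sum over cells bounded by `caps`."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for v in range(min(total, caps[0]) + 1):
        for tail in _row_fills(total - v, caps[1:]):
            yield (v,) + tail


def _count_tables(row_margins, col_margins, limit):
    count = 0
    for _ in _enumerate_tables(row_margins, col_margins):
        count += 1
        if count > limit:
            return count
    return count


def fisher_exact_rxc(
    table: CrossTable | np.ndarray,
    n_mc: int = 20000,
    seed: int | None = None,
    max_enumerate: int = 1_000_000,
) -> float:
    """Fisher's exact test for a general r x c table.

    The p-value is the total conditional probability (given the margins)
    of all tables no more probable than the observed one.  Exact
    enumeration is used while the number of margin-preserving tables stays
    below ``max_enumerate``; beyond that a Monte-Carlo permutation null
    (``n_mc`` resamples of the column labels, fixed ``seed``) estimates
    p as (1 + #{p_sim <= p_obs}) / (1 + n_mc).
    """
    T = table.counts if isinstance(table, CrossTable) else np.asarray(table)
    T = np.asarray(T, dtype=np.int64)
    if T.size == 0 or T.sum() == 0:
        raise ValueError("empty table")
    keep_r = T.sum(axis=1) > 0
    keep_c = T.sum(axis=0) > 0
    T = T[np.ix_(keep_r, keep_c)]
    if T.shape[0] < 2 or T.shape[1] < 2:
        return 1.0  # a single non-degenerate row or column carries no association
    n = int(T.sum())
    rm = T.sum(axis=1)
    cm = T.sum(axis=0)
    log_fact_margins = float(gammaln(rm + 1).sum() + gammaln(cm + 1).sum())
    log_fact_n = float(gammaln(n + 1))
    log_p_obs = _log_table_prob(T, log_fact_margins, log_fact_n)
    eps = 1e-10
    if _count_tables(list(rm), list(cm), max_enumerate) <= max_enumerate:
        total = 0.0
        for cand in _enumerate_tables(list(rm), list(cm)):
            lp = _log_table_prob(
                np.asarray(cand, dtype=np.int64), log_fact_margins, log_fact_n
            )
            if lp <= log_p_obs + eps:
                total += math.exp(lp)
        return min(total, 1.0)
    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(rm.size), rm)
    col_of = np.repeat(np.arange(cm.size), cm)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_of)
        sim = np.zeros_like(T)
        np.add.at(sim, (row_of, perm), 1)
        if _log_table_prob(sim, log_fact_margins, log_fact_n) <= log_p_obs + eps:
            hits += 1
    return (1 + hits) / (1 + n_mc)
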