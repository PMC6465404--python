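"""Categorical state-sequence data model for interval-sampled behaviour.

Behaviour scored in a home-pen play test is discretised into fixed 5-s
intervals.  Each interval carries an instantaneous state (object play on or
off the ground, or no play) plus one-zero flags for locomotor and social
play.  For sequence analysis these channels are merged into a three-state
alphabet — ``NoP`` (no play), ``ObjP`` (object play, any variant) and
``LocSocP`` (locomotor and/or social play) — with object play taking
priority over the one-zero flags when both occur in the same interval.

This module provides the merged :class:`StateSequence`, run-length spell
extraction, lag-1 transition-rate matrices, and the three within-sequence
variability measures used in social-science sequence analysis:
longitudinal entropy, turbulence and the complexity index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "MISSING_CODE",
    "Alphabet",
    "DEFAULT_ALPHABET",
    "IntervalRecord",
    "StateSequence",
    "Spell",
    "TransitionMatrix",
    "SequenceInputError",
    "build_state_sequence",
    "extract_spells",
    "transition_rates",
    "longitudinal_entropy",
    "count_distinct_subsequences",
    "turbulence",
    "complexity_index",
]

#: Label reserved for unscored intervals.
MISSING = "*"
#: Integer code for unscored intervals in :attr:`StateSequence.codes`.
MISSING_CODE = -1

#: Instantaneous (5-s point-sample) states accepted in raw records.
OBJP_INSTANT_STATES = frozenset({"ObjP_ground", "ObjP_off_ground"})
INSTANT_STATES = OBJP_INSTANT_STATES | {"NoP"}


class SequenceInputError(ValueError):
    """Structured error for malformed interval records or sequences."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered finite state alphabet.

    The default merged alphabet is ``(NoP, ObjP, LocSocP)`` in this fixed
    order; transition matrices, substitution-cost matrices and serialised
    outputs all follow it.
    """

    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("alphabet must contain at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError("alphabet labels must be unique")
        if any(not s for s in self.states):
            raise ValueError("alphabet labels must be non-empty")

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"state {label!r} not in alphabet {self.states}") from None

    def __iter__(self):
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)


DEFAULT_ALPHABET = Alphabet(("NoP", "ObjP", "LocSocP"))


@dataclass(frozen=True)
class IntervalRecord:
    """One animal in one 5-s observation interval, as scored from video.

    ``objp_onset_kind`` distinguishes, at the start of an object-play bout,
    whether the animal initiated play (first to touch a free toy) or joined
    a toy a penmate was already playing with; ``objp_company`` records
    whether it played alone or together with penmates during the interval.
    """

    animal_id: str
    group_id: str
    interval_index: int  # 1-based
    instantaneous_state: str  # ObjP_ground | ObjP_off_ground | NoP
    locp_flag: bool = False
    socp_flag: bool = False
    toy_id: Optional[int] = None
    objp_onset_kind: str = "none"  # initiate | join | none
    objp_company: str = "none"  # alone | together | none

    def __post_init__(self) -> None:
        if self.instantaneous_state not in INSTANT_STATES:
            raise SequenceInputError(
                f"unknown instantaneous state {self.instantaneous_state!r}"
            )
        if self.objp_onset_kind not in ("initiate", "join", "none"):
            raise SequenceInputError(f"bad onset kind {self.objp_onset_kind!r}")
        if self.objp_company not in ("alone", "together", "none"):
            raise SequenceInputError(f"bad company label {self.objp_company!r}")
        is_objp = self.instantaneous_state in OBJP_INSTANT_STATES
        if is_objp and self.objp_company == "none":
            raise SequenceInputError("object-play interval requires a company label")
        if not is_objp and self.objp_company != "none":
            raise SequenceInputError("company label outside object play")
        if not is_objp and self.objp_onset_kind != "none":
            raise SequenceInputError("onset label outside object play")
        if is_objp and self.toy_id is None:
            raise SequenceInputError("object-play interval requires a toy id")
        if not is_objp and self.toy_id is not None:
            raise SequenceInputError("toy id outside object play")

    @property
    def is_objp(self) -> bool:
        return self.instantaneous_state in OBJP_INSTANT_STATES


@dataclass
class StateSequence:
    """Merged per-animal state sequence over a fixed interval grid.

    ``codes`` holds alphabet indices, with :data:`MISSING_CODE` marking
    unscored intervals.  ``covariates`` carries per-animal descriptors
    (sex, handling treatment, weights, latency to approach a toy) used by
    the downstream trait models.
    """

    animal_id: str
    group_id: str
    codes: np.ndarray
    alphabet: Alphabet = DEFAULT_ALPHABET
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1:
            raise SequenceInputError("state codes must be one-dimensional")
        bad = (self.codes != MISSING_CODE) & (
            (self.codes < 0) | (self.codes >= self.alphabet.size)
        )
        if bad.any():
            raise SequenceInputError("state code outside alphabet")

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def labels(self) -> list[str]:
        return [
            MISSING if c == MISSING_CODE else self.alphabet.states[c]
            for c in self.codes
        ]

    def observed_codes(self) -> np.ndarray:
        """Codes with missing intervals removed (order preserved)."""
        return self.codes[self.codes != MISSING_CODE]

    def n_observed(self) -> int:
        return int((self.codes != MISSING_CODE).sum())


@dataclass(frozen=True)
class Spell:
    """Maximal run of one state: ``state`` from ``start_index`` (1-based)
    lasting ``duration`` intervals."""

    state: str
    start_index: int
    duration: int


@dataclass
class TransitionMatrix:
    """Lag-1 transition counts and row-stochastic rates over an alphabet.

    Rows whose from-state never occurs are left all-zero and flagged in
    ``defined_rows``.
    """

    alphabet: Alphabet
    counts: np.ndarray
    P: np.ndarray
    defined_rows: np.ndarray

    def rate(self, from_state: str, to_state: str) -> float:
        return float(
            self.P[self.alphabet.index(from_state), self.alphabet.index(to_state)]
        )


def build_state_sequence(
    records: Sequence[IntervalRecord],
    alphabet: Alphabet = DEFAULT_ALPHABET,
    n_intervals: int = 360,
) -> StateSequence:
    """Merge raw interval records for one animal into a 3-state sequence.

    Merging priority is ObjP > LocSocP > NoP: any instantaneous object-play
    state maps to ``ObjP`` regardless of the one-zero flags; otherwise a set
    locomotor or social flag maps to ``LocSocP``; otherwise ``NoP``.
    Intervals with no record become the missing marker.

    Raises
    ------
    SequenceInputError
        On duplicate or out-of-range interval indices, or records from more
        than one animal.
    """
    if n_intervals < 1:
        raise SequenceInputError("n_intervals must be positive")
    codes = np.full(n_intervals, MISSING_CODE, dtype=np.int64)
    seen: set[int] = set()
    animal_id = group_id = None
    i_nop = alphabet.index("NoP")
    i_obj = alphabet.index("ObjP")
    i_ls = alphabet.index("LocSocP")
    for rec in records:
        if animal_id is None:
            animal_id, group_id = rec.animal_id, rec.group_id
        elif rec.animal_id != animal_id:
            raise SequenceInputError("records from more than one animal")
        t = rec.interval_index
        if not (1 <= t <= n_intervals):
            raise SequenceInputError(f"interval index {t} out of range 1..{n_intervals}")
        if t in seen:
            raise SequenceInputError(f"duplicate interval index {t}")
        seen.add(t)
        if rec.is_objp:
            codes[t - 1] = i_obj
        elif rec.locp_flag or rec.socp_flag:
            codes[t - 1] = i_ls
        else:
            codes[t - 1] = i_nop
    return StateSequence(
        animal_id=animal_id or "", group_id=group_id or "",
        codes=codes, alphabet=alphabet,
    )


def extract_spells(seq: StateSequence) -> list[Spell]:
    """Run-length encode a sequence into maximal same-state spells.

    Missing intervals belong to no spell and are skipped: a state that
    resumes unchanged after a gap extends the running spell, so consecutive
    spells always differ in state and spell durations sum to the number of
    observed intervals.  ``start_index`` refers to the original grid.
    """
    if len(seq) == 0:
        raise SequenceInputError("empty sequence has no spells")
    spells: list[Spell] = []
    prev = MISSING_CODE
    for pos, c in enumerate(seq.codes, start=1):
        c = int(c)
        if c == MISSING_CODE:
            continue
        if c == prev and spells:
            last = spells[-1]
            spells[-1] = Spell(last.state, last.start_index, last.duration + 1)
        else:
            spells.append(Spell(seq.alphabet.states[c], pos, 1))
        prev = c
    return spells


def transition_rates(
    seqs: Iterable[StateSequence] | StateSequence,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> TransitionMatrix:
    """Pool lag-1 transition counts over sequences and row-normalise.

    Adjacent pairs where either interval is missing are skipped, so a gap
    contributes no transitions.  Rows with zero from-state count are left
    all-zero and flagged as undefined.
    """
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    seqs = list(seqs)
    if not seqs:
        raise SequenceInputError("no sequences supplied")
    if all(len(s) < 2 for s in seqs):
        raise SequenceInputError("need at least one sequence of length >= 2")
    a = alphabet.size
    counts = np.zeros((a, a), dtype=np.int64)
    for s in seqs:
        c = s.codes
        src, dst = c[:-1], c[1:]
        ok = (src != MISSING_CODE) & (dst != MISSING_CODE)
        np.add.at(counts, (src[ok], dst[ok]), 1)
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    P = np.zeros((a, a), dtype=float)
    P[defined] = counts[defined] / row_sums[defined, None]
    return TransitionMatrix(alphabet=alphabet, counts=counts, P=P, defined_rows=defined)


def _state_proportions(seq: StateSequence, alphabet: Alphabet) -> np.ndarray:
    obs = seq.observed_codes()
    if obs.size == 0:
        raise SequenceInputError("sequence has no observed intervals")
    return np.bincount(obs, minlength=alphabet.size) / obs.size


def longitudinal_entropy(
    seq: StateSequence, alphabet: Alphabet = DEFAULT_ALPHABET
) -> float:
    """Shannon entropy of the within-sequence state distribution, in [0, 1].

    h(x) = −Σ_i π_i ln π_i over observed state proportions, normalised by
    ln(a) so a uniform time budget over the full alphabet scores 1 and a
    constant sequence scores 0.  The measure ignores ordering entirely.
    """
    pi = _state_proportions(seq, alphabet)
    pi = pi[pi > 0]
    h = float(-(pi * np.log(pi)).sum())
    if alphabet.size == 1:
        return 0.0
    return h / math.log(alphabet.size)


def count_distinct_subsequences(dss: Sequence[str]) -> int:
    """Number of distinct subsequences of a distinct-successive-states
    sequence, counting the empty subsequence.

    Uses the exact-integer recurrence phi_t = 2 phi_{t-1} − phi_{k-1},
    where k is the last earlier position holding the same symbol (the
    correction term is 0 when the symbol is new).
    """
    phi = [1]  # phi[t] = count over the first t symbols
    last_seen: dict[str, int] = {}
    for t, sym in enumerate(dss, start=1):
        val = 2 * phi[t - 1]
        if sym in last_seen:
            val -= phi[last_seen[sym] - 1]
        phi.append(val)
        last_seen[sym] = t
    return phi[-1]


def turbulence(seq: StateSequence) -> float:
    """Sequence turbulence: variability of spell structure.

    T(x) = log2( phi(x) · (s2_max + 1) / (s2 + 1) ) where phi(x) counts the
    distinct subsequences of the spell-state (DSS) sequence, s2 is the
    population variance of spell durations and s2_max = (n−1)(1−t̄)² its
    maximum given the number of spells n and mean duration t̄.  A constant
    single-spell sequence scores exactly 1.
    """
    spells = extract_spells(seq)
    if not spells:
        raise SequenceInputError("sequence has no observed intervals")
    durations = np.array([sp.duration for sp in spells], dtype=float)
    n = durations.size
    tbar = durations.mean()
    s2 = float(durations.var())  # population variance (divide by n)
    s2_max = (n - 1) * (1.0 - tbar) ** 2
    phi = count_distinct_subsequences([sp.state for sp in spells])
    return math.log2(phi * (s2_max + 1.0) / (s2 + 1.0))


def complexity_index(
    seq: StateSequence, alphabet: Alphabet = DEFAULT_ALPHABET
) -> float:
    """Complexity index in [0, 1]: geometric mean of the normalised number
    of state changes and the normalised longitudinal entropy.

    C(x) = sqrt( q/q_max · h_norm ) with q the number of state changes
    between adjacent observed intervals and q_max the number of adjacent
    observed pairs (ℓ−1 for a gap-free sequence of length ℓ).
    """
    c = seq.codes
    src, dst = c[:-1], c[1:]
    ok = (src != MISSING_CODE) & (dst != MISSING_CODE)
    q_max = int(ok.sum())
    if seq.n_observed() < 2 or q_max == 0:
        raise SequenceInputError("complexity index needs at least two observed intervals")
    q = int((src[ok] != dst[ok]).sum())
    h = longitudinal_entropy(seq, alphabet)
    return math.sqrt((q / q_max) * h)
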