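"""Readers and writers for the plain-text interchange formats.

Three formats are supported, all delimited text:

* **long format** — one :class:`~playseq.seqcore.IntervalRecord` per row
  (``animal_id, group_id, interval_index, instantaneous_state, locp_flag,
  socp_flag, toy_id, objp_onset_kind, objp_company``);
* **wide format** — one merged sequence per row, states as the single
  characters ``N``/``O``/``L`` (``-`` for a missing interval);
* **distance matrix** — square CSV with the animal ids as header row and
  first column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    DEFAULT_ALPHABET,
    MISSING_CODE,
    Alphabet,
    IntervalRecord,
    SequenceInputError,
    StateSequence,
    build_state_sequence,
)

__all__ = [
    "LONG_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "write_records",
    "read_records",
    "sequences_from_frame",
    "write_wide",
    "read_wide",
    "write_distance_matrix",
    "read_distance_matrix",
]

LONG_COLUMNS = [
    "animal_id",
    "group_id",
    "interval_index",
    "instantaneous_state",
    "locp_flag",
    "socp_flag",
    "toy_id",
    "objp_onset_kind",
    "objp_company",
]

_WIDE_CHARS = {"NoP": "N", "ObjP": "O", "LocSocP": "L"}
_WIDE_STATES = {v: k for k, v in _WIDE_CHARS.items()}


def records_to_frame(records: Iterable[IntervalRecord]) -> pd.DataFrame:
    rows = [
        (
            r.animal_id, r.group_id, r.interval_index, r.instantaneous_state,
            int(r.locp_flag), int(r.socp_flag),
            "" if r.toy_id is None else r.toy_id,
            r.objp_onset_kind, r.objp_company,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[IntervalRecord]:
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise SequenceInputError(f"long-format table lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        toy = getattr(row, "toy_id")
        toy_id = None if (toy is None or toy == "" or pd.isna(toy)) else int(toy)
        records.append(
            IntervalRecord(
                animal_id=str(row.animal_id),
                group_id=str(row.group_id),
                interval_index=int(row.interval_index),
                instantaneous_state=str(row.instantaneous_state),
                locp_flag=bool(int(row.locp_flag)),
                socp_flag=bool(int(row.socp_flag)),
                toy_id=toy_id,
                objp_onset_kind=str(row.objp_onset_kind),
                objp_company=str(row.objp_company),
            )
        )
    return records


def write_records(records: Iterable[IntervalRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records(path: str | Path) -> list[IntervalRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    return frame_to_records(df)


def sequences_from_frame(
    df: pd.DataFrame,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    n_intervals: int = 360,
    covariates: pd.DataFrame | None = None,
) -> list[StateSequence]:
    """Build one merged sequence per animal from a long-format table.

    ``covariates``, if given, is indexed by ``animal_id`` and its columns
    are attached to each sequence.
    """
    seqs = []
    for _, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("interval_index")
        seq = build_state_sequence(frame_to_records(sub), alphabet, n_intervals)
        if covariates is not None and seq.animal_id in covariates.index:
            seq.covariates = covariates.loc[seq.animal_id].to_dict()
        seqs.append(seq)
    return seqs


def write_wide(seqs: Sequence[StateSequence], path: str | Path) -> None:
    rows = []
    for s in seqs:
        chars = "".join(
            "-" if c == MISSING_CODE else _WIDE_CHARS[s.alphabet.states[c]]
            for c in s.codes
        )
        rows.append((s.animal_id, s.group_id, chars))
    pd.DataFrame(rows, columns=["animal_id", "group_id", "states"]).to_csv(
        path, index=False
    )


def read_wide(
    path: str | Path, alphabet: Alphabet = DEFAULT_ALPHABET
) -> list[StateSequence]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    seqs = []
    for row in df.itertuples(index=False):
        codes = np.array(
            [
                MISSING_CODE if ch == "-" else alphabet.index(_WIDE_STATES[ch])
                for ch in row.states
            ],
            dtype=np.int64,
        )
        seqs.append(
            StateSequence(
                animal_id=str(row.animal_id), group_id=str(row.group_id),
                codes=codes, alphabet=alphabet,
            )
        )
    return seqs


def write_distance_matrix(ids: Sequence[str], D: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(D, index=list(ids), columns=list(ids)).to_csv(path)


def read_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)
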