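import numpy as np
import pytest

import playseq as ps
from playseq.io import records_to_frame, sequences_from_frame
from playseq.seqcore import DEFAULT_ALPHABET, StateSequence

#: Conventional seed for the deterministic study-scale fixtures.
STUDY_SEED = 1


def make_seq(codes, animal_id="a", group_id="g"):
    return StateSequence(
        animal_id=animal_id, group_id=group_id,
        codes=np.asarray(codes, dtype=np.int64), alphabet=DEFAULT_ALPHABET,
    )


def random_seq(rng, length, missing_rate=0.0, animal_id="a"):
    codes = rng.integers(0, 3, size=length)
    if missing_rate:
        codes[rng.random(length) < missing_rate] = -1
    return make_seq(codes, animal_id=animal_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_data():
    """One study-scale synthetic dataset (15 groups x 4 pigs x 360)."""
    config = ps.preset_study(seed=STUDY_SEED)
    return ps.generate_dataset(config)


@pytest.fixture(scope="session")
def study_seqs(study_data):
    records, covariates, _ = study_data
    return sequences_from_frame(
        records_to_frame(records), covariates=covariates
    )


@pytest.fixture(scope="session")
def study_distances(study_seqs):
    """Pooled transition rates, substitution costs and the OM distance
    matrix of the study-scale dataset (computed once per session)."""
    tm = ps.transition_rates(study_seqs)
    sc = ps.substitution_costs_from_rates(tm)
    D = ps.pairwise_distances(study_seqs, sc)
    return tm, sc, D
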