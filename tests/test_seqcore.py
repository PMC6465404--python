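"""Sequence construction, spells, transition rates and complexity measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from playseq.seqcore import (
    DEFAULT_ALPHABET,
    MISSING_CODE,
    IntervalRecord,
    SequenceInputError,
    build_state_sequence,
    complexity_index,
    count_distinct_subsequences,
    extract_spells,
    longitudinal_entropy,
    transition_rates,
    turbulence,
)

from conftest import make_seq, random_seq


def rec(t, state="NoP", locp=False, socp=False, **kw):
    defaults = dict(animal_id="a", group_id="g", interval_index=t,
                    instantaneous_state=state, locp_flag=locp, socp_flag=socp)
    if state != "NoP":
        defaults.update(toy_id=1, objp_company="alone")
    defaults.update(kw)
    return IntervalRecord(**defaults)


class TestBuildStateSequence:
    @pytest.mark.parametrize(
        "record,expected",
        [
            (rec(1, "ObjP_ground", locp=True), "ObjP"),      # ObjP wins over flags
            (rec(1, "ObjP_off_ground"), "ObjP"),
            (rec(1, "NoP"), "NoP"),
            (rec(1, "NoP", socp=True), "LocSocP"),
            (rec(1, "NoP", locp=True, socp=True), "LocSocP"),
        ],
    )
    def test_merge_priority(self, record, expected):
        seq = build_state_sequence([record], n_intervals=1)
        assert seq.labels == [expected]

    def test_unscored_intervals_become_missing(self):
        seq = build_state_sequence([rec(2)], n_intervals=3)
        assert seq.labels == ["*", "NoP", "*"]

    def test_duplicate_index_rejected(self):
        with pytest.raises(SequenceInputError, match="duplicate"):
            build_state_sequence([rec(1), rec(1)], n_intervals=2)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(SequenceInputError, match="out of range"):
            build_state_sequence([rec(5)], n_intervals=3)

    def test_default_length_is_360(self):
        assert len(build_state_sequence([rec(1)])) == 360


class TestSpells:
    def test_run_length_encoding(self):
        spells = extract_spells(make_seq([1, 1, 0, 1]))
        assert [(s.state, s.start_index, s.duration) for s in spells] == [
            ("ObjP", 1, 2), ("NoP", 3, 1), ("ObjP", 4, 1)
        ]

    def test_constant_sequence_is_one_spell(self):
        (spell,) = extract_spells(make_seq([2] * 360))
        assert (spell.state, spell.duration) == ("LocSocP", 360)

    def test_all_distinct_states(self):
        spells = extract_spells(make_seq([0, 1, 2, 0]))
        assert [s.duration for s in spells] == [1, 1, 1, 1]

    def test_gap_does_not_split_a_spell(self):
        # consecutive spells must differ in state even across missing gaps
        spells = extract_spells(make_seq([1, 1, MISSING_CODE, 1, 0]))
        assert [(s.state, s.duration) for s in spells] == [("ObjP", 3), ("NoP", 1)]

    def test_durations_sum_to_observed(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 50, missing_rate=0.2)
            if seq.n_observed() == 0:
                continue
            assert sum(s.duration for s in extract_spells(seq)) == seq.n_observed()


class TestTransitionRates:
    def test_constant_objp_row(self):
        tm = transition_rates(make_seq([1] * 5))
        assert np.allclose(tm.P[1], [0, 1, 0])
        assert not tm.defined_rows[0] and not tm.defined_rows[2]

    def test_hand_counted_example(self):
        tm = transition_rates(make_seq([0, 0, 1, 1, 0]))
        assert tm.rate("NoP", "NoP") == 0.5
        assert tm.rate("NoP", "ObjP") == 0.5
        assert tm.rate("ObjP", "ObjP") == 0.5
        assert tm.rate("ObjP", "NoP") == 0.5

    def test_pooling_over_sequences(self):
        tm = transition_rates([make_seq([0, 1]), make_seq([0, 1], animal_id="b")])
        assert tm.counts[0, 1] == 2
        assert tm.rate("NoP", "ObjP") == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(SequenceInputError):
            transition_rates(make_seq([1]))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            seqs = [random_seq(rng, int(rng.integers(2, 15)), missing_rate=0.2,
                               animal_id=str(i)) for i in range(3)]
            tm = transition_rates(seqs)
            counts = np.zeros((3, 3), dtype=int)
            for s in seqs:
                c = list(s.codes)
                for a, b in zip(c[:-1], c[1:]):
                    if a != MISSING_CODE and b != MISSING_CODE:
                        counts[a, b] += 1
            assert np.array_equal(tm.counts, counts)
            for i in range(3):
                if counts[i].sum():
                    assert np.allclose(tm.P[i], counts[i] / counts[i].sum())
                    assert abs(tm.P[i].sum() - 1.0) < 1e-12


class TestEntropy:
    def test_constant_is_zero(self):
        assert longitudinal_entropy(make_seq([0] * 10)) == 0.0

    def test_uniform_is_one(self):
        assert longitudinal_entropy(make_seq([0, 1, 2] * 4)) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        # proportions (1/2, 1/4, 1/4) over a 3-letter alphabet
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25)) / math.log(3)
        seq = make_seq([1, 1, 0, 2])
        assert longitudinal_entropy(seq) == pytest.approx(expected)
        assert expected == pytest.approx(0.9464, abs=1e-4)

    def test_missing_ignored(self):
        with_gap = make_seq([1, MISSING_CODE, 1, 0, 2])
        without = make_seq([1, 1, 0, 2])
        assert longitudinal_entropy(with_gap) == longitudinal_entropy(without)


def brute_force_distinct_subsequences(dss):
    found = {()}
    n = len(dss)
    for mask in range(1, 2 ** n):
        found.add(tuple(dss[i] for i in range(n) if mask >> i & 1))
    return len(found)


class TestDistinctSubsequences:
    @pytest.mark.parametrize(
        "dss,expected",
        [([], 1), (["N"], 2), (["N", "O", "N"], 7)],
    )
    def test_known_values(self, dss, expected):
        assert count_distinct_subsequences(dss) == expected
        if dss:
            assert brute_force_distinct_subsequences(dss) == expected

    def test_matches_enumeration_short(self):
        # every valid DSS (no two adjacent equal) over 3 symbols, length <= 7
        all_dss = [[]] + [[s] for s in "NOL"]
        level = [[s] for s in "NOL"]
        for _ in range(6):
            level = [d + [s] for d in level for s in "NOL" if s != d[-1]]
            all_dss.extend(level)
        for dss in all_dss:
            assert count_distinct_subsequences(dss) == \
                brute_force_distinct_subsequences(dss)


class TestTurbulence:
    def test_single_spell_exactly_one(self):
        for n in (1, 5, 360):
            assert turbulence(make_seq([1] * n)) == 1.0

    def test_two_equal_spells(self):
        # two spells of duration 2: phi = 4, s2 = 0, s2max = (1-2)^2 = 1
        assert turbulence(make_seq([0, 0, 1, 1])) == pytest.approx(math.log2(8))

    def test_direct_formula(self, rng):
        for _ in range(25):
            seq = random_seq(rng, int(rng.integers(2, 40)))
            spells = extract_spells(seq)
            d = np.array([s.duration for s in spells], float)
            phi = count_distinct_subsequences([s.state for s in spells])
            s2 = d.var()
            s2max = (d.size - 1) * (1 - d.mean()) ** 2
            assert turbulence(seq) == pytest.approx(
                math.log2(phi * (s2max + 1) / (s2 + 1))
            )

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_phi_monotone_under_spell_insertion(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 8))
        dss = ["NOL"[r.integers(0, 3)]]
        while len(dss) < n:
            s = "NOL"[r.integers(0, 3)]
            if s != dss[-1]:
                dss.append(s)
        pos = int(r.integers(0, len(dss) + 1))
        sym = "NOL"[r.integers(0, 3)]
        extended = dss[:pos] + [sym] + dss[pos:]
        # collapse any adjacent duplicates the insertion created
        cleaned = [extended[0]]
        for s in extended[1:]:
            if s != cleaned[-1]:
                cleaned.append(s)
        assert count_distinct_subsequences(cleaned) >= \
            count_distinct_subsequences(dss)


class TestComplexityIndex:
    def test_constant_is_zero(self):
        assert complexity_index(make_seq([0] * 10)) == 0.0

    def test_strict_alternation(self):
        seq = make_seq([1, 0] * 180)
        assert complexity_index(seq) == pytest.approx(
            math.sqrt(math.log(2) / math.log(3))
        )

    def test_bounds_on_random_sequences(self, rng):
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(2, 100)))
            c = complexity_index(seq)
            h = longitudinal_entropy(seq)
            assert 0.0 <= c <= 1.0
            assert 0.0 <= h <= 1.0

    def test_too_short_rejected(self):
        with pytest.raises(SequenceInputError):
            complexity_index(make_seq([1]))
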