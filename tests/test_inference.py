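"""Stratified tests, bout extraction and the regression models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from playseq.inference import (
    bonferroni,
    bout_table,
    cmh_test,
    extract_bouts,
    linear_model_traits,
    mh_chisq_frequencies,
    poisson_bout_model,
    traits_table,
)
from playseq.seqcore import extract_spells

from conftest import make_seq, random_seq


def random_2x2_strata(rng, k):
    return [rng.integers(1, 12, size=(2, 2)).astype(float) for _ in range(k)]


class TestCmh:
    def test_single_stratum_direct_value(self):
        stat, df, p = cmh_test([np.array([[10, 0], [0, 10]])])
        assert df == 1
        assert stat == pytest.approx(25 / ((10 * 10 * 10 * 10) / (20 ** 2 * 19)))
        assert stat == pytest.approx(19.0)

    def test_no_association_is_small(self):
        strata = [np.array([[10, 10], [10, 10]])] * 3
        stat, _, p = cmh_test(strata)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.contingency_tables import StratifiedTable

        for _ in range(50):
            strata = random_2x2_strata(rng, int(rng.integers(1, 6)))
            stat, df, p = cmh_test(strata)
            st = StratifiedTable(np.stack(strata, axis=-1))
            res = st.test_null_odds(correction=False)
            assert stat == pytest.approx(float(res.statistic))
            assert p == pytest.approx(float(res.pvalue))

    def test_zero_margin_stratum_skipped(self):
        good = np.array([[10, 0], [0, 10]])
        bad = np.array([[5, 5], [0, 0]])
        with pytest.warns(UserWarning, match="zero margin"):
            stat, _, _ = cmh_test([good, bad])
        assert stat == pytest.approx(19.0)

    def test_all_degenerate_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                cmh_test([np.array([[5, 5], [0, 0]])])

    def test_general_association_df(self, rng):
        # 3x3xK strata use the general-association statistic with df 4
        strata = [rng.integers(1, 10, size=(3, 3)).astype(float)
                  for _ in range(3)]
        stat, df, p = cmh_test(strata)
        assert df == 4 and stat >= 0 and 0 <= p <= 1


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps_in,expected",
        [([0.01], [0.01]), ([0.01, 0.02], [0.02, 0.04]), ([0.9, 0.9], [1.0, 1.0])],
    )
    def test_adjustment(self, ps_in, expected):
        assert bonferroni(ps_in) == pytest.approx(expected)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


def mh_oracle(T):
    """Expand the table to individual scores and use the plain Pearson
    correlation — an independent route to (N-1) r^2."""
    rows, cols = [], []
    R, C = T.shape
    for i in range(R):
        for j in range(C):
            rows += [i + 1] * int(T[i, j])
            cols += [j + 1] * int(T[i, j])
    r = np.corrcoef(rows, cols)[0, 1]
    return (len(rows) - 1) * r ** 2


class TestMhChisq:
    def test_perfectly_linear_diagonal(self):
        T = np.diag([7, 7, 7])
        stat, df, _ = mh_chisq_frequencies(T)
        assert (stat, df) == (pytest.approx(T.sum() - 1), 1)

    def test_independence_near_zero(self):
        T = np.full((3, 3), 8)
        stat, _, p = mh_chisq_frequencies(T)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_expansion_oracle(self, rng):
        for _ in range(50):
            T = rng.integers(0, 10, size=(3, 4))
            if T.sum() < 2:
                continue
            try:
                stat, _, _ = mh_chisq_frequencies(T)
            except ValueError:
                continue
            assert stat == pytest.approx(mh_oracle(T))

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            mh_chisq_frequencies(np.array([[3, 4, 5]]))


class TestBouts:
    def test_examples(self):
        bouts = extract_bouts(make_seq([1, 1, 0, 1]))
        assert [(b.start_index, b.duration) for b in bouts] == [(1, 2), (4, 1)]
        assert extract_bouts(make_seq([0, 0, 2])) == []
        (b,) = extract_bouts(make_seq([1] * 360))
        assert b.duration == 360

    def test_round_trips_with_spells(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 50, missing_rate=0.1)
            bouts = extract_bouts(seq, "ObjP")
            spells = [s for s in extract_spells(seq) if s.state == "ObjP"]
            assert [(b.start_index, b.duration) for b in bouts] == \
                [(s.start_index, s.duration) for s in spells]


class TestPoissonModel:
    def test_intercept_only_recovers_log_mean(self, rng):
        durations = rng.poisson(6.0, size=300) + 1
        df = pd.DataFrame({"duration": durations})
        fit = poisson_bout_model(df, fixed=(), covariates=())
        assert fit.params["Intercept"] == pytest.approx(
            np.log(durations.mean()), abs=1e-6
        )

    def test_recovers_planted_time_slope(self, rng):
        n = 500
        t = rng.uniform(0, 1800, size=n)
        beta_time = -0.0003
        mu = np.exp(1.8 + beta_time * t)
        df = pd.DataFrame({"duration": rng.poisson(mu), "time_s": t})
        fit = poisson_bout_model(df, fixed=(), covariates=("time_s",))
        est, se = fit.params["time_s"], fit.bse["time_s"]
        assert abs(est - beta_time) < 3 * se

    def test_flat_durations_cover_zero_slope(self, rng):
        df = pd.DataFrame(
            {"duration": np.full(100, 5), "time_s": rng.uniform(0, 1800, 100)}
        )
        fit = poisson_bout_model(df, fixed=(), covariates=("time_s",))
        lo, hi = fit.conf_int().loc["time_s"]
        assert lo < 0 < hi

    def test_constant_factor_dropped_with_warning(self, rng):
        df = pd.DataFrame(
            {"duration": rng.poisson(5, 50) + 1, "sex": ["male"] * 50}
        )
        with pytest.warns(UserWarning, match="constant"):
            fit = poisson_bout_model(df, fixed=("sex",), covariates=())
        assert "Intercept" in fit.params.index


class TestLinearModelTraits:
    @staticmethod
    def noise_frame(rng, group_effect=0.0):
        rows = []
        for g in range(8):
            bump = group_effect * rng.normal()
            for p in range(4):
                rows.append(
                    {
                        "entropy": rng.normal() + bump,
                        "group_id": f"g{g}",
                        "sex": ["male", "female"][p % 2],
                        "birth_weight": rng.normal(1.5, 0.2),
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_group_effect_detected(self, rng):
        df = self.noise_frame(rng, group_effect=5.0)
        _, anova = linear_model_traits(
            df, "entropy", fixed=("group_id", "sex"), covariates=("birth_weight",)
        )
        assert anova.loc["C(group_id, Sum)", "PR(>F)"] < 0.01

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(150):
            df = self.noise_frame(rng)
            _, anova = linear_model_traits(
                df, "entropy", fixed=("group_id", "sex"),
                covariates=("birth_weight",),
            )
            pvals.append(anova.loc["C(group_id, Sum)", "PR(>F)"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_deterministic(self, rng):
        df = self.noise_frame(rng, group_effect=1.0)
        _, a1 = linear_model_traits(df, "entropy", fixed=("group_id", "sex"),
                                    covariates=("birth_weight",))
        _, a2 = linear_model_traits(df, "entropy", fixed=("group_id", "sex"),
                                    covariates=("birth_weight",))
        assert np.allclose(a1["F"].dropna(), a2["F"].dropna())


class TestTraitAndBoutTables:
    def test_tables_carry_covariates(self, study_seqs):
        traits = traits_table(study_seqs[:8])
        assert {"entropy", "turbulence", "complexity", "sex"} <= set(traits.columns)
        assert len(traits) == 8
        bouts = bout_table(study_seqs[:8])
        assert (bouts["duration"] >= 1).all()
        assert np.allclose(bouts["time_s"], (bouts["start_index"] - 1) * 5.0)
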