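"""Stratified tests and regression models for sequence-derived traits.

Covers four analyses that sit downstream of the sequence construction:

* Cochran–Mantel–Haenszel tests comparing transition usage between player
  types across group strata (2x2xK primary; general IxJxK association
  statistic as an extension), with Bonferroni correction over the family
  of transition comparisons;
* the Mantel–Haenszel chi-square for ordered r x c frequency tables,
  Q = (N−1) r² with r the score correlation;
* run-length extraction of object-play bouts and a log-link Poisson
  regression of bout duration on group, treatment, sex, player type,
  weights and bout start time;
* a Gaussian linear model of the per-animal complexity traits (entropy,
  turbulence, complexity index) on the same fixed effects and covariates,
  with marginal (Type-III-style) F tests per term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .seqcore import StateSequence, complexity_index, longitudinal_entropy, turbulence
from .seqcore import DEFAULT_ALPHABET, Alphabet, extract_spells

__all__ = [
    "Bout",
    "cmh_test",
    "bonferroni",
    "mh_chisq_frequencies",
    "extract_bouts",
    "bout_table",
    "traits_table",
    "poisson_bout_model",
    "linear_model_traits",
]

#: Seconds per observation interval; bout start times enter models in seconds.
INTERVAL_SECONDS = 5.0


@dataclass(frozen=True)
class Bout:
    """One maximal run of a target state for one animal."""

    animal_id: str
    state: str
    start_index: int  # 1-based interval position
    duration: int  # in intervals


def cmh_test(strata: Sequence[np.ndarray]) -> tuple[float, int, float]:
    """Cochran–Mantel–Haenszel chi-square over K same-shaped tables.

    For 2x2xK the classic form sum(a_k − E_k)² / sum(Var_k) is used with
    hypergeometric variances and no continuity correction.  For larger
    tables the general-association statistic with df = (I−1)(J−1) is
    computed from the stacked cell deviations and their multivariate
    hypergeometric covariance.  Strata with a zero row or column margin
    total are skipped with a warning (they carry no information about
    association).
    """
    tables = [np.asarray(t, dtype=float) for t in strata]
    if not tables:
        raise ValueError("no strata supplied")
    shape = tables[0].shape
    if any(t.shape != shape for t in tables):
        raise ValueError("strata must share one table shape")
    usable = []
    for idx, t in enumerate(tables):
        if t.sum() <= 1 or (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
            warnings.warn(f"stratum {idx} has a zero margin; skipped", stacklevel=2)
            continue
        usable.append(t)
    if not usable:
        raise ValueError("all strata degenerate")
    I, J = shape
    if (I, J) == (2, 2):
        num = 0.0
        var = 0.0
        for t in usable:
            n = t.sum()
            r1, c1 = t[0].sum(), t[:, 0].sum()
            e = r1 * c1 / n
            v = r1 * (n - r1) * c1 * (n - c1) / (n ** 2 * (n - 1))
            num += t[0, 0] - e
            var += v
        if var == 0:
            raise ValueError("zero variance across strata")
        stat = num ** 2 / var
        df = 1
    else:
        p = (I - 1) * (J - 1)
        dev = np.zeros(p)
        cov = np.zeros((p, p))
        for t in usable:
            n = t.sum()
            pr = t.sum(axis=1) / n
            pc = t.sum(axis=0) / n
            e = np.outer(pr, pc) * n
            dev += (t - e)[: I - 1, : J - 1].ravel()
            # covariance of the (I-1)(J-1) cell counts under the
            # multiple-hypergeometric null
            vr = np.diag(pr[: I - 1]) - np.outer(pr[: I - 1], pr[: I - 1])
            vc = np.diag(pc[: J - 1]) - np.outer(pc[: J - 1], pc[: J - 1])
            cov += (n ** 2 / (n - 1)) * np.kron(vr, vc)
        stat = float(dev @ np.linalg.solve(cov, dev))
        df = p
    return float(stat), int(df), float(chi2.sf(stat, df))


def bonferroni(p_values: Iterable[float]) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, m p)."""
    ps = list(p_values)
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def mh_chisq_frequencies(
    table: np.ndarray,
    row_scores: Sequence[float] | None = None,
    col_scores: Sequence[float] | None = None,
) -> tuple[float, int, float]:
    """Mantel–Haenszel chi-square for linear association in an ordered table.

    Q = (N − 1) r² where r is the Pearson correlation between row and
    column scores weighted by the cell counts; df = 1.  Default scores are
    the integer ranks 1..r and 1..c.
    """
    T = np.asarray(table, dtype=float)
    R, C = T.shape
    rs = np.asarray(row_scores if row_scores is not None else np.arange(1, R + 1), float)
    cs = np.asarray(col_scores if col_scores is not None else np.arange(1, C + 1), float)
    n = T.sum()
    if n < 2:
        raise ValueError("need at least two observations")
    w = T / n
    mr = float((w.sum(axis=1) * rs).sum())
    mc = float((w.sum(axis=0) * cs).sum())
    vr = float((w.sum(axis=1) * (rs - mr) ** 2).sum())
    vc = float((w.sum(axis=0) * (cs - mc) ** 2).sum())
    if vr == 0 or vc == 0:
        raise ValueError("zero variance in a margin; MH statistic undefined")
    cov = float((w * np.outer(rs - mr, cs - mc)).sum())
    r = cov / np.sqrt(vr * vc)
    stat = (n - 1) * r ** 2
    return float(stat), 1, float(chi2.sf(stat, 1))


def extract_bouts(seq: StateSequence, state: str = "ObjP") -> list[Bout]:
    """Maximal runs of one target state, with 1-based start positions."""
    return [
        Bout(seq.animal_id, sp.state, sp.start_index, sp.duration)
        for sp in extract_spells(seq)
        if sp.state == state
    ]


def bout_table(
    seqs: Iterable[StateSequence], state: str = "ObjP"
) -> pd.DataFrame:
    """Long table of bouts with start time in seconds and the per-animal
    covariates attached (for the Poisson duration model)."""
    rows = []
    for s in seqs:
        for b in extract_bouts(s, state):
            row = {
                "animal_id": s.animal_id,
                "group_id": s.group_id,
                "state": b.state,
                "start_index": b.start_index,
                "duration": b.duration,
                "time_s": (b.start_index - 1) * INTERVAL_SECONDS,
            }
            row.update(s.covariates)
            rows.append(row)
    return pd.DataFrame(rows)


def traits_table(
    seqs: Iterable[StateSequence], alphabet: Alphabet = DEFAULT_ALPHABET
) -> pd.DataFrame:
    """Per-animal complexity traits plus covariates (for the trait models)."""
    rows = []
    for s in seqs:
        row = {
            "animal_id": s.animal_id,
            "group_id": s.group_id,
            "entropy": longitudinal_entropy(s, alphabet),
            "turbulence": turbulence(s),
            "complexity": complexity_index(s, alphabet),
        }
        row.update(s.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def _drop_aliased(df: pd.DataFrame, terms: list[str]) -> list[str]:
    """Drop constant factors/covariates, which would be aliased with the
    intercept, warning per dropped term."""
    kept = []
    for t in terms:
        col = t
        if t.startswith("C("):
            col = t[2:].rstrip(")").split(",")[0].strip()
        if col in df.columns and df[col].nunique(dropna=True) < 2:
            warnings.warn(f"term {t!r} is constant; dropped from the model", stacklevel=3)
            continue
        kept.append(t)
    return kept


def poisson_bout_model(
    bouts: pd.DataFrame,
    fixed: Sequence[str] = ("group_id", "treatment", "sex", "player_type"),
    covariates: Sequence[str] = ("birth_weight", "weight9", "time_s"),
):
    """Log-link Poisson regression of bout duration on fixed effects and
    covariates (bout start time among them).

    Returns the fitted statsmodels results object; ``.params``,
    ``.bse`` and ``.wald_test_terms()`` give the coefficient table and
    per-term tests.
    """
    if bouts.empty:
        raise ValueError("no bouts to model")
    terms = [f"C({f})" for f in fixed if f in bouts.columns]
    terms += [c for c in covariates if c in bouts.columns]
    terms = _drop_aliased(bouts, terms)
    rhs = " + ".join(terms) if terms else "1"
    model = smf.glm(
        f"duration ~ {rhs}", data=bouts, family=sm.families.Poisson()
    )
    return model.fit()


def linear_model_traits(
    traits: pd.DataFrame,
    response: str,
    fixed: Sequence[str] = ("group_id", "treatment", "sex", "player_type"),
    covariates: Sequence[str] = ("birth_weight", "weight9"),
) -> tuple[object, pd.DataFrame]:
    """Gaussian linear model of one complexity trait with marginal F tests.

    Factors enter with sum-to-zero contrasts so the per-term (Type-III
    style) F tests are invariant to the factor level ordering.  Returns
    ``(fit, anova_table)``.
    """
    from statsmodels.stats.anova import anova_lm

    if response not in traits.columns:
        raise ValueError(f"unknown response {response!r}")
    terms = [f"C({f}, Sum)" for f in fixed if f in traits.columns]
    terms += [c for c in covariates if c in traits.columns]
    terms = _drop_aliased(traits, terms)
    rhs = " + ".join(terms) if terms else "1"
    fit = smf.ols(f"{response} ~ {rhs}", data=traits).fit()
    if terms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_lm(fit, typ=3)
    else:
        table = pd.DataFrame()
    return fit, table
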