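"""Association statistics on 2x3 genotype count tables.

The worked-example values are frozen from independent oracles: direct
hand evaluation of the score formulas, R's prop.trend.test for the trend
statistic, and a Monte-Carlo permutation of case labels.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetgwas import (
    GenotypeCountTable,
    allele_table,
    allelic_or,
    catt,
    chisq_allelic,
    chisq_genotype,
)
from hetgwas.association import catt_statistic


def test_worked_example_statistics(toy_table):
    r = catt(toy_table)
    assert r.statistic == pytest.approx(4.265403, abs=5e-4)
    assert r.p_value == pytest.approx(0.038896, abs=5e-5)
    assert r.df == 1

    g = chisq_genotype(toy_table)
    assert g.statistic == pytest.approx(4.380952, abs=5e-4)
    assert g.df == 2
    assert g.p_value == pytest.approx(0.111863, abs=5e-5)

    a = chisq_allelic(toy_table)
    assert a.statistic == pytest.approx(5.128205, abs=5e-4)
    assert a.p_value == pytest.approx(0.023540, abs=5e-5)

    o = allelic_or(toy_table)
    assert o.odds_ratio == pytest.approx(2.0, abs=1e-12)
    assert not o.corrected
    assert o.ci_low <= o.odds_ratio <= o.ci_high


def test_allele_table_arithmetic(toy_table):
    assert allele_table(toy_table).tolist() == [[40, 60], [25, 75]]
    assert allele_table(
        GenotypeCountTable((10, 0, 0), (5, 0, 0))
    ).tolist() == [[0, 20], [0, 10]]
    assert allele_table(
        GenotypeCountTable((0, 0, 10), (10, 0, 0))
    ).tolist() == [[20, 0], [0, 20]]


def test_identical_groups_are_null():
    t = GenotypeCountTable((30, 15, 5), (30, 15, 5))
    assert catt(t).statistic == 0.0 and catt(t).p_value == 1.0
    assert chisq_genotype(t).statistic == 0.0 and chisq_genotype(t).p_value == 1.0
    assert chisq_allelic(t).statistic == 0.0 and chisq_allelic(t).p_value == 1.0
    assert allelic_or(t).odds_ratio == pytest.approx(1.0)


def test_trend_weights_affine_invariance(toy_table):
    assert catt(toy_table, weights=(2, 1, 0)).statistic == pytest.approx(
        catt(toy_table).statistic
    )
    assert catt(toy_table, weights=(10, 30, 50)).statistic == pytest.approx(
        catt(toy_table).statistic
    )


def test_degenerate_tables_report_p_one():
    one_column = GenotypeCountTable((20, 0, 0), (30, 0, 0))
    assert catt(one_column).degenerate and catt(one_column).p_value == 1.0
    assert chisq_genotype(one_column).degenerate
    assert chisq_allelic(one_column).degenerate  # monomorphic


def test_all_zero_column_reduces_df():
    t = GenotypeCountTable((20, 10, 0), (10, 20, 0))
    assert chisq_genotype(t).df == 1


def test_zero_cell_or_is_corrected_and_finite():
    t = GenotypeCountTable((10, 10, 0), (20, 0, 0))
    o = allelic_or(t)
    assert o.corrected
    assert np.isfinite(o.odds_ratio) and o.odds_ratio > 0
    assert np.isfinite(o.log_se)


def test_catt_equals_n_times_squared_correlation(toy_table):
    """Independent route: the trend statistic is N * corr(dosage, status)^2
    over the expanded individual-level data."""
    n, m = toy_table.cases.astype(int), toy_table.controls.astype(int)
    dosage = np.repeat([0, 1, 2], n).tolist() + np.repeat([0, 1, 2], m).tolist()
    status = [1] * n.sum() + [0] * m.sum()
    r = np.corrcoef(dosage, status)[0, 1]
    assert catt(toy_table).statistic == pytest.approx(len(status) * r**2, rel=1e-12)


def test_catt_against_permutation_oracle():
    """On a small table the asymptotic trend p-value tracks the Monte-Carlo
    permutation p-value of the same statistic."""
    table = GenotypeCountTable((8, 6, 4), (10, 4, 1))
    observed = catt(table).statistic
    dosage = np.repeat(
        [0, 1, 2, 0, 1, 2], np.concatenate([table.cases, table.controls]).astype(int)
    )
    n_cases = int(table.cases.sum())
    rng = np.random.default_rng(42)
    hits = 0
    reps = 20000
    for _ in range(reps):
        perm = rng.permutation(dosage)
        cases = np.bincount(perm[:n_cases], minlength=3)
        controls = np.bincount(perm[n_cases:], minlength=3)
        if catt_statistic(cases, controls) >= observed - 1e-12:
            hits += 1
    p_perm = hits / reps
    assert catt(table).p_value == pytest.approx(p_perm, abs=0.03)


def test_catt_matches_linear_by_linear_cross_check(toy_table):
    """statsmodels' ordinal (linear-by-linear) score test differs from the
    trend statistic only by the known (N-1)/N factor."""
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    tab = sm.Table(np.array([toy_table.case_counts, toy_table.control_counts]))
    res = tab.test_ordinal_association(
        row_scores=np.array([1.0, 0.0]), col_scores=np.array([0.0, 1.0, 2.0])
    )
    N = 100
    assert catt(toy_table).statistic == pytest.approx(
        res.zscore**2 * N / (N - 1), rel=1e-10
    )


@settings(derandomize=True, max_examples=60)
@given(
    counts=st.lists(st.integers(0, 50), min_size=6, max_size=6).filter(
        lambda c: sum(c[:3]) >= 1 and sum(c[3:]) >= 1
    )
)
def test_label_swap_symmetry(counts):
    t = GenotypeCountTable(tuple(counts[:3]), tuple(counts[3:]))
    s = t.swapped()
    assert catt(s).statistic == pytest.approx(catt(t).statistic, abs=1e-9)
    assert chisq_genotype(s).statistic == pytest.approx(
        chisq_genotype(t).statistic, abs=1e-9
    )
    assert chisq_allelic(s).statistic == pytest.approx(
        chisq_allelic(t).statistic, abs=1e-9
    )
    assert allelic_or(s).odds_ratio == pytest.approx(
        1.0 / allelic_or(t).odds_ratio, rel=1e-9
    )
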