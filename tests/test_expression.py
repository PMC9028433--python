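"""Expression scoring: paired logFC, the two tests, SS and top-rank selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from netcombo.expression import (
    PairingError,
    compute_paired_logfc,
    paired_wilcoxon,
    rank_scores,
    score_genes,
    select_candidate_genes,
    significance_scores,
    variance_f_test,
)

from conftest import make_paired_expression


# ---------------------------------------------------------------------------
# logFC
# ---------------------------------------------------------------------------

def test_logfc_zero_for_identical_conditions():
    vals = np.array([[1.0, 5.0, 9.0], [0.0, 2.0, 4.0]])
    expr = make_paired_expression(vals, vals)
    assert np.allclose(compute_paired_logfc(expr), 0.0)


def test_logfc_doubling_saturates_to_one():
    v = np.full((1, 3), 1e4)
    expr = make_paired_expression(2 * v, v)
    assert compute_paired_logfc(expr).iloc[0] == pytest.approx(1.0, abs=0.01)


def test_logfc_matches_hand_arithmetic():
    disease = np.array([[3.0, 7.0], [0.0, 1.0], [15.0, 15.0]])
    control = np.array([[1.0, 1.0], [3.0, 0.0], [15.0, 15.0]])
    expected = [
        np.mean(np.log2(disease[i] + 1)) - np.mean(np.log2(control[i] + 1))
        for i in range(3)
    ]
    expr = make_paired_expression(disease, control)
    assert np.allclose(compute_paired_logfc(expr), expected)


def test_unpaired_subject_rejected():
    vals = np.array([[1.0, 2.0]])
    expr_frame = pd.DataFrame(vals, index=["g1"], columns=["a", "b"])
    meta = pd.DataFrame(
        [("a", "s1", "disease"), ("b", "s2", "control")],
        columns=["sample_id", "subject_id", "condition"],
    )
    from netcombo.expression import ExpressionMatrix

    with pytest.raises(PairingError):
        ExpressionMatrix(expr_frame, meta)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_all_zero_differences_gives_p_one():
    vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
    expr = make_paired_expression(vals, vals)
    assert paired_wilcoxon(expr).iloc[0] == 1.0


def test_wilcoxon_five_positive_pairs_exact():
    """n = 5 all-positive differences: the extreme signed-rank statistic has
    probability 2/2^5 two-sided, verified by full sign enumeration."""
    log_d = np.array([[5.0, 6.0, 7.0, 8.0, 9.0]])
    log_c = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
    expr = make_paired_expression(2.0**log_d - 1, 2.0**log_c - 1)
    p = paired_wilcoxon(expr).iloc[0]

    # sign-enumeration oracle: distribution of W+ over all 2^5 assignments
    diffs = (log_d - log_c).ravel()
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_obs = ranks[diffs > 0].sum()
    total = ranks.sum()
    count = 0
    for mask in range(2**5):
        w = sum(r for k, r in enumerate(ranks) if mask >> k & 1)
        if min(w, total - w) <= min(w_obs, total - w_obs):
            count += 1
    assert p == pytest.approx(count / 2**5)
    assert p == pytest.approx(0.0625)


def test_wilcoxon_antisymmetric_differences_not_significant():
    log_d = np.array([[4.0, 1.0, 5.0, 2.0, 6.0, 3.0]])
    log_c = np.array([[1.0, 4.0, 2.0, 5.0, 3.0, 6.0]])  # differences +-3 paired
    expr = make_paired_expression(2.0**log_d - 1, 2.0**log_c - 1)
    assert paired_wilcoxon(expr).iloc[0] >= 0.5


# ---------------------------------------------------------------------------
# variance F-test
# ---------------------------------------------------------------------------

def _f_density(x: float, d1: int, d2: int) -> float:
    """F density written out with lgamma (independent of scipy.stats.f)."""
    log_b = (
        math.lgamma(d1 / 2) + math.lgamma(d2 / 2) - math.lgamma((d1 + d2) / 2)
    )
    log_pdf = (
        (d1 / 2) * math.log(d1 / d2)
        + (d1 / 2 - 1) * math.log(x)
        - ((d1 + d2) / 2) * math.log(1 + d1 * x / d2)
        - log_b
    )
    return math.exp(log_pdf)


def test_ftest_equal_variances_gives_p_one():
    x = np.arange(11.0)
    expr = make_paired_expression(2.0 ** (x + 3) - 1, 2.0**x - 1)  # shifted, same var
    assert variance_f_test(expr).iloc[0] == pytest.approx(1.0)


def test_ftest_matches_lgamma_quadrature_oracle():
    """Variance ratio 4 with 11 samples per group: two-sided p equals twice
    the F(10, 10) upper tail at 4, computed by integrating the density."""
    x = np.arange(11.0)
    expr = make_paired_expression(2.0 ** (2 * x) - 1, 2.0**x - 1)
    p = variance_f_test(expr).iloc[0]
    upper, _ = quad(_f_density, 4.0, np.inf, args=(10, 10))
    assert p == pytest.approx(2 * upper, abs=1e-8)


def test_ftest_label_swap_symmetry():
    rng = np.random.default_rng(3)
    d = rng.random((4, 6)) * 10
    c = rng.random((4, 6)) * 10
    p1 = variance_f_test(make_paired_expression(d, c))
    p2 = variance_f_test(make_paired_expression(c, d))
    assert np.allclose(p1.to_numpy(), p2.to_numpy())


def test_ftest_degenerate_variances():
    const = np.full((2, 5), 7.0)
    varying = np.vstack([np.arange(5.0), np.full(5, 7.0)])
    expr = make_paired_expression(const, varying)
    p = variance_f_test(expr)
    assert p.iloc[0] == np.finfo(float).tiny  # one group constant
    assert p.iloc[1] == 1.0  # both constant


# ---------------------------------------------------------------------------
# significance scores
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "logfc, p, expected",
    [(3.5, 1.0, 0.0), (0.0, 1e-9, 0.0), (-2.0, 1e-3, 6.0)],
)
def test_significance_score_values(logfc, p, expected):
    ss = significance_scores(pd.Series([logfc]), np.array([p]))
    assert ss.iloc[0] == pytest.approx(expected)


def test_significance_score_rejects_p_zero():
    with pytest.raises(ValueError):
        significance_scores(pd.Series([1.0]), np.array([0.0]))


@given(
    logfc=st.floats(0.01, 10),
    p1=st.floats(1e-12, 1.0),
    p2=st.floats(1e-12, 1.0),
)
@settings(deadline=None, max_examples=50)
def test_ss_sign_invariance_and_monotonicity(logfc, p1, p2):
    lo, hi = sorted([p1, p2])
    ss = significance_scores(
        pd.Series([logfc, -logfc, logfc, logfc]), np.array([lo, lo, lo, hi])
    )
    assert ss.iloc[0] == pytest.approx(ss.iloc[1])  # |logFC| symmetry
    if lo < hi:
        assert ss.iloc[2] >= ss.iloc[3]  # smaller p never lowers SS


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _table_from_ss(ss_w: pd.Series, ss_f: pd.Series) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank_wilcoxon": rank_scores(ss_w),
            "rank_ftest": rank_scores(ss_f),
        }
    )


def test_selection_disjoint_top_lists():
    genes = [f"g{i:04d}" for i in range(1000)]
    ss_w = pd.Series(np.arange(1000, 0, -1, dtype=float), index=genes)
    ss_f = pd.Series(np.arange(1000, dtype=float), index=genes)
    sel = select_candidate_genes(_table_from_ss(ss_w, ss_f), 0.10)
    assert len(sel) == 200


def test_selection_identical_top_lists():
    genes = [f"g{i:04d}" for i in range(1000)]
    ss = pd.Series(np.arange(1000, 0, -1, dtype=float), index=genes)
    sel = select_candidate_genes(_table_from_ss(ss, ss.copy()), 0.10)
    assert len(sel) == 100


def test_selection_small_universe():
    genes = [f"g{i}" for i in range(10)]
    rng = np.random.default_rng(0)
    ss_w = pd.Series(rng.random(10), index=genes)
    ss_f = pd.Series(rng.random(10), index=genes)
    sel = select_candidate_genes(_table_from_ss(ss_w, ss_f), 0.10)
    assert len(sel) in (1, 2)


def test_selection_rejects_bad_fraction():
    genes = ["a", "b"]
    table = _table_from_ss(
        pd.Series([1.0, 2.0], index=genes), pd.Series([2.0, 1.0], index=genes)
    )
    with pytest.raises(ValueError):
        select_candidate_genes(table, 0.0)
    with pytest.raises(ValueError):
        select_candidate_genes(table, 1.5)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=25)
def test_selection_size_bounds(seed):
    rng = np.random.default_rng(seed)
    g = int(rng.integers(20, 300))
    genes = [f"g{i:04d}" for i in range(g)]
    ss_w = pd.Series(rng.random(g), index=genes)
    ss_f = pd.Series(rng.random(g), index=genes)
    k = int(np.floor(0.1 * g))
    sel = select_candidate_genes(_table_from_ss(ss_w, ss_f), 0.10)
    assert k <= len(sel) <= 2 * k


def test_score_genes_ranks_are_permutations():
    rng = np.random.default_rng(5)
    expr = make_paired_expression(rng.random((30, 12)) * 50, rng.random((30, 12)) * 50)
    table = score_genes(expr)
    for col in ("rank_wilcoxon", "rank_ftest"):
        assert sorted(table[col]) == list(range(1, 31))
    assert set(table.columns) >= {
        "logFC", "p_wilcoxon", "p_ftest", "SS_wilcoxon", "SS_ftest", "selected",
    }
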