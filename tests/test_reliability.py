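"""Error statistics, ICC/SEM, and the nonparametric tests, against
independent oracles (brute-force ANOVA, full sign enumeration, scipy and
pingouin reference implementations)."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_rigid
from pelvimetry3d.reliability import (
    RaterMatrix,
    classify_icc,
    dagostino_k2,
    error_vs_consensus,
    icc,
    leave_one_out_error,
    measure_error_loo,
    relative_error,
    sem,
    wilcoxon_signed_rank,
)
from pelvimetry3d.reliability import wilcoxon_null_pmf


def brute_force_icc(x, form):
    """Independent two-way ANOVA mean-squares computation (loops, no reuse)."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    bms = ss_rows / (n - 1)
    ems = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "(3,1)":
        return (bms - ems) / (bms + (k - 1) * ems)
    return (bms - ems) / bms


class TestLeaveOneOut:
    def test_collinear_example(self):
        errs = leave_one_out_error(np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0.0]]))
        np.testing.assert_allclose(errs, [2.0, 0.5, 2.5])

    def test_identical_raters_zero(self):
        errs = leave_one_out_error(np.tile([1.0, 2.0, 3.0], (4, 1)))
        np.testing.assert_allclose(errs, 0.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(3, 3))
        errs = leave_one_out_error(pos)
        for r in range(3):
            others = np.mean([pos[j] for j in range(3) if j != r], axis=0)
            assert errs[r] == pytest.approx(np.linalg.norm(pos[r] - others))

    def test_two_raters_flagged(self):
        with pytest.warns(UserWarning, match="2 raters"):
            errs = leave_one_out_error(np.array([[0, 0, 0], [3, 4, 0.0]]))
        np.testing.assert_allclose(errs, [5.0, 5.0])

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError, match="insufficient raters"):
            leave_one_out_error(np.array([[0, 0, 0.0]]))

    def test_scalar_variant(self):
        np.testing.assert_allclose(measure_error_loo([10.0, 11.0, 15.0]), [3.0, 1.5, 4.5])
        np.testing.assert_allclose(measure_error_loo([4.0, 4.0, 4.0]), 0.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(3, 3)) * 10
        base = leave_one_out_error(pos)
        m = random_rigid(rng)
        moved = pos @ m[:3, :3].T + m[:3, 3]
        np.testing.assert_allclose(leave_one_out_error(moved), base, atol=1e-9)

    def test_signed_deviations_from_consensus_average_to_zero(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(size=(5, 3))
        consensus = pos.mean(axis=0)
        np.testing.assert_allclose((pos - consensus).mean(axis=0), 0.0, atol=1e-12)


class TestConsensusError:
    def test_vector_example(self):
        raters = np.array([[2, 0, 0], [2, 0, 0], [2, 0, 0.0]])
        assert error_vs_consensus(np.zeros(3), raters) == pytest.approx(2.0)

    def test_equal_to_consensus_zero(self):
        raters = np.array([[1.0, 2.0], [3.0, 4.0]]).T  # scalars per rater
        assert error_vs_consensus(2.0, np.array([1.0, 3.0])) == pytest.approx(0.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        raters = rng.normal(size=(4, 3))
        val = rng.normal(size=3)
        expected = np.linalg.norm(val - raters.mean(axis=0))
        assert error_vs_consensus(val, raters) == pytest.approx(expected)

    def test_no_raters_rejected(self):
        with pytest.raises(ValueError, match="no raters"):
            error_vs_consensus(1.0, np.array([]))


class TestRelativeError:
    def test_simple_percent(self):
        assert relative_error(0.5, 10.0) == pytest.approx(5.0)
        assert relative_error(0.0, 10.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        assert icc(x, "(3,1)").icc == pytest.approx(1.0)
        assert icc(x, "(3,k)").icc == pytest.approx(1.0)

    def test_additive_rater_constants_ignored_by_consistency(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 1)) * 3
        x = base + np.array([0.0, 5.0, -2.0])
        assert icc(x, "(3,1)").icc == pytest.approx(1.0, abs=1e-12)

    def test_fixture_matrix_matches_anova_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 3)) + 2 * rng.normal(size=(5, 1))
        for form in ("(3,1)", "(3,k)"):
            assert icc(x, form).icc == pytest.approx(brute_force_icc(x, form), abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 3)) + 2 * rng.normal(size=(12, 1)) + np.array([0, 1, 2.0])
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subj", "rater", "y").set_index("Type")
        assert icc(x, "(3,1)").icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-10)
        assert icc(x, "(3,k)").icc == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-10)

    def test_spearman_brown_ordering(self):
        """ICC(3,k) >= ICC(3,1) whenever both are in (0, 1)."""
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            n = int(rng.integers(5, 31))
            x = rng.normal(size=(n, 3)) + rng.normal(size=(n, 1)) * rng.uniform(0.2, 3)
            one = icc(x, "(3,1)").icc
            kf = icc(x, "(3,k)").icc
            if 0 < one < 1 and 0 < kf < 1:
                assert kf >= one
                checked += 1

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="undefined ICC"):
            icc(np.full((4, 3), 7.0))

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            RaterMatrix(np.array([[1.0, 2.0]]))  # single subject
        with pytest.raises(ValueError, match="missing cells"):
            RaterMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestSemAndClassification:
    def test_perfect_icc_gives_zero(self):
        assert sem(np.array([1.0, 5.0, 9.0]), 1.0) == 0.0

    def test_closed_form(self):
        vals = np.array([0.0, 20.0])  # sd = sqrt(200) = 14.142
        assert sem(vals, 0.75) == pytest.approx(np.std(vals, ddof=1) * 0.5)

    def test_negative_icc_floored_and_flagged(self):
        with pytest.warns(UserWarning, match="floored"):
            out = sem(np.array([1.0, 2.0, 3.0]), -0.4)
        assert out == pytest.approx(np.std([1, 2, 3], ddof=1))

    def test_category_boundaries_inclusive(self):
        assert classify_icc(0.90) == "excellent"
        assert classify_icc(0.75) == "good"
        assert classify_icc(0.50) == "moderate"
        assert classify_icc(0.49) == "poor"
        assert classify_icc(-0.2) == "poor"


class TestWilcoxon:
    def test_all_positive_five(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2 / 32)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="no nonzero pairs"):
            wilcoxon_signed_rank(np.ones(4), np.ones(4))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            mine = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b, mode="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_full_enumeration_with_ties(self):
        rng = np.random.default_rng(4)
        d = rng.integers(-4, 5, size=8).astype(float)
        d[d == 0] = 1.0  # keep all pairs nonzero; integer diffs create ties
        res = wilcoxon_signed_rank(d, np.zeros(8))
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        w_mean = ranks.sum() / 2
        lo = min(w_obs, 2 * w_mean - w_obs)
        total = 0
        for signs in itertools.product([0, 1], repeat=8):
            w = float(np.dot(signs, ranks))
            if w <= lo + 1e-9 or w >= 2 * w_mean - lo - 1e-9:
                total += 1
        assert res.p_value == pytest.approx(total / 2**8, abs=1e-12)

    def test_null_pmf_is_probability_mass_function(self):
        ranks = sps.rankdata([1.0, 1.0, 2.5, 2.5, 4.0])
        values, pmf = wilcoxon_null_pmf(ranks)
        assert pmf.sum() == pytest.approx(1.0)
        assert (pmf >= 0).all()

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=40) + 0.5
        b = rng.normal(size=40)
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "normal-approximation"
        ref = sps.wilcoxon(a, b, correction=True, mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.02)


class TestDagostino:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="sample too small"):
            dagostino_k2(np.arange(5.0))

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(0).normal(size=500)
        _, p = dagostino_k2(x)
        assert p > 0.05
        assert p == pytest.approx(sps.normaltest(x).pvalue)

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(0).exponential(size=500)
        _, p = dagostino_k2(x)
        assert p < 0.01


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=3,
        max_size=6,
    )
)
def test_loo_errors_nonnegative_and_consistent(values):
    """Scalar leave-one-out errors are non-negative and reproduce the
    definition for every rater."""
    vals = np.asarray(values)
    errs = measure_error_loo(vals)
    assert (errs >= 0).all()
    k = len(vals)
    for r in range(k):
        others = (vals.sum() - vals[r]) / (k - 1)
        assert errs[r] == pytest.approx(abs(vals[r] - others), abs=1e-9)
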