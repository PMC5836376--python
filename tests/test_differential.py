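"""Moderated two-sample test, permutation FDR and the one-sample t-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ligandq import (
    ModeratedTTest,
    ValidationError,
    ZeroVarianceError,
    one_sample_ttest,
    significance_stars,
    volcano_classify,
)
from ligandq.differential import _d_statistic
from conftest import make_design


def _fit(data, design, **kw):
    return ModeratedTTest(data, design, **kw).fit()


def _random_matrix(n_pep, design, seed, shift=0.0):
    rng = np.random.default_rng(seed)
    cols = design.samples
    data = rng.normal(20, 2, size=(n_pep, len(cols)))
    treated = [i for i, s in enumerate(cols) if s.startswith("ifng")]
    data[:, treated] += shift
    return pd.DataFrame(data, columns=cols)


class TestDStatistic:
    def test_s0_zero_equals_textbook_pooled_t(self):
        x1 = np.array([[1.0, 2.0, 3.0]])
        x2 = np.array([[4.0, 5.0, 6.0]])
        d = _d_statistic(x1, x2, s0=0.0)
        np.testing.assert_allclose(d, [3.0 / np.sqrt(2.0 / 3.0)], rtol=1e-12)
        np.testing.assert_allclose(d, [3.674], atol=5e-4)

    def test_s0_zero_matches_scipy_on_random_rows(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=(1000, 4))
        x2 = rng.normal(size=(1000, 5))
        d = _d_statistic(x1, x2, s0=0.0)
        ref = stats.ttest_ind(x2, x1, axis=1).statistic
        np.testing.assert_allclose(d, ref, atol=1e-9)

    def test_identical_groups_give_zero(self):
        x = np.array([[5.0, 5.0, 5.0]])
        assert _d_statistic(x, x, s0=0.0) == 0.0
        assert _d_statistic(x, x, s0=1.0) == 0.0

    def test_abs_d_strictly_decreasing_in_s0(self):
        x1 = np.array([[1.0, 2.0, 3.0]])
        x2 = np.array([[4.0, 5.0, 6.0]])
        d_vals = [abs(_d_statistic(x1, x2, s0)[0]) for s0 in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(d_vals, d_vals[1:]))


class TestPermutationFDR:
    def test_q_values_monotone_in_abs_d(self, two_group_design):
        res = _fit(_random_matrix(300, two_group_design, seed=5, shift=0.7),
                   two_group_design, s0=1.0)
        frame = res.frame.sort_values("d", key=np.abs, ascending=False)
        assert (np.diff(frame["q"]) >= -1e-15).all()

    def test_invariant_to_sample_column_order(self, two_group_design):
        data = _random_matrix(100, two_group_design, seed=6, shift=0.5)
        res1 = _fit(data, two_group_design)
        res2 = _fit(data[data.columns[::-1]], two_group_design)
        pd.testing.assert_frame_equal(res1.frame, res2.frame)

    def test_exhaustive_enumeration_for_small_designs(self, two_group_design):
        res = _fit(_random_matrix(20, two_group_design, seed=7), two_group_design)
        assert res.n_relabelings == 70  # C(8, 4)

    def test_global_null_yields_few_significant_calls(self, two_group_design):
        fracs = []
        for seed in range(5):
            res = _fit(_random_matrix(500, two_group_design, seed=100 + seed),
                       two_group_design, s0=1.0, fdr=0.01)
            fracs.append((res.n_up + res.n_down) / 500)
        assert np.mean(fracs) <= 0.02

    def test_requires_complete_matrix(self, two_group_design):
        data = _random_matrix(10, two_group_design, seed=8)
        data.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="complete"):
            ModeratedTTest(data, two_group_design)

    def test_requires_two_samples_per_group(self):
        design = make_design({"ctrl": ["ctrl_1"], "ifng": ["ifng_1", "ifng_2"]})
        data = pd.DataFrame(np.ones((5, 3)), columns=design.samples)
        with pytest.raises(ValidationError):
            ModeratedTTest(data, design)


class TestVolcanoClassify:
    @pytest.mark.parametrize(
        "q,log2fc,expected",
        [(0.005, 2.0, "up"), (0.005, -2.0, "down"), (0.5, 5.0, "ns"), (0.005, 0.0, "ns")],
    )
    def test_classes(self, q, log2fc, expected):
        frame = pd.DataFrame({"q": [q], "log2fc": [log2fc]})
        assert volcano_classify(frame, fdr=0.01)["volcano_class"].iloc[0] == expected

    def test_counts_partition_the_table(self, two_group_design):
        res = _fit(_random_matrix(200, two_group_design, seed=9, shift=1.0),
                   two_group_design)
        assert res.n_up + res.n_down + res.n_ns == 200


class TestOneSampleTTest:
    def test_closed_form_example(self):
        res = one_sample_ttest([0.5, 0.6, 0.4, 0.5])
        assert res["t"] == pytest.approx(12.247, abs=1e-3)
        assert res["p"] < 0.01
        assert res["stars"] == "***"

    def test_zero_mean_gives_half(self):
        res = one_sample_ttest([-1.0, 1.0, -2.0, 2.0])
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(0.5)

    def test_single_value_raises(self):
        with pytest.raises(ValidationError):
            one_sample_ttest([1.0])

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            one_sample_ttest([1.0, 1.0, 1.0])


@pytest.mark.parametrize(
    "p,expected", [(0.005, "***"), (0.03, "**"), (0.07, "*"), (0.5, "")]
)
def test_significance_star_thresholds(p, expected):
    assert significance_stars(p) == expected
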